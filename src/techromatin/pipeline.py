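"""End-to-end orchestration: simulate -> regions -> enrichment -> composition
-> Z-scores -> expression link.

Every stage lives in its own module; this wires them together with
deterministic per-stage random substreams derived from the master seed, and
optionally writes each stage's tidy TSV under an output directory. The
numbered driver scripts under ``analysis/`` run the same stages one at a
time against files on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chromatin_regions import (
    ACTIVE, REPRESSED, RegionSet, extract_regions, region_summary, write_region_bed,
)
from .composition import (
    assign_typologies, class_by_mark_association, class_composition_test,
    repression_mark_partition, typology_enrichment,
)
from .enrichment import age_class_enrichment, permutation_enrichment
from .synthetic_data import SimulationConfig, SimulatedDataset, simulate_dataset
from .tissue_specificity import (
    VarianceAnalysisResult, categorize_genes, compute_zscores,
    or_matrix_from_enrichment, te_gene_assignments, tissue_expression_shift,
    variance_category_analysis, variance_records,
)

logger = logging.getLogger(__name__)

FDR_THRESHOLD = 0.05


def stage_rng(seed: int, *tags: int) -> np.random.Generator:
    """Independent generator for one pipeline stage, derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(tags)))


@dataclass
class PipelineResult:
    dataset: SimulatedDataset
    regions: dict
    region_summary: pd.DataFrame
    enrichment: pd.DataFrame
    age_enrichment: pd.DataFrame
    age_summary: pd.DataFrame
    typology: pd.DataFrame
    typology_tests: pd.DataFrame
    class_composition: pd.DataFrame
    mark_partition: pd.DataFrame
    class_by_mark: pd.DataFrame
    zscores: pd.DataFrame
    categories: pd.DataFrame
    variance: VarianceAnalysisResult | None
    shift: pd.DataFrame


def extract_all_regions(dataset: SimulatedDataset) -> dict[tuple[str, str], RegionSet]:
    return {
        (tissue, activity): extract_regions(
            dataset.segmentations[tissue], activity, tissue_id=tissue
        )
        for tissue in dataset.config.tissues
        for activity in (ACTIVE, REPRESSED)
    }


def run_enrichment(dataset, regions, n_reps: int, seed: int) -> pd.DataFrame:
    """Family-level permutation enrichment for every (tissue, activity) run."""
    frames = []
    for i, ((tissue, activity), rs) in enumerate(sorted(regions.items())):
        res = permutation_enrichment(
            dataset.te_catalog, rs, dataset.genome, n_reps, stage_rng(seed, 1, i)
        )
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def run_age_enrichment(dataset, regions, n_reps: int, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    per, summ = [], []
    for i, ((tissue, activity), rs) in enumerate(sorted(regions.items())):
        a, b = age_class_enrichment(
            dataset.te_catalog, rs, dataset.genome, n_reps, stage_rng(seed, 2, i)
        )
        per.append(a)
        summ.append(b)
    return pd.concat(per, ignore_index=True), pd.concat(summ, ignore_index=True)


def run_composition(dataset, regions, enrichment: pd.DataFrame):
    """Typology, class composition, repressive-mark partition and class-by-mark tests."""
    from ._intervals import overlap_any_and_bp
    from .composition import GeneIndex

    gene_index = GeneIndex(dataset.genes)
    te_df = dataset.te_catalog.df
    background = assign_typologies(te_df, gene_index)
    background["tissue"] = "(all copies)"

    typology_rows, typo_test_rows, class_rows, mark_rows, cbm_rows = [], [], [], [], []
    for (tissue, activity), rs in sorted(regions.items()):
        if activity == ACTIVE:
            by_chrom = rs.merged_by_chrom()
            hit = np.zeros(len(te_df), dtype=bool)
            for chrom, sub in te_df.groupby("chrom", sort=False):
                if chrom in by_chrom:
                    m, _ = overlap_any_and_bp(
                        sub["start"].values, sub["end"].values, *by_chrom[chrom]
                    )
                    hit[sub.index] = m
            interest = assign_typologies(te_df[hit], gene_index)
            interest["tissue"] = tissue
            typology_rows.append(interest)
            if len(interest):
                t = typology_enrichment(interest, background)
                t.insert(0, "tissue", tissue)
                typo_test_rows.append(t)
        else:
            part = repression_mark_partition(rs, dataset.te_catalog)
            base = repression_mark_partition(rs)
            mark_rows.append(
                {
                    "tissue": tissue, "n_k27": part.n_k27, "n_k9": part.n_k9,
                    "fraction_k27": part.fraction_k27,
                    "baseline_fraction_k27": base.fraction_k27,
                    "p_value": part.p_value,
                }
            )
            try:
                cbm = class_by_mark_association(dataset.te_catalog, rs)
                cbm.insert(0, "tissue", tissue)
                cbm_rows.append(cbm)
            except ValueError:
                logger.warning("no TE copies on repressed fragments of %s", tissue)

        enriched = enrichment.query(
            "tissue == @tissue and activity == @activity and "
            "direction == 'enriched' and q_value < @FDR_THRESHOLD"
        )["key"].tolist()
        if enriched:
            cc = class_composition_test(enriched, dataset.te_catalog)
            cc.insert(0, "activity", activity)
            cc.insert(0, "tissue", tissue)
            class_rows.append(cc)

    empty = pd.DataFrame()
    return (
        pd.concat(typology_rows, ignore_index=True) if typology_rows else empty,
        pd.concat(typo_test_rows, ignore_index=True) if typo_test_rows else empty,
        pd.concat(class_rows, ignore_index=True) if class_rows else empty,
        pd.DataFrame(mark_rows),
        pd.concat(cbm_rows, ignore_index=True) if cbm_rows else empty,
    )


def run_expression_link(dataset, regions):
    """Gene categories, the variance model and the planted-shift test."""
    region_sets = [rs for _, rs in sorted(regions.items())]
    assignments = te_gene_assignments(dataset.te_catalog, region_sets, dataset.genes)
    categories = categorize_genes(assignments, dataset.genes)
    recs = variance_records(dataset.expression, dataset.genes, dataset.genome)
    variance = None
    if (categories["category"].value_counts() >= 2).sum() >= 2:
        variance = variance_category_analysis(recs, categories)

    shift_rows = []
    shift_genes = dataset.truth.get("shift", {}).get("genes", [])
    focal = dataset.truth.get("shift", {}).get("focal_tissue")
    if focal and len(shift_genes) >= 3:
        res = tissue_expression_shift(shift_genes, focal, dataset.expression)
        shift_rows.append(
            {
                "gene_set": "planted_shift_set", "focal_tissue": focal,
                "n_genes": res.n_genes, "median_focal": res.median_focal,
                "median_other": res.median_other, "p_value": res.p_value,
                "direction": res.direction,
            }
        )
    return categories, variance, pd.DataFrame(shift_rows)


def run_pipeline(
    config: SimulationConfig,
    n_reps: int = 200,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """The whole analysis on one simulated dataset; see class docstrings for stages."""
    out = Path(out_dir) if out_dir is not None else None
    dataset = simulate_dataset(config, out / "data" if out else None)
    regions = extract_all_regions(dataset)
    summary = region_summary([rs for _, rs in sorted(regions.items())])
    enrichment = run_enrichment(dataset, regions, n_reps, config.seed)
    age_enr, age_sum = run_age_enrichment(dataset, regions, n_reps, config.seed)
    typology, typo_tests, class_comp, mark_part, cbm = run_composition(
        dataset, regions, enrichment
    )
    active_or = or_matrix_from_enrichment(enrichment[enrichment["activity"] == ACTIVE])
    zscores = compute_zscores(active_or)
    categories, variance, shift = run_expression_link(dataset, regions)

    result = PipelineResult(
        dataset, regions, summary, enrichment, age_enr, age_sum, typology,
        typo_tests, class_comp, mark_part, cbm, zscores, categories, variance, shift,
    )
    if out is not None:
        write_outputs(result, out)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    regions_dir = out / "regions"
    regions_dir.mkdir(exist_ok=True)
    for (tissue, activity), rs in sorted(result.regions.items()):
        write_region_bed(rs, regions_dir / f"{tissue}_{activity}.bed")

    def dump(df: pd.DataFrame, name: str, index=False):
        df.to_csv(out / name, sep="\t", index=index, float_format="%.10g", lineterminator="\n")

    dump(result.region_summary, "region_summary.tsv")
    dump(result.enrichment, "enrichment.tsv")
    dump(result.age_enrichment, "age_enrichment.tsv")
    dump(result.age_summary, "age_summary.tsv")
    dump(result.typology, "typology.tsv")
    dump(result.typology_tests, "typology_tests.tsv")
    dump(result.class_composition, "class_composition.tsv")
    dump(result.mark_partition, "mark_partition.tsv")
    dump(result.class_by_mark, "class_by_mark.tsv")
    dump(result.zscores, "zscores.tsv", index=True)
    dump(result.categories, "gene_categories.tsv")
    if result.variance is not None:
        dump(result.variance.wilcoxon, "variance_wilcoxon.tsv")
        dump(result.variance.ols, "variance_ols.tsv", index=True)
    dump(result.shift, "expression_shift.tsv")
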