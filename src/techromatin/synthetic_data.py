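"""Synthetic multi-tissue datasets with planted, parameterised structure.

Emulates the shape of the real inputs — per-tissue dense chromHMM
segmentations, a RepeatMasker-style TE catalog with families, classes and
age classes, BED12 gene models, and a gene x tissue mean-TPM matrix — at a
toy scale where every pipeline stage runs in seconds, with a ground-truth
manifest recording every planted effect.

Planting:

* *TE enrichment*: a family targeted at (tissue T, activity A, bias b) is
  placed by rejection sampling against the realised segmentation of T, so
  that the probability of a copy overlapping an A-region is b times the
  uniform-placement probability. b > 1 plants enrichment, b < 1 depletion,
  b = 1 is indistinguishable from uniform. b times the A overlap
  probability must not exceed 1, else the bias is unreachable.
* *Expression variance*: per-tissue TPMs are Gamma around a per-gene
  log-normal baseline, with the Gamma scale equal to the index of
  dispersion (variance / mean), so a variance-inflation factor v on
  TE-in-active-chromatin (category 1) genes shifts their expected
  normalised variance by exactly dispersion * (v - 1).
* *Tissue shift*: a designated gene set has its TPM multiplied by a fold
  factor in one focal tissue only.

One master seed makes every emitted file byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._intervals import overlap_any_and_bp
from .chromatin_regions import ACTIVE, REPRESSED, extract_regions
from .io_formats import (
    ExpressionMatrix,
    GeneCatalog,
    GeneModel,
    GenomeTable,
    Segmentation,
    TECatalog,
    TE_COLUMNS,
    write_chrom_sizes,
    write_expression_matrix,
    write_gene_models,
    write_segmentation,
    write_te_bed,
)
from .tissue_specificity import categorize_genes, te_gene_assignments


@dataclass(frozen=True)
class StateGrammar:
    """Chromatin-state vocabulary: target bp fractions and mean segment lengths."""

    freqs: Mapping[str, float]
    mean_lengths: Mapping[str, float]

    def __post_init__(self):
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state frequencies must sum to 1, got {total}")
        missing = set(self.freqs) - set(self.mean_lengths)
        if missing:
            raise ValueError(f"states without a mean length: {sorted(missing)}")


#: coreMarks-like default grammar: ~10% active bp, ~15% repressed bp, rest quiescent.
DEFAULT_GRAMMAR = StateGrammar(
    freqs={
        "TssA": 0.010, "TssAFlnk": 0.005, "TxFlnk": 0.005, "Tx": 0.0275,
        "TxWk": 0.0275, "EnhG": 0.005, "Enh": 0.015, "TssBiv": 0.0025,
        "EnhBiv": 0.0025, "Het": 0.040, "ReprPC": 0.060, "ReprPCWk": 0.050,
        "Quies": 0.750,
    },
    mean_lengths={
        "TssA": 400, "TssAFlnk": 300, "TxFlnk": 300, "Tx": 2000, "TxWk": 2000,
        "EnhG": 300, "Enh": 400, "TssBiv": 300, "EnhBiv": 300,
        "Het": 3000, "ReprPC": 1500, "ReprPCWk": 1500, "Quies": 8000,
    },
)


@dataclass(frozen=True)
class FamilySpec:
    """One TE family: copy number, length range, and an optional planted target."""

    family: str
    te_class: str
    age_class: str
    n_copies: int
    length_min: int = 150
    length_max: int = 1500
    # (tissue_id, activity, bias); bias > 1 plants enrichment, < 1 depletion
    target: tuple[str, str, float] | None = None


def default_family_specs() -> list[FamilySpec]:
    """Thirty families across the five classes; a handful carry planted biases.

    Ancient (pre-eutherian) SINE/DNA families are planted into active
    chromatin and young LTR/SVA families into repressed chromatin, mirroring
    the age-by-activity structure the pipeline is meant to resolve; one LINE
    family is planted depleted from active chromatin.
    """
    specs = [
        FamilySpec("F01_SINE", "SINE", "Mammalia", 400, target=("t1", ACTIVE, 3.0)),
        FamilySpec("F02_DNA", "DNA", "Eutheria", 300, target=("t2", ACTIVE, 3.0)),
        FamilySpec("F03_LTR", "LTR", "Hominidae", 300, target=("t1", REPRESSED, 3.0)),
        FamilySpec("F04_SVA", "SVA", "Homo", 200, target=("t2", REPRESSED, 3.0)),
        FamilySpec("F05_LINE", "LINE", "Primates", 300, target=("t1", ACTIVE, 1 / 3)),
    ]
    ages = ["Vertebrata", "Mammalia", "Eutheria", "Primates", "Hominidae"]
    classes = ["SINE"] * 8 + ["DNA"] * 5 + ["LINE"] * 6 + ["LTR"] * 4 + ["SVA"] * 2
    rng = np.random.default_rng(1729)  # fixed: the default family table is a constant
    for i, klass in enumerate(classes, start=6):
        specs.append(
            FamilySpec(
                f"F{i:02d}_{klass}", klass, ages[(i - 6) % len(ages)],
                n_copies=int(rng.integers(100, 501)),
            )
        )
    return specs


#: sparse grammar for the expression-link study: ~2% active and ~2% repressed bp.
#: With eight independent tissue tracks this keeps all four gene categories
#: populated — under denser coverage nearly every gene's TE partners touch both
#: activity classes somewhere and the "mixed" category swallows the rest.
EXPRESSION_GRAMMAR = StateGrammar(
    freqs={
        "TssA": 0.002, "TssAFlnk": 0.001, "TxFlnk": 0.001, "Tx": 0.005,
        "TxWk": 0.004, "EnhG": 0.001, "Enh": 0.004, "TssBiv": 0.001,
        "EnhBiv": 0.001, "Het": 0.006, "ReprPC": 0.008, "ReprPCWk": 0.006,
        "Quies": 0.960,
    },
    mean_lengths={
        "TssA": 400, "TssAFlnk": 300, "TxFlnk": 300, "Tx": 2000, "TxWk": 2000,
        "EnhG": 300, "Enh": 400, "TssBiv": 300, "EnhBiv": 300,
        "Het": 3000, "ReprPC": 1500, "ReprPCWk": 1500, "Quies": 20000,
    },
)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the toy study conditions."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    n_tissues: int = 4
    state_grammar: StateGrammar = field(default_factory=lambda: DEFAULT_GRAMMAR)
    family_specs: list[FamilySpec] = field(default_factory=default_family_specs)
    n_genes: int = 300
    exons_per_gene: int = 5
    exon_length: int = 200
    gene_length_min: int = 5_000
    gene_length_max: int = 20_000
    # robustly expressed genes (~40 TPM): the var/mean ratio estimator has a
    # deterministic downward bias ~ dispersion^2 * E[1/baseline] / n_tissues,
    # so low baselines would distort the planted dispersion effects
    baseline_log_mean: float = 3.7   # ln TPM
    baseline_log_sd: float = 0.7
    dispersion: float = 1.0          # baseline index of dispersion (var/mean of TPM)
    variance_inflation: float = 2.0  # multiplies dispersion for category-1 genes
    shift_fold: float = 3.0          # TPM multiplier in the focal tissue
    shift_focal_tissue: str = "t1"
    n_shift_genes: int = 50

    @property
    def tissues(self) -> list[str]:
        return [f"t{i + 1}" for i in range(self.n_tissues)]

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.n_tissues < 2:
            raise ValueError("need at least two tissues")
        tissues = set(self.tissues)
        for spec in self.family_specs:
            if spec.target is not None:
                tissue, activity, bias = spec.target
                if tissue not in tissues:
                    raise ValueError(f"{spec.family}: target tissue {tissue!r} does not exist")
                if activity not in (ACTIVE, REPRESSED):
                    raise ValueError(f"{spec.family}: bad target activity {activity!r}")
                if bias <= 0:
                    raise ValueError(f"{spec.family}: bias must be positive")
            if spec.length_max >= self.chrom_length:
                raise ValueError(f"{spec.family}: copy length exceeds chromosome length")
        if self.shift_focal_tissue not in tissues:
            raise ValueError(f"shift focal tissue {self.shift_focal_tissue!r} does not exist")

    @classmethod
    def null_study(cls, seed: int = 0, n_families: int = 50, n_copies: int = 150,
                   n_tissues: int = 2) -> "SimulationConfig":
        """Calibration conditions: many families, nothing planted."""
        classes = ["SINE", "DNA", "LINE", "LTR", "SVA"]
        specs = [
            FamilySpec(f"N{i:02d}_{classes[i % 5]}", classes[i % 5],
                       "Eutheria" if i % 2 else "Primates", n_copies)
            for i in range(n_families)
        ]
        return cls(seed=seed, n_tissues=n_tissues, family_specs=specs)

    @classmethod
    def expression_study(cls, seed: int = 0, variance_inflation: float = 2.0,
                         shift_fold: float = 3.0) -> "SimulationConfig":
        """Conditions for the TE / expression-variance and tissue-shift analyses.

        A 100 Mb genome carrying 2,000 genes and a sparse chromatin landscape
        (:data:`EXPRESSION_GRAMMAR`), eight tissues, and a moderate TE load
        (15 families x 300 copies), so the four TE-association gene categories
        are all populated with at least a couple of hundred genes each.
        """
        classes = ["SINE", "DNA", "LINE", "LTR", "SVA"]
        specs = [
            FamilySpec(f"E{i:02d}_{classes[i % 5]}", classes[i % 5],
                       "Eutheria" if i % 2 else "Hominidae", 300,
                       length_min=150, length_max=600)
            for i in range(15)
        ]
        return cls(
            seed=seed, n_chromosomes=4, chrom_length=25_000_000, n_tissues=8,
            state_grammar=EXPRESSION_GRAMMAR, family_specs=specs, n_genes=2000,
            variance_inflation=variance_inflation, shift_fold=shift_fold,
            shift_focal_tissue="t1", n_shift_genes=100,
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "state_grammar" in raw:
            raw["state_grammar"] = StateGrammar(**raw["state_grammar"])
        if "family_specs" in raw:
            raw["family_specs"] = [
                FamilySpec(**{**f, "target": tuple(f["target"]) if f.get("target") else None})
                for f in raw["family_specs"]
            ]
        return cls(**raw)


# ---------------------------------------------------------------------------
# genome and segmentations
# ---------------------------------------------------------------------------


def simulate_genome(config: SimulationConfig) -> GenomeTable:
    """Chromosomes chrS1..chrSn of the configured length."""
    config.validate()
    return GenomeTable(
        {f"chrS{i + 1}": config.chrom_length for i in range(config.n_chromosomes)}
    )


def simulate_segmentations(
    config: SimulationConfig, genome: GenomeTable, rng: np.random.Generator
) -> dict[str, Segmentation]:
    """Tile every chromosome end-to-end with labelled segments, per tissue.

    States are drawn with probability proportional to freq / mean_length (so
    the *bp* fraction converges to the grammar frequency) and segment lengths
    are geometric with the stated means; the last segment is clipped to the
    chromosome end. Independent across tissues.
    """
    grammar = config.state_grammar
    states = sorted(grammar.freqs)
    draw_w = np.array([grammar.freqs[s] / grammar.mean_lengths[s] for s in states])
    draw_w = draw_w / draw_w.sum()
    p_geo = np.array([1.0 / grammar.mean_lengths[s] for s in states])
    out = {}
    for tissue in config.tissues:
        rows = []
        for chrom in genome.chroms:
            L = genome.lengths[chrom]
            pos = 0
            # draw in batches to keep the loop cheap
            while pos < L:
                n_batch = max(16, int((L - pos) / min(grammar.mean_lengths.values())) + 16)
                idx = rng.choice(len(states), size=n_batch, p=draw_w)
                lens = rng.geometric(p_geo[idx])
                for k, ln in zip(idx, lens):
                    end = min(pos + int(ln), L)
                    rows.append((chrom, pos, end, states[k]))
                    pos = end
                    if pos >= L:
                        break
        out[tissue] = Segmentation(pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]), genome)
    return out


# ---------------------------------------------------------------------------
# TE catalog with planted biases
# ---------------------------------------------------------------------------


def _target_regions(segmentations, tissue, activity):
    return extract_regions(segmentations[tissue], activity, tissue_id=tissue).merged_by_chrom()


def simulate_te_catalog(
    config: SimulationConfig,
    genome: GenomeTable,
    segmentations: Mapping[str, Segmentation],
    rng: np.random.Generator,
) -> tuple[TECatalog, dict]:
    """Place every family's copies, biased into the target regions where planted.

    Untargeted families are uniform over the genome (chromosome chosen
    proportional to length, start uniform). For a target (T, A, b) each copy
    is rejection-sampled so its probability of overlapping an A-region of T
    is b times the uniform probability; the realised and background overlap
    rates are recorded in the returned ground-truth dict.
    """
    config.validate()
    chroms = genome.chroms
    chrom_lens = np.array([genome.lengths[c] for c in chroms], dtype=np.int64)
    chrom_w = chrom_lens / chrom_lens.sum()

    region_cache: dict[tuple[str, str], dict] = {}
    frames = []
    truth_families: dict[str, dict] = {}
    for spec in config.family_specs:
        n = spec.n_copies
        lens = rng.integers(spec.length_min, spec.length_max + 1, size=n)
        ci = rng.choice(len(chroms), size=n, p=chrom_w)
        starts = rng.integers(0, chrom_lens[ci] - lens + 1)

        info = {"target": None, "bias": 1.0, "realized_overlap_rate": None,
                "background_overlap_rate": None, "n_copies": int(n)}
        if spec.target is not None:
            tissue, activity, bias = spec.target
            key = (tissue, activity)
            if key not in region_cache:
                region_cache[key] = _target_regions(segmentations, tissue, activity)
            regions = region_cache[key]

            def overlaps(ci_, s_, lens_):
                hit = np.zeros(len(s_), dtype=bool)
                for j, chrom in enumerate(chroms):
                    m = ci_ == j
                    if m.any() and chrom in regions:
                        rs, re = regions[chrom]
                        h, _ = overlap_any_and_bp(s_[m], s_[m] + lens_[m], rs, re)
                        hit[m] = h
                return hit

            hit = overlaps(ci, starts, lens)
            f = hit.mean()  # uniform-placement overlap probability, estimated on proposals
            n_prop, n_hit_prop = n, int(hit.sum())
            if bias * f > 1:
                raise ValueError(
                    f"{spec.family}: bias {bias} unreachable "
                    f"(uniform overlap probability ~{f:.3f})"
                )
            if bias >= 1:
                p_in, p_out = 1.0, (1 - bias * f) / (bias * (1 - f)) if f < 1 else 0.0
            else:
                p_in, p_out = bias * (1 - f) / (1 - bias * f), 1.0
            accepted = rng.random(n) < np.where(hit, p_in, p_out)
            # redraw rejected copies until all are placed
            for _ in range(10_000):
                if accepted.all():
                    break
                m = ~accepted
                k = int(m.sum())
                ci_new = rng.choice(len(chroms), size=k, p=chrom_w)
                s_new = rng.integers(0, chrom_lens[ci_new] - lens[m] + 1)
                h_new = overlaps(ci_new, s_new, lens[m])
                n_prop += k
                n_hit_prop += int(h_new.sum())
                keep = rng.random(k) < np.where(h_new, p_in, p_out)
                ci[m] = np.where(keep, ci_new, ci[m])
                starts[m] = np.where(keep, s_new, starts[m])
                acc = accepted.copy()
                acc[m] = keep
                accepted = acc
            else:
                raise RuntimeError(f"{spec.family}: rejection sampling did not converge")
            final_hit = overlaps(ci, starts, lens)
            info = {
                "target": [tissue, activity, bias], "bias": float(bias),
                "realized_overlap_rate": float(final_hit.mean()),
                "background_overlap_rate": float(n_hit_prop / n_prop),
                "n_copies": int(n),
            }
        truth_families[spec.family] = info
        frames.append(
            pd.DataFrame(
                {
                    "chrom": np.array(chroms, dtype=object)[ci],
                    "start": starts,
                    "end": starts + lens,
                    "family": spec.family,
                    "te_class": spec.te_class,
                    "strand": np.where(rng.random(n) < 0.5, "+", "-"),
                    "age_class": spec.age_class,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)[TE_COLUMNS]
    df = df.sort_values(["chrom", "start", "end", "family"], kind="stable").reset_index(drop=True)
    return TECatalog(df, genome), {"families": truth_families}


# ---------------------------------------------------------------------------
# genes and expression
# ---------------------------------------------------------------------------


def simulate_genes(config: SimulationConfig, genome: GenomeTable, rng: np.random.Generator) -> GeneCatalog:
    """Uniformly placed genes with evenly spaced fixed-size exon blocks."""
    chroms = genome.chroms
    chrom_lens = np.array([genome.lengths[c] for c in chroms], dtype=np.int64)
    chrom_w = chrom_lens / chrom_lens.sum()
    genes = []
    for i in range(config.n_genes):
        length = int(rng.integers(config.gene_length_min, config.gene_length_max + 1))
        j = int(rng.choice(len(chroms), p=chrom_w))
        start = int(rng.integers(0, chrom_lens[j] - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        k = config.exons_per_gene
        gap = (length - k * config.exon_length) // max(k - 1, 1) + config.exon_length
        ex_s = tuple(start + min(m * gap, length - config.exon_length) for m in range(k))
        ex_e = tuple(s + config.exon_length for s in ex_s)
        genes.append(GeneModel(f"g{i:04d}", chroms[j], start, start + length, strand, ex_s, ex_e))
    return GeneCatalog(genes, genome)


def simulate_expression(
    config: SimulationConfig,
    gene_ids: Sequence[str],
    categories: Mapping[str, int],
    rng: np.random.Generator,
) -> tuple[ExpressionMatrix, dict]:
    """Gamma TPMs around log-normal per-gene baselines, with planted effects.

    Category-1 genes get their index of dispersion multiplied by
    ``variance_inflation``; a random set of ``n_shift_genes`` genes gets TPM
    multiplied by ``shift_fold`` in the focal tissue only.
    """
    gene_ids = list(gene_ids)
    n, t = len(gene_ids), config.n_tissues
    base = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n))
    cat = np.array([categories.get(g, 4) for g in gene_ids])
    theta = np.where(cat == 1, config.dispersion * config.variance_inflation, config.dispersion)
    shape = base / theta
    tpm = rng.gamma(shape[:, None], theta[:, None], size=(n, t))

    n_shift = min(config.n_shift_genes, n)
    shift_idx = rng.choice(n, size=n_shift, replace=False) if n_shift else np.array([], dtype=int)
    focal_col = config.tissues.index(config.shift_focal_tissue)
    tpm[shift_idx, focal_col] *= config.shift_fold

    expr = ExpressionMatrix(pd.DataFrame(tpm, index=pd.Index(gene_ids, name="gene_id"),
                                         columns=config.tissues))
    truth = {
        "genes": {
            g: {
                "category": int(cat[i]),
                "dispersion": float(theta[i]),
                "shifted": bool(i in set(shift_idx.tolist())),
            }
            for i, g in enumerate(gene_ids)
        },
        "planted_variance_effect": float(config.dispersion * (config.variance_inflation - 1)),
        "shift": {
            "focal_tissue": config.shift_focal_tissue,
            "fold": float(config.shift_fold),
            "genes": sorted(gene_ids[i] for i in shift_idx),
        },
    }
    return expr, truth


def simulate_genes_and_expression(
    config: SimulationConfig,
    genome: GenomeTable,
    te_catalog: TECatalog,
    segmentations: Mapping[str, Segmentation],
    rng: np.random.Generator,
) -> tuple[GeneCatalog, ExpressionMatrix, dict]:
    """Genes, their TE-association categories, and the expression matrix.

    Categories follow the pipeline's own rules: every TE copy overlapping an
    active or repressed region of any tissue is assigned to its nearest-TSS
    gene, and genes are split 1/2/3/4 on the activities of their TE partners.
    """
    genes = simulate_genes(config, genome, rng)
    region_sets = [
        extract_regions(segmentations[tissue], activity, tissue_id=tissue)
        for tissue in config.tissues
        for activity in (ACTIVE, REPRESSED)
    ]
    assignments = te_gene_assignments(te_catalog, region_sets, genes)
    cats = categorize_genes(assignments, genes)
    cat_map = dict(zip(cats["gene_id"], cats["category"]))
    expr, truth = simulate_expression(config, genes.gene_ids(), cat_map, rng)
    return genes, expr, truth


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: GenomeTable
    segmentations: dict[str, Segmentation]
    te_catalog: TECatalog
    genes: GeneCatalog
    expression: ExpressionMatrix
    truth: dict


def simulate_dataset(config: SimulationConfig, out_dir=None) -> SimulatedDataset:
    """Run the full generator from the master seed; optionally write all files.

    Emits chrom.sizes, te.bed (BED6+age), one segmentation BED per tissue,
    genes.bed12, expr.tsv and truth.json under ``out_dir``. Byte-identical
    across runs with the same config.
    """
    config.validate()
    master = np.random.default_rng(config.seed)
    rng_seg, rng_te, rng_genes = master.spawn(3)
    genome = simulate_genome(config)
    segmentations = simulate_segmentations(config, genome, rng_seg)
    te_catalog, truth_te = simulate_te_catalog(config, genome, segmentations, rng_te)
    genes, expr, truth_expr = simulate_genes_and_expression(
        config, genome, te_catalog, segmentations, rng_genes
    )
    truth = {**truth_te, **truth_expr, "seed": config.seed}
    ds = SimulatedDataset(config, genome, segmentations, te_catalog, genes, expr, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_chrom_sizes(genome, out / "chrom.sizes")
        write_te_bed(te_catalog, out / "te.bed")
        for tissue, seg in segmentations.items():
            write_segmentation(seg, out / f"segmentation_{tissue}.bed")
        write_gene_models(genes, out / "genes.bed12")
        write_expression_matrix(expr, out / "expr.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return ds
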