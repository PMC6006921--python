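"""Tissue-specificity effect sizes and the TE / gene-expression link.

Z-scores: for each TE family the per-tissue enrichment odds ratios are
standardised across tissues, z_t = (OR_t - mean(OR)) / sd(OR) (sample sd),
using finite entries only. A high z marks the tissue where the family's
enrichment is most tissue-specific. Rows with fewer than 3 finite odds
ratios or zero spread are reported as all-NA.

Expression link: every TE copy overlapping an active or repressed region in
some tissue is assigned to the gene with the nearest transcription start
site. Genes are then split into four categories — (1) TE partners only ever
in active regions, (2) mixed, (3) only in repressed regions, (4) never
TE-associated — and the cross-tissue expression variance of each gene
(normalised by its grand mean TPM, an index of dispersion) is compared
across categories by rank-sum tests and by an OLS fit with gene length and
local exonic density (exonic bp within +/- 100 kb) as covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._intervals import merge_intervals, overlap_any_and_bp
from .chromatin_regions import RegionSet
from .io_formats import ExpressionMatrix, GeneCatalog, GenomeTable, TECatalog

logger = logging.getLogger(__name__)

DENSITY_WINDOW = 100_000  # bp either side of the gene body

CATEGORY_LABELS = {1: "active_only", 2: "mixed", 3: "repressed_only", 4: "no_te"}


# ---------------------------------------------------------------------------
# Z-scores
# ---------------------------------------------------------------------------


def or_matrix_from_enrichment(records: pd.DataFrame) -> pd.DataFrame:
    """Pivot enrichment records into a family x tissue odds-ratio matrix."""
    return records.pivot_table(index="key", columns="tissue", values="odds_ratio", aggfunc="first")


def compute_zscores(or_matrix: pd.DataFrame, min_finite: int = 3) -> pd.DataFrame:
    """Standardise each family row of an odds-ratio matrix across tissues.

    Uses finite entries only (sample sd, ddof=1). Rows with fewer than
    ``min_finite`` finite entries, or zero spread, are all-NA.
    """
    values = or_matrix.to_numpy(dtype=float)
    z = np.full_like(values, np.nan)
    finite = np.isfinite(values)
    for i in range(values.shape[0]):
        f = finite[i]
        if f.sum() < min_finite:
            continue
        row = values[i, f]
        sd = row.std(ddof=1)
        if sd == 0:
            continue
        z[i, f] = (row - row.mean()) / sd
    return pd.DataFrame(z, index=or_matrix.index, columns=or_matrix.columns)


# ---------------------------------------------------------------------------
# nearest-gene assignment and gene categories
# ---------------------------------------------------------------------------


class TSSIndex:
    """Sorted TSS positions per chromosome for nearest-gene queries."""

    def __init__(self, catalog: GeneCatalog):
        if len(catalog) == 0:
            raise ValueError("gene catalog is empty")
        self.catalog = catalog
        self._pos: dict[str, np.ndarray] = {}
        self._ids: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[tuple[int, str]]] = {}
        for g in catalog:
            by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            self._pos[chrom] = np.array([p for p, _ in pairs], dtype=np.int64)
            self._ids[chrom] = np.array([i for _, i in pairs], dtype=object)

    def nearest(self, chrom: str, start: int, end: int) -> str:
        """Gene id with nearest TSS: distance 0 if a TSS lies inside [start, end),
        else the gap to the interval edge; ties go to the smallest gene id."""
        if chrom not in self._pos:
            # fall back to global tie rule across all genes at infinite distance
            raise ValueError(f"no genes on chromosome {chrom!r}")
        pos, ids = self._pos[chrom], self._ids[chrom]
        i = np.searchsorted(pos, start, side="left")
        j = np.searchsorted(pos, end, side="left")
        if i < j:  # >=1 TSS inside the interval
            return min(ids[i:j])
        cands: list[tuple[int, str]] = []
        if i > 0:
            d = start - pos[i - 1]
            lo = np.searchsorted(pos, pos[i - 1], side="left")
            cands.extend((d, g) for g in ids[lo:i])
        if i < len(pos):
            d = int(pos[i]) - (end - 1)
            hi = np.searchsorted(pos, pos[i], side="right")
            cands.extend((d, g) for g in ids[i:hi])
        dmin = min(d for d, _ in cands)
        tied = sorted(g for d, g in cands if d == dmin)
        if len(tied) > 1:
            logger.debug("nearest-TSS tie at distance %d: %s", dmin, tied)
        return tied[0]


def assign_te_to_nearest_gene(chrom: str, start: int, end: int, genes: GeneCatalog | TSSIndex) -> str:
    """Nearest-TSS gene for one TE interval (see :meth:`TSSIndex.nearest`)."""
    index = genes if isinstance(genes, TSSIndex) else TSSIndex(genes)
    return index.nearest(chrom, start, end)


def te_gene_assignments(
    catalog: TECatalog,
    region_sets: Sequence[RegionSet],
    genes: GeneCatalog | TSSIndex,
) -> pd.DataFrame:
    """Assign every TE copy overlapping each region set to its nearest gene.

    Returns one row per (copy, region set) with columns copy_index, family,
    te_class, tissue, activity, gene_id. This is the input of
    :func:`categorize_genes`.
    """
    index = genes if isinstance(genes, TSSIndex) else TSSIndex(genes)
    df = catalog.df
    rows = []
    for rs in region_sets:
        regions_by_chrom = rs.merged_by_chrom()
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in regions_by_chrom:
                continue
            r_s, r_e = regions_by_chrom[chrom]
            mask, _ = overlap_any_and_bp(sub["start"].values, sub["end"].values, r_s, r_e)
            for idx, row in zip(sub.index[mask], sub[mask].itertuples(index=False)):
                rows.append(
                    {
                        "copy_index": idx,
                        "family": row.family,
                        "te_class": row.te_class,
                        "tissue": rs.tissue_id,
                        "activity": rs.activity,
                        "gene_id": index.nearest(chrom, int(row.start), int(row.end)),
                    }
                )
    return pd.DataFrame(rows, columns=["copy_index", "family", "te_class", "tissue", "activity", "gene_id"])


def categorize_genes(assignments: pd.DataFrame, gene_catalog: GeneCatalog) -> pd.DataFrame:
    """Four-way TE-association category per gene (partition of the catalog).

    1 = every TE assignment touching the gene is in active regions,
    2 = both activities occur, 3 = repressed only, 4 = no assignment.
    Returns gene_id, category (int), category_label.
    """
    acts: dict[str, set[str]] = {}
    if len(assignments):
        for gene_id, sub in assignments.groupby("gene_id"):
            acts[gene_id] = set(sub["activity"])
    rows = []
    for gene_id in gene_catalog.gene_ids():
        a = acts.get(gene_id, set())
        if not a:
            cat = 4
        elif a == {"active"}:
            cat = 1
        elif a == {"repressed"}:
            cat = 3
        else:
            cat = 2
        rows.append({"gene_id": gene_id, "category": cat, "category_label": CATEGORY_LABELS[cat]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# variance records and covariates
# ---------------------------------------------------------------------------


def normalized_variance(expr: ExpressionMatrix, method: str = "index_of_dispersion") -> pd.DataFrame:
    """Cross-tissue expression variance per gene, normalised by the grand mean.

    ``index_of_dispersion`` (default) is var / mean; ``cv2`` is var / mean^2.
    Genes with grand mean 0 are excluded. Variance is the sample variance
    (ddof=1) over per-tissue mean TPMs.
    """
    if method not in ("index_of_dispersion", "cv2"):
        raise ValueError(f"unknown normalisation {method!r}")
    mean = expr.df.mean(axis=1)
    var = expr.df.var(axis=1, ddof=1)
    keep = mean > 0
    denom = mean[keep] if method == "index_of_dispersion" else mean[keep] ** 2
    return pd.DataFrame(
        {"grand_mean": mean[keep], "variance": var[keep], "normalized_variance": var[keep] / denom}
    )


def gene_densities(catalog: GeneCatalog, genome: GenomeTable | None = None, window: int = DENSITY_WINDOW) -> pd.Series:
    """Exonic bp of the union of all exon blocks within +/- ``window`` of each gene.

    The window spans [gene.start - window, gene.end + window], clipped to the
    chromosome; the gene's own exons are included in the union.
    """
    exons: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in catalog:
        by_chrom.setdefault(g.chrom, []).extend(zip(g.exon_starts, g.exon_ends))
    for chrom, blocks in by_chrom.items():
        arr = np.array(blocks, dtype=np.int64)
        exons[chrom] = merge_intervals(arr[:, 0], arr[:, 1])
    out = {}
    for g in catalog:
        lo = max(0, g.start - window)
        hi = g.end + window
        if genome is not None and g.chrom in genome:
            hi = min(hi, genome.lengths[g.chrom])
        es, ee = exons[g.chrom]
        _, bp = overlap_any_and_bp(np.array([lo]), np.array([hi]), es, ee)
        out[g.gene_id] = int(bp[0])
    return pd.Series(out, name="gene_density")


def gene_density(gene_id: str, catalog: GeneCatalog, genome: GenomeTable | None = None,
                 window: int = DENSITY_WINDOW) -> int:
    """Exonic density of one gene (see :func:`gene_densities`)."""
    return int(gene_densities(catalog, genome, window).loc[gene_id])


def variance_records(
    expr: ExpressionMatrix,
    gene_catalog: GeneCatalog,
    genome: GenomeTable | None = None,
    method: str = "index_of_dispersion",
) -> pd.DataFrame:
    """Per-gene normalised variance with gene_length and gene_density covariates."""
    nv = normalized_variance(expr, method=method)
    dens = gene_densities(gene_catalog, genome)
    rows = []
    for g in gene_catalog:
        if g.gene_id not in nv.index:
            continue
        rows.append(
            {
                "gene_id": g.gene_id,
                "normalized_variance": nv.loc[g.gene_id, "normalized_variance"],
                "gene_length": g.gene_length,
                "gene_density": int(dens.loc[g.gene_id]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparisons and the variance model
# ---------------------------------------------------------------------------


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U): exact for small untied
    samples, otherwise normal approximation with tie and continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # degenerate: every observation tied
        return float(len(x) * len(y) / 2), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto", use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class VarianceAnalysisResult:
    wilcoxon: pd.DataFrame   # one row per group contrast
    ols: pd.DataFrame        # coefficient table: coef, se, p_value
    model: object            # fitted statsmodels results


def variance_category_analysis(
    variance_recs: pd.DataFrame,
    categories: pd.DataFrame,
    log_length: bool = False,
) -> VarianceAnalysisResult:
    """Compare normalised expression variance across the four gene categories.

    Rank-sum contrasts: categories 1 u 2 (TE in active chromatin somewhere)
    vs 3 u 4, and 1 vs 2. OLS: normalized_variance ~ category indicators
    (reference = 4, no TE) + gene_length + gene_density; ``log_length``
    switches the length covariate to log10(bp).
    """
    df = variance_recs.merge(categories, on="gene_id", how="inner")
    populated = df["category"].value_counts()
    if (populated >= 2).sum() < 2:
        raise ValueError("need at least two categories with >= 2 genes")
    small = populated[populated < 2].index.tolist()
    if small:
        logger.warning("categories with < 2 genes dropped from pairwise tests: %s", small)
        pair_df = df[~df["category"].isin(small)]
    else:
        pair_df = df

    nv = "normalized_variance"
    contrasts = []
    g12 = pair_df.loc[pair_df["category"].isin([1, 2]), nv]
    g34 = pair_df.loc[pair_df["category"].isin([3, 4]), nv]
    if len(g12) and len(g34):
        stat, p = rank_sum_test(g12, g34)
        contrasts.append(
            {"contrast": "active_any_vs_rest", "n1": len(g12), "n2": len(g34),
             "median1": g12.median(), "median2": g34.median(), "statistic": stat, "p_value": p}
        )
    g1 = pair_df.loc[pair_df["category"] == 1, nv]
    g2 = pair_df.loc[pair_df["category"] == 2, nv]
    if len(g1) and len(g2):
        stat, p = rank_sum_test(g1, g2)
        contrasts.append(
            {"contrast": "active_only_vs_mixed", "n1": len(g1), "n2": len(g2),
             "median1": g1.median(), "median2": g2.median(), "statistic": stat, "p_value": p}
        )

    length = np.log10(df["gene_length"].to_numpy(dtype=float)) if log_length else df["gene_length"]
    X = pd.DataFrame(
        {
            "cat1": (df["category"] == 1).astype(float),
            "cat2": (df["category"] == 2).astype(float),
            "cat3": (df["category"] == 3).astype(float),
            "gene_length": np.asarray(length, dtype=float),
            "gene_density": df["gene_density"].astype(float),
        }
    )
    X = X.loc[:, (X != X.iloc[0]).any()]  # drop constant (absent-category) columns
    fit = sm.OLS(df[nv].to_numpy(), sm.add_constant(X)).fit()
    ols = pd.DataFrame({"coef": fit.params, "se": fit.bse, "p_value": fit.pvalues})
    return VarianceAnalysisResult(wilcoxon=pd.DataFrame(contrasts), ols=ols, model=fit)


# ---------------------------------------------------------------------------
# tissue expression shifts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShiftResult:
    focal_tissue: str
    n_genes: int
    median_focal: float
    median_other: float
    statistic: float
    p_value: float
    direction: str  # up | down | none


def tissue_expression_shift(
    gene_set: Sequence[str], focal_tissue: str, expr: ExpressionMatrix
) -> ShiftResult:
    """Compare a gene set's TPM in one tissue against its mean over the others.

    For each gene the pair (TPM in the focal tissue, mean TPM across all other
    tissues) is formed; the two value vectors are compared by a two-sided
    rank-sum test. Requires >= 3 genes.
    """
    genes = list(dict.fromkeys(gene_set))
    if len(genes) < 3:
        raise ValueError(f"need >= 3 genes for the shift test, got {len(genes)}")
    missing = set(genes) - set(expr.genes)
    if missing:
        raise ValueError(f"genes not in expression matrix: {sorted(missing)[:5]}")
    if focal_tissue not in expr.tissues:
        raise ValueError(f"unknown tissue {focal_tissue!r}")
    sub = expr.df.loc[genes]
    focal = sub[focal_tissue].to_numpy()
    others = sub.drop(columns=[focal_tissue]).mean(axis=1).to_numpy()
    stat, p = rank_sum_test(focal, others)
    med_f, med_o = float(np.median(focal)), float(np.median(others))
    direction = "up" if med_f > med_o else ("down" if med_f < med_o else "none")
    if p >= 1.0:
        direction = direction if med_f != med_o else "none"
    return ShiftResult(focal_tissue, len(genes), med_f, med_o, float(stat), float(p), direction)
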