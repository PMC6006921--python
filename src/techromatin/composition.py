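"""Genomic typology and composition analyses of enriched TEs.

Typology follows the standard promoter / gene body / intergenic scheme:
an interval overlapping any TSS +/- 1 kb window is a *promoter* hit
(promoter takes precedence); otherwise an interval overlapping a gene is
*gene body*, split into *exon* (>= 1 bp overlap with an exon of the
assigned gene) and *intron*; everything else is *intergenic*. Overlap
always means >= 1 bp; gene attribution uses the nearest TSS, ties broken
by lexicographically smallest gene id.

Statistical tests: per-typology two-sided Fisher exact tests (interest set
vs background), exact binomial "proportion tests" of TE-class composition
against catalog-wide class fractions, and the partition of repressed
chromatin fragments between the two repressive marks (H3K27me3 Polycomb vs
H3K9me3 heterochromatin), with and without the restriction to fragments
containing a TE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from ._intervals import merge_intervals, overlap_any_and_bp
from .chromatin_regions import RegionSet, StateMap, COREMARKS_15, H3K27ME3, H3K9ME3, mark_of_state
from .io_formats import GeneCatalog, TECatalog

logger = logging.getLogger(__name__)

PROMOTER_FLANK = 1000  # bp either side of the TSS, both flanks inclusive

TYPOLOGIES = ("promoter", "gene_body", "intergenic")
TYPOLOGY_TEST_LEVELS = ("promoter", "gene_body", "intergenic", "intron", "exon")


@dataclass(frozen=True)
class TypologyAssignment:
    typology: str          # promoter | gene_body | intergenic
    sub_typology: str      # intron | exon | n/a
    assigned_gene: str | None


class GeneIndex:
    """Interval indexes over a gene catalog for typology queries."""

    def __init__(self, catalog: GeneCatalog, promoter_flank: int = PROMOTER_FLANK):
        self.catalog = catalog
        self.promoter_flank = promoter_flank
        self._promoters: dict[str, IntervalTree] = {}
        self._bodies: dict[str, IntervalTree] = {}
        for idx, g in enumerate(catalog):
            # promoter window [tss - flank, tss + flank] inclusive of both flanks
            lo = max(0, g.tss - promoter_flank)
            self._promoters.setdefault(g.chrom, IntervalTree()).addi(lo, g.tss + promoter_flank + 1, idx)
            self._bodies.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, idx)

    def _nearest(self, hits: Iterable[int], start: int, end: int) -> int:
        """Among candidate gene indexes, the one with the nearest TSS (tie: smallest id)."""
        best = None
        for idx in hits:
            g = self.catalog.genes[idx]
            t = g.tss
            dist = 0 if start <= t < end else (start - t if t < start else t - (end - 1))
            key = (dist, g.gene_id)
            if best is None or key < best[0]:
                best = (key, idx)
        return best[1]

    def assign(self, chrom: str, start: int, end: int) -> TypologyAssignment:
        ptree = self._promoters.get(chrom)
        hits = {iv.data for iv in ptree.overlap(start, end)} if ptree else set()
        if hits:
            g = self.catalog.genes[self._nearest(hits, start, end)]
            return TypologyAssignment("promoter", "n/a", g.gene_id)
        btree = self._bodies.get(chrom)
        hits = {iv.data for iv in btree.overlap(start, end)} if btree else set()
        if hits:
            g = self.catalog.genes[self._nearest(hits, start, end)]
            exonic = any(s < end and start < e for s, e in zip(g.exon_starts, g.exon_ends))
            return TypologyAssignment("gene_body", "exon" if exonic else "intron", g.gene_id)
        return TypologyAssignment("intergenic", "n/a", None)


def assign_typology(chrom: str, start: int, end: int, genes: GeneCatalog | GeneIndex) -> TypologyAssignment:
    """Typology of one interval (promoter precedence; see module docstring)."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return index.assign(chrom, start, end)


def assign_typologies(intervals: pd.DataFrame, genes: GeneCatalog | GeneIndex) -> pd.DataFrame:
    """Typology of every interval in a frame with chrom/start/end columns.

    Returns the input columns plus typology, sub_typology, assigned_gene.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    rows = [index.assign(r.chrom, int(r.start), int(r.end)) for r in intervals.itertuples(index=False)]
    out = intervals.reset_index(drop=True).copy()
    out["typology"] = [a.typology for a in rows]
    out["sub_typology"] = [a.sub_typology for a in rows]
    out["assigned_gene"] = [a.assigned_gene for a in rows]
    return out


def _level_counts(assignments: pd.DataFrame, level: str) -> int:
    if level in ("intron", "exon"):
        return int((assignments["sub_typology"] == level).sum())
    return int((assignments["typology"] == level).sum())


def typology_enrichment(
    assignments_of_interest: pd.DataFrame, background_assignments: pd.DataFrame
) -> pd.DataFrame:
    """Two-sided Fisher exact tests per typology level: interest set vs background.

    For each level T the 2x2 table is [interest, background] x [T, not T].
    Levels empty in both sets are skipped. A zero margin yields p = 1 and an
    undefined odds ratio (NaN).
    """
    if assignments_of_interest.empty or background_assignments.empty:
        raise ValueError("both assignment sets must be nonempty")
    n1, n2 = len(assignments_of_interest), len(background_assignments)
    rows = []
    for level in TYPOLOGY_TEST_LEVELS:
        k1 = _level_counts(assignments_of_interest, level)
        k2 = _level_counts(background_assignments, level)
        if k1 == 0 and k2 == 0:
            logger.warning("typology level %r empty in both sets; skipped", level)
            continue
        table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            odds, p = np.nan, 1.0
        else:
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            if not np.isfinite(odds):
                odds = np.nan
        rows.append(
            {
                "typology": level,
                "k_interest": k1, "n_interest": n1,
                "k_background": k2, "n_background": n2,
                "odds_ratio": odds, "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def class_composition_test(enriched_families: Sequence[str], catalog: TECatalog) -> pd.DataFrame:
    """Exact binomial proportion tests of TE-class composition among enriched families.

    For each class c: k = enriched families of class c, n = all enriched
    families, p0 = fraction of annotated families (catalog-wide) of class c.
    Two-sided exact binomial p, plus the normal-approximation proportion-test
    p for comparison.
    """
    fam_class = catalog.df.drop_duplicates("family").set_index("family")["te_class"]
    unknown = set(enriched_families) - set(fam_class.index)
    if unknown:
        raise ValueError(f"enriched families not in catalog: {sorted(unknown)[:5]}")
    n = len(set(enriched_families))
    if n == 0:
        return pd.DataFrame(
            columns=["te_class", "k", "n", "p0", "estimate", "p_value", "p_normal"]
        )
    enriched_classes = fam_class.loc[sorted(set(enriched_families))]
    rows = []
    for klass, n_families in fam_class.value_counts().sort_index().items():
        p0 = n_families / len(fam_class)
        k = int((enriched_classes == klass).sum())
        if k == 0 and n_families == 0:
            continue
        p = stats.binomtest(k, n, p0, alternative="two-sided").pvalue
        se = np.sqrt(p0 * (1 - p0) / n)
        z = (k / n - p0) / se if se > 0 else 0.0
        rows.append(
            {
                "te_class": klass, "k": k, "n": n, "p0": p0, "estimate": k / n,
                "p_value": p, "p_normal": 2 * stats.norm.sf(abs(z)),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MarkPartition:
    """Counts of repressed fragments by repressive mark for one tissue.

    When the partition is restricted to TE-containing fragments,
    ``baseline_fraction_k27`` holds the unrestricted fraction and ``p_value``
    the two-sided binomial test of the restricted fraction against it.
    """

    tissue_id: str
    n_k27: int
    n_k9: int
    baseline_fraction_k27: float | None = None
    p_value: float | None = None

    @property
    def fraction_k27(self) -> float:
        return self.n_k27 / (self.n_k27 + self.n_k9)


def repression_mark_partition(
    repressed: RegionSet,
    te_catalog: TECatalog | None = None,
    state_map: StateMap = COREMARKS_15,
) -> MarkPartition:
    """Partition repressed fragments between H3K27me3 and H3K9me3.

    With ``te_catalog`` given, only fragments overlapping >= 1 TE copy by
    >= 1 bp are counted, and the restricted H3K27me3 fraction is tested
    (two-sided binomial) against the unrestricted fraction as null.
    """
    frags = repressed.fragments.reset_index(drop=True)
    if frags.empty:
        raise ValueError("no repressed fragments")
    marks = frags["state"].map(lambda s: mark_of_state(s, state_map)).to_numpy()
    all_k27 = int((marks == H3K27ME3).sum())
    all_k9 = int((marks == H3K9ME3).sum())
    if te_catalog is None:
        return MarkPartition(repressed.tissue_id, all_k27, all_k9)

    te_by_chrom = {
        chrom: merge_intervals(sub["start"].values, sub["end"].values)
        for chrom, sub in te_catalog.df.groupby("chrom", sort=False)
    }
    has_te = np.zeros(len(frags), dtype=bool)
    for chrom, sub in frags.groupby("chrom", sort=False):
        if chrom in te_by_chrom:
            ts, te_ = te_by_chrom[chrom]
            m, _ = overlap_any_and_bp(sub["start"].values, sub["end"].values, ts, te_)
            has_te[sub.index] = m
    sel = marks[has_te]
    n_k27 = int((sel == H3K27ME3).sum())
    n_k9 = int((sel == H3K9ME3).sum())
    p0 = all_k27 / (all_k27 + all_k9)
    n_sel = n_k27 + n_k9
    p = stats.binomtest(n_k27, n_sel, p0, alternative="two-sided").pvalue if n_sel else 1.0
    return MarkPartition(repressed.tissue_id, n_k27, n_k9, baseline_fraction_k27=p0, p_value=p)


def class_by_mark_association(
    te_catalog: TECatalog,
    repressed: RegionSet,
    state_map: StateMap = COREMARKS_15,
) -> pd.DataFrame:
    """Per-class Fisher tests of association between TE class and repressive mark.

    The counting unit is a TE copy overlapping a repressed fragment; for each
    class c the 2x2 table is [class c, other classes] x [H3K9me3, H3K27me3].
    Copies overlapping fragments of both marks count once in each mark
    category (the duplication rate is logged).
    """
    frags = repressed.fragments.reset_index(drop=True)
    if frags.empty:
        raise ValueError("no repressed fragments")
    marks = frags["state"].map(lambda s: mark_of_state(s, state_map))
    mark_regions = {}
    for mark in (H3K27ME3, H3K9ME3):
        sub = frags[marks == mark]
        mark_regions[mark] = {
            chrom: merge_intervals(g["start"].values, g["end"].values)
            for chrom, g in sub.groupby("chrom", sort=False)
        }
    df = te_catalog.df
    touch = {}
    for mark, regions in mark_regions.items():
        hit = np.zeros(len(df), dtype=bool)
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom in regions:
                rs, re = regions[chrom]
                m, _ = overlap_any_and_bp(sub["start"].values, sub["end"].values, rs, re)
                hit[sub.index] = m
        touch[mark] = hit
    any_hit = touch[H3K27ME3] | touch[H3K9ME3]
    if not any_hit.any():
        raise ValueError("no TE copies overlap repressed fragments")
    both = touch[H3K27ME3] & touch[H3K9ME3]
    if both.any():
        logger.info(
            "%.2f%% of repressed-overlapping copies touch both marks and are counted once per mark",
            100 * both.sum() / any_hit.sum(),
        )
    counts = pd.DataFrame(
        {
            "te_class": np.concatenate([df.loc[touch[H3K9ME3], "te_class"], df.loc[touch[H3K27ME3], "te_class"]]),
            "mark": [H3K9ME3] * int(touch[H3K9ME3].sum()) + [H3K27ME3] * int(touch[H3K27ME3].sum()),
        }
    )
    tab = counts.groupby(["te_class", "mark"]).size().unstack(fill_value=0)
    for mark in (H3K9ME3, H3K27ME3):
        if mark not in tab:
            tab[mark] = 0
    rows = []
    for klass in tab.index:
        a = int(tab.loc[klass, H3K9ME3])
        b = int(tab.loc[klass, H3K27ME3])
        c = int(tab[H3K9ME3].sum() - a)
        d = int(tab[H3K27ME3].sum() - b)
        table = np.array([[a, b], [c, d]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            odds, p = np.nan, 1.0
        else:
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            if not np.isfinite(odds):
                odds = np.inf
        rows.append(
            {"te_class": klass, "n_k9": a, "n_k27": b, "other_k9": c, "other_k27": d,
             "odds_ratio": odds, "p_value": p}
        )
    return pd.DataFrame(rows)
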