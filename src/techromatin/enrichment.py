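"""Shuffle-based permutation tests for TE enrichment in chromatin region sets.

For each TE grouping (family, class or age class) the observed number of
copies overlapping a region set by >= 1 bp is compared with the distribution
of the same count over ``n_reps`` randomisations of the catalog. Two
randomisation modes are provided:

* ``positional`` (default): every copy is independently re-placed uniformly
  on its own chromosome, preserving its length; overlaps among shuffled
  copies are allowed.
* ``label_permutation``: positions stay fixed and the (family, class, age)
  labels are permuted uniformly among copies.

Both preserve, per chromosome, the multiset of copy lengths. The empirical
two-tailed p-value uses the add-one rule, ``p = min(1, 2 * min(tails))``
with each tail ``(#{exp as extreme} + 1) / (n_reps + 1)``, so p is never 0
and the test is valid at finite ``n_reps``. The odds ratio is defined as
observed count / mean expected count. Benjamini-Hochberg FDR is applied
across the groups tested in one run (one tissue, one activity class).

Randomness: one master seed; each replicate draws from an independent
substream spawned from the master generator's seed sequence, so results are
reproducible and independent of execution order. The catalog is canonically
sorted before substreams are assigned, so p-values do not depend on the row
order of the input files.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._intervals import overlap_any_and_bp, merge_intervals
from .io_formats import GenomeTable, TECatalog, ValidationError

logger = logging.getLogger(__name__)

MODES = ("positional", "label_permutation")
GROUP_COLUMNS = {"family": "family", "age_class": "age_class", "te_class": "te_class"}

#: default lineage ordering, oldest to youngest, for the two-level age summary
DEFAULT_LINEAGE_ORDER = (
    "Vertebrata", "Gnathostomata", "Tetrapoda", "Amniota", "Mammalia", "Theria",
    "Eutheria", "Boreoeutheria", "Euarchontoglires", "Primates", "Haplorrhini",
    "Simiiformes", "Catarrhini", "Hominoidea", "Hominidae", "Homininae", "Homo",
)

ENRICHMENT_COLUMNS = [
    "tissue", "activity", "key", "obs_count", "obs_bp", "exp_mean", "exp_sd",
    "odds_ratio", "p_value", "q_value", "direction", "n_reps", "mode",
]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in ("chrom", "start", "end", "family", "te_class", "age_class") if c in df]
    return df.sort_values(cols, kind="stable").reset_index(drop=True)


def _chrom_slices(df: pd.DataFrame) -> list[tuple[str, slice]]:
    """Contiguous row slices per chromosome of a canonically sorted frame."""
    chroms = df["chrom"].values
    bounds = np.flatnonzero(np.concatenate(([True], chroms[1:] != chroms[:-1])))
    bounds = np.append(bounds, len(chroms))
    return [(chroms[bounds[i]], slice(bounds[i], bounds[i + 1])) for i in range(len(bounds) - 1)]


def _overlap(starts, ends, slices, regions_by_chrom):
    n = len(starts)
    mask = np.zeros(n, dtype=bool)
    bp = np.zeros(n, dtype=np.int64)
    for chrom, sl in slices:
        reg = regions_by_chrom.get(chrom)
        if reg is None:
            continue
        m, b = overlap_any_and_bp(starts[sl], ends[sl], reg[0], reg[1])
        mask[sl] = m
        bp[sl] = b
    return mask, bp


def count_overlaps(catalog: TECatalog, regions, group_by: str = "family") -> pd.DataFrame:
    """Per-group overlap counts against a (merged) region set.

    Returns one row per group present in the catalog with columns ``key``,
    ``n_copies_overlapping`` (distinct copies with >= 1 bp overlap, each
    counted once even when it spans several regions) and ``bp_overlapping``.
    ``regions`` is a :class:`~techromatin.chromatin_regions.RegionSet` or a
    mapping chrom -> (starts, ends) of merged intervals.
    """
    group_col = GROUP_COLUMNS[group_by]
    df = _canonical(catalog.df)
    regions_by_chrom = regions if isinstance(regions, dict) else regions.merged_by_chrom()
    keys = np.sort(df[group_col].unique())
    codes = pd.Categorical(df[group_col], categories=keys).codes.astype(np.int64)
    mask, bp = _overlap(df["start"].values, df["end"].values, _chrom_slices(df), regions_by_chrom)
    counts = np.bincount(codes[mask], minlength=len(keys))
    bp_sum = np.bincount(codes, weights=bp, minlength=len(keys)).astype(np.int64)
    return pd.DataFrame(
        {"key": keys, "n_copies_overlapping": counts, "bp_overlapping": bp_sum}
    )


def shuffle_te_positions(
    catalog: TECatalog,
    genome: GenomeTable,
    rng,
    mode: str = "positional",
    exclude: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> TECatalog:
    """One randomisation of the catalog (see module docstring for modes).

    ``exclude`` is an optional mapping chrom -> merged (starts, ends) of
    regions (e.g. assembly gaps) that positional placements must not touch;
    placements are rejection-sampled against it.
    """
    if mode not in MODES:
        raise ValueError(f"unknown shuffle mode {mode!r}")
    rng = _as_rng(rng)
    df = _canonical(catalog.df)
    if mode == "label_permutation":
        perm = rng.permutation(len(df))
        out = df.copy()
        out[["family", "te_class", "age_class"]] = (
            df[["family", "te_class", "age_class"]].iloc[perm].to_numpy()
        )
        return catalog.with_df(out)

    out = df.copy()
    starts = np.empty(len(df), dtype=np.int64)
    for chrom, sl in _chrom_slices(df):
        if chrom not in genome:
            raise ValidationError(f"catalog chromosome {chrom!r} not in genome table")
        L = genome.lengths[chrom]
        lens = (df["end"].values[sl] - df["start"].values[sl])
        if (lens > L).any():
            raise ValidationError(f"TE copy longer than chromosome {chrom!r}")
        s = rng.integers(0, L - lens + 1)
        if exclude and chrom in exclude:
            ex_s, ex_e = exclude[chrom]
            for _ in range(1000):
                bad, _bp = overlap_any_and_bp(s, s + lens, ex_s, ex_e)
                if not bad.any():
                    break
                s[bad] = rng.integers(0, L - lens[bad] + 1)
            else:
                raise ValidationError(f"could not place copies outside excluded regions on {chrom}")
        starts[sl] = s
    out["start"] = starts
    out["end"] = starts + (df["end"].values - df["start"].values)
    return catalog.with_df(out)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, clipped to (0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def permutation_enrichment(
    catalog: TECatalog,
    regions,
    genome: GenomeTable,
    n_reps: int,
    rng,
    group_by: str = "family",
    mode: str = "positional",
    exclude: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> pd.DataFrame:
    """Observed vs shuffled overlap counts per group, with empirical p and BH q.

    Returns a DataFrame with one row per group (columns
    :data:`ENRICHMENT_COLUMNS`): observed copy count and bp, mean and sample
    sd of the shuffled counts, odds ratio obs/exp_mean (NaN when
    exp_mean = 0), the two-tailed add-one empirical p-value, the BH q-value
    across the groups of this run, and the direction of the deviation.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if mode not in MODES:
        raise ValueError(f"unknown shuffle mode {mode!r}")
    rng = _as_rng(rng)
    group_col = GROUP_COLUMNS[group_by]
    df = _canonical(catalog.df)
    tissue = getattr(regions, "tissue_id", "")
    activity = getattr(regions, "activity", "")
    regions_by_chrom = regions if isinstance(regions, dict) else regions.merged_by_chrom()

    keys = np.sort(df[group_col].unique())
    k = len(keys)
    codes = pd.Categorical(df[group_col], categories=keys).codes.astype(np.int64)
    slices = _chrom_slices(df)
    starts = df["start"].values
    lens = df["end"].values - starts
    for chrom, sl in slices:
        if chrom not in genome:
            raise ValidationError(f"catalog chromosome {chrom!r} not in genome table")
        if (lens[sl] > genome.lengths[chrom]).any():
            raise ValidationError(f"TE copy longer than chromosome {chrom!r}")

    obs_mask, obs_bp = _overlap(starts, starts + lens, slices, regions_by_chrom)
    obs = np.bincount(codes[obs_mask], minlength=k)
    obs_bp_group = np.bincount(codes, weights=obs_bp, minlength=k).astype(np.int64)

    children = rng.spawn(n_reps)
    exp = np.empty((n_reps, k), dtype=np.int64)
    new_starts = np.empty_like(starts)
    for r, child in enumerate(children):
        if mode == "positional":
            for chrom, sl in slices:
                L = genome.lengths[chrom]
                s = child.integers(0, L - lens[sl] + 1)
                if exclude and chrom in exclude:
                    ex_s, ex_e = exclude[chrom]
                    for _ in range(1000):
                        bad, _ = overlap_any_and_bp(s, s + lens[sl], ex_s, ex_e)
                        if not bad.any():
                            break
                        s[bad] = child.integers(0, L - lens[sl][bad] + 1)
                new_starts[sl] = s
            mask, _ = _overlap(new_starts, new_starts + lens, slices, regions_by_chrom)
            exp[r] = np.bincount(codes[mask], minlength=k)
        else:
            exp[r] = np.bincount(codes[child.permutation(len(df))][obs_mask], minlength=k)

    exp_mean = exp.mean(axis=0)
    exp_sd = exp.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(k)
    c_ge = (exp >= obs).sum(axis=0)
    c_le = (exp <= obs).sum(axis=0)
    p = np.minimum(
        1.0, 2.0 * np.minimum(c_ge + 1, c_le + 1) / (n_reps + 1)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.where(exp_mean > 0, obs / np.where(exp_mean > 0, exp_mean, 1.0), np.nan)
    direction = np.where(obs > exp_mean, "enriched", np.where(obs < exp_mean, "depleted", "none"))

    out = pd.DataFrame(
        {
            "tissue": tissue,
            "activity": activity,
            "key": keys,
            "obs_count": obs,
            "obs_bp": obs_bp_group,
            "exp_mean": exp_mean,
            "exp_sd": exp_sd,
            "odds_ratio": odds,
            "p_value": p,
            "q_value": bh_fdr(p),
            "direction": direction,
            "n_reps": n_reps,
            "mode": mode,
        }
    )
    return out


def age_class_enrichment(
    catalog: TECatalog,
    regions,
    genome: GenomeTable,
    n_reps: int,
    rng,
    mode: str = "positional",
    lineage_order: Sequence[str] = DEFAULT_LINEAGE_ORDER,
    split_at: str = "Eutheria",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Permutation enrichment of TE age classes, plus a two-level summary.

    Runs the same machinery as :func:`permutation_enrichment` grouped by
    ``age_class``, and additionally tests two macro classes: *ancient*
    (``split_at`` and everything older in ``lineage_order``) vs *young*
    (everything younger). Age classes absent from ``lineage_order``
    (including "unknown") are grouped under "unknown" in the summary.

    Returns ``(per_age_class, two_level_summary)``.
    """
    rng = _as_rng(rng)
    per_class = permutation_enrichment(
        catalog, regions, genome, n_reps, rng.spawn(1)[0], group_by="age_class", mode=mode
    )
    order = {name: i for i, name in enumerate(lineage_order)}
    if split_at not in order:
        raise ValueError(f"split_at {split_at!r} not in lineage_order")
    cut = order[split_at]

    def macro(age: str) -> str:
        if age not in order:
            return "unknown"
        return "ancient" if order[age] <= cut else "young"

    macro_df = catalog.df.copy()
    macro_df["age_class"] = macro_df["age_class"].map(macro)
    summary = permutation_enrichment(
        catalog.with_df(macro_df), regions, genome, n_reps, rng.spawn(1)[0],
        group_by="age_class", mode=mode,
    )
    return per_class, summary


def read_exclude_bed(path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read a BED3+ of regions to exclude from shuffled placement, merged per chromosome."""
    from .io_formats import _open_text

    rows = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2])))
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    for chrom, sub in df.groupby("chrom", sort=False):
        out[chrom] = merge_intervals(sub["start"].values, sub["end"].values)
    return out
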