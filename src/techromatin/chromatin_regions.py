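"""Activity classification of chromHMM states and per-tissue region sets.

The 15-state chromHMM coreMarks vocabulary is partitioned into *active*
states (driven by H3K4me1 / H3K4me3 / H3K36me3: promoters, transcription,
enhancers, plus the bivalent TssBiv/EnhBiv states), *repressed* states
(H3K27me3 Polycomb: ReprPC, ReprPCWk; H3K9me3 heterochromatin: Het) and
everything else (*neither*: ZNF/Rpts, BivFlnk, Quies). The mapping is
configurable so other chromHMM models can be plugged in.

A :class:`RegionSet` keeps two views of the same regions: the labelled
*fragments* (each carrying the chromHMM state it came from, needed to
partition repressed chromatin by repressive mark) and the *merged* union
(used by overlap counting, so a TE spanning two abutting active states is
counted once).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._intervals import merge_intervals
from .io_formats import Segmentation, ValidationError

logger = logging.getLogger(__name__)

ACTIVE = "active"
REPRESSED = "repressed"
NEITHER = "neither"

H3K27ME3 = "H3K27me3"
H3K9ME3 = "H3K9me3"


@dataclass(frozen=True)
class StateMap:
    """Mapping from chromHMM state mnemonics to activity classes and repressive marks."""

    active: frozenset[str]
    repressed: frozenset[str]
    marks: Mapping[str, str]  # repressed state -> H3K27me3 | H3K9me3

    def __post_init__(self):
        both = self.active & self.repressed
        if both:
            raise ValidationError(f"states in both activity classes: {sorted(both)}")
        missing = self.repressed - set(self.marks)
        if missing:
            raise ValidationError(f"repressed states without a mark: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path) -> "StateMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(frozenset(raw["active"]), frozenset(raw["repressed"]), dict(raw["marks"]))


#: chromHMM coreMarks 15-state model, the default vocabulary.
COREMARKS_15 = StateMap(
    active=frozenset(
        ["TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "TssBiv", "EnhBiv"]
    ),
    repressed=frozenset(["Het", "ReprPC", "ReprPCWk"]),
    marks={"Het": H3K9ME3, "ReprPC": H3K27ME3, "ReprPCWk": H3K27ME3},
)


def classify_state(state_label: str, state_map: StateMap = COREMARKS_15) -> str:
    """Classify a chromHMM state mnemonic as active / repressed / neither."""
    if state_label in state_map.active:
        return ACTIVE
    if state_label in state_map.repressed:
        return REPRESSED
    if state_label not in ("Quies", "ZNF/Rpts", "BivFlnk"):
        logger.debug("state %r not in the activity map; classified as neither", state_label)
    return NEITHER


def mark_of_state(state_label: str, state_map: StateMap = COREMARKS_15) -> str:
    """Repressive histone mark behind a repressed state (Het -> H3K9me3, ReprPC* -> H3K27me3)."""
    if classify_state(state_label, state_map) != REPRESSED:
        raise ValueError(f"state {state_label!r} is not a repressed state")
    return state_map.marks[state_label]


@dataclass
class RegionSet:
    """Regions of one activity class for one tissue.

    ``fragments`` carries one row per source segment (chrom, start, end,
    state); ``merged`` (when built with merge=True) is the sorted union per
    chromosome, abutting and overlapping fragments coalesced.
    """

    tissue_id: str
    activity: str
    fragments: pd.DataFrame
    merged: pd.DataFrame | None = None

    @property
    def total_bp(self) -> int:
        df = self.merged if self.merged is not None else self.fragments
        return int((df["end"] - df["start"]).sum())

    @property
    def n_regions(self) -> int:
        df = self.merged if self.merged is not None else self.fragments
        return len(df)

    def merged_by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome merged (starts, ends) arrays for overlap kernels."""
        df = self.merged
        if df is None:
            out = {}
            for chrom, sub in self.fragments.groupby("chrom", sort=False):
                out[chrom] = merge_intervals(sub["start"].values, sub["end"].values)
            return out
        return {
            chrom: (sub["start"].values.astype(np.int64), sub["end"].values.astype(np.int64))
            for chrom, sub in df.groupby("chrom", sort=False)
        }


def extract_regions(
    segmentation: Segmentation,
    activity: str,
    tissue_id: str = "",
    merge: bool = True,
    state_map: StateMap = COREMARKS_15,
) -> RegionSet:
    """Filter a segmentation to one activity class, optionally merging intervals.

    Fragments always retain their source state label; when ``merge`` is true
    a merged union view is attached (total_bp then equals the measure of the
    union of the filtered fragments).
    """
    if activity not in (ACTIVE, REPRESSED):
        raise ValueError(f"activity must be {ACTIVE!r} or {REPRESSED!r}, got {activity!r}")
    df = segmentation.df
    keep = df["state"].map(lambda s: classify_state(s, state_map)) == activity
    fragments = df.loc[keep].reset_index(drop=True)
    merged = None
    if merge:
        parts = []
        for chrom, sub in fragments.groupby("chrom", sort=False):
            s, e = merge_intervals(sub["start"].values, sub["end"].values)
            parts.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
        merged = (
            pd.concat(parts, ignore_index=True)
            if parts
            else pd.DataFrame(columns=["chrom", "start", "end"])
        )
    return RegionSet(tissue_id=tissue_id, activity=activity, fragments=fragments, merged=merged)


def write_region_bed(regions: RegionSet, path) -> None:
    """BED4 of the labelled fragments (chrom, start, end, source state)."""
    from .io_formats import _open_text

    with _open_text(path, "wt") as fh:
        for r in regions.fragments.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.state}\n")


def load_region_bed(path, tissue_id: str, activity: str) -> RegionSet:
    """Rebuild a RegionSet from a BED4 written by :func:`write_region_bed`."""
    from .io_formats import read_segmentation

    seg = read_segmentation(path)
    fragments = seg.df
    parts = []
    for chrom, sub in fragments.groupby("chrom", sort=False):
        s, e = merge_intervals(sub["start"].values, sub["end"].values)
        parts.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e}))
    merged = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    return RegionSet(tissue_id=tissue_id, activity=activity, fragments=fragments, merged=merged)


def region_summary(region_sets: list[RegionSet]) -> pd.DataFrame:
    """One row per (tissue, activity): number of merged regions and union bp."""
    rows = [
        {
            "tissue": rs.tissue_id,
            "activity": rs.activity,
            "n_regions": rs.n_regions,
            "total_bp": rs.total_bp,
        }
        for rs in region_sets
    ]
    return pd.DataFrame(rows)
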