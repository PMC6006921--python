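"""Vectorised interval kernels shared across the package.

All coordinates are 0-based half-open. Functions here operate on numpy
arrays for a single chromosome; callers are responsible for grouping by
chromosome. Regions passed to the overlap kernels must be merged (sorted,
pairwise disjoint) — the merge itself is provided here too.
"""

from __future__ import annotations

import numpy as np

__all__ = ["merge_intervals", "union_length", "overlap_any_and_bp"]


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of intervals on one chromosome.

    Abutting intervals (end == next start) are coalesced. Returns sorted,
    pairwise-disjoint (starts, ends).
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts.copy(), ends.copy()
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    # running max of ends; a new block starts where start > max(end) so far
    run_end = np.maximum.accumulate(e)
    new_block = np.empty(s.size, dtype=bool)
    new_block[0] = True
    new_block[1:] = s[1:] > run_end[:-1]
    block = np.cumsum(new_block) - 1
    out_s = s[new_block]
    out_e = np.maximum.reduceat(e, np.flatnonzero(new_block))
    del block
    return out_s, out_e


def union_length(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total bp covered by the union of the intervals."""
    s, e = merge_intervals(starts, ends)
    return int(np.sum(e - s))


def overlap_any_and_bp(
    q_starts: np.ndarray,
    q_ends: np.ndarray,
    r_starts: np.ndarray,
    r_ends: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per query interval: does it overlap the merged region set, and by how many bp.

    ``r_starts``/``r_ends`` must be merged (sorted, disjoint). Runs in
    O((n + m) log m) via binary search and prefix sums.

    Returns (any_overlap: bool[n], bp: int64[n]).
    """
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    r_starts = np.asarray(r_starts, dtype=np.int64)
    r_ends = np.asarray(r_ends, dtype=np.int64)
    n = q_starts.size
    if n == 0 or r_starts.size == 0:
        return np.zeros(n, dtype=bool), np.zeros(n, dtype=np.int64)

    # regions strictly left of the query: r_end <= q_start
    lo = np.searchsorted(r_ends, q_starts, side="right")
    # regions starting before the query end: r_start < q_end
    hi = np.searchsorted(r_starts, q_ends, side="left")
    any_ov = hi > lo

    cum = np.concatenate(([0], np.cumsum(r_ends - r_starts)))
    bp = np.zeros(n, dtype=np.int64)
    if any_ov.any():
        l = lo[any_ov]
        h = hi[any_ov]
        total = cum[h] - cum[l]
        # clip the flanking regions to the query bounds
        left_trim = np.maximum(0, q_starts[any_ov] - r_starts[l])
        right_trim = np.maximum(0, r_ends[h - 1] - q_ends[any_ov])
        bp[any_ov] = total - left_trim - right_trim
    return any_ov, bp
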