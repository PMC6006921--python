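import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from techromatin.io_formats import GenomeTable, TECatalog, TE_COLUMNS
from techromatin.synthetic_data import SimulationConfig, simulate_dataset

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_genome():
    return GenomeTable({"chr1": 10_000, "chr2": 5_000})


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated dataset shared by read-only tests."""
    cfg = SimulationConfig(seed=11, chrom_length=1_000_000)
    return simulate_dataset(cfg)


def make_catalog(rows, genome=None):
    """Catalog from (chrom, start, end, family[, te_class[, age]]) tuples."""
    full = []
    for r in rows:
        chrom, start, end, family = r[:4]
        klass = r[4] if len(r) > 4 else "SINE"
        age = r[5] if len(r) > 5 else "Eutheria"
        full.append((chrom, start, end, family, klass, "+", age))
    return TECatalog(pd.DataFrame(full, columns=TE_COLUMNS), genome)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_overlaps(te_df, regions_by_chrom):
    """All-pairs O(n*m) overlap oracle: per TE row, any-overlap and clipped bp."""
    any_ov = np.zeros(len(te_df), dtype=bool)
    bp = np.zeros(len(te_df), dtype=np.int64)
    for i, row in enumerate(te_df.itertuples(index=False)):
        reg = regions_by_chrom.get(row.chrom)
        if reg is None:
            continue
        for rs, re in zip(*reg):
            lo, hi = max(row.start, rs), min(row.end, re)
            if lo < hi:
                any_ov[i] = True
                bp[i] += hi - lo
    return any_ov, bp


def bitmask_union_bp(intervals, length):
    """Per-base bitmask oracle for the measure of a union of intervals."""
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return int(mask.sum())
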