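import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from techromatin import enrichment as enr
from techromatin._intervals import merge_intervals
from techromatin.io_formats import GenomeTable

from conftest import brute_force_overlaps, make_catalog


def regions_dict(intervals_by_chrom):
    return {
        chrom: merge_intervals(np.array([s for s, _ in ivs]), np.array([e for _, e in ivs]))
        for chrom, ivs in intervals_by_chrom.items()
    }


class TestCountOverlaps:
    def test_single_intersection(self):
        cat = make_catalog([("chr1", 100, 200, "A")])
        res = enr.count_overlaps(cat, regions_dict({"chr1": [(150, 160)]}))
        assert res.iloc[0]["n_copies_overlapping"] == 1
        assert res.iloc[0]["bp_overlapping"] == 10

    def test_copy_spanning_two_regions_counted_once(self):
        cat = make_catalog([("chr1", 100, 200, "A")])
        res = enr.count_overlaps(cat, regions_dict({"chr1": [(90, 110), (190, 210)]}))
        assert res.iloc[0]["n_copies_overlapping"] == 1
        assert res.iloc[0]["bp_overlapping"] == 20

    @given(st.integers(0, 2_000_000_000))
    @settings(max_examples=30)
    def test_matches_brute_force_oracle(self, seed):
        """Random instances agree exactly with the all-pairs O(n*m) oracle."""
        rng = np.random.default_rng(seed)
        n, m = rng.integers(1, 300, size=2)
        chroms = np.array(["chr1", "chr2"])
        te = pd.DataFrame(
            {
                "chrom": chroms[rng.integers(0, 2, n)],
                "start": rng.integers(0, 9_000, n),
                "family": [f"F{i % 7}" for i in range(n)],
            }
        )
        te["end"] = te["start"] + rng.integers(1, 1_000, n)
        regions = {}
        for chrom in chroms:
            rs = rng.integers(0, 9_500, m)
            regions[chrom] = merge_intervals(rs, rs + rng.integers(1, 500, m))
        cat = make_catalog(list(te[["chrom", "start", "end", "family"]].itertuples(index=False)))
        res = enr.count_overlaps(cat, regions).set_index("key")
        df = cat.df.sort_values(["chrom", "start", "end", "family"], kind="stable")
        any_ov, bp = brute_force_overlaps(df, regions)
        expect = (
            pd.DataFrame({"family": df["family"].values, "hit": any_ov, "bp": bp})
            .groupby("family")
            .agg(n=("hit", "sum"), bp=("bp", "sum"))
        )
        for fam, row in expect.iterrows():
            assert res.loc[fam, "n_copies_overlapping"] == row["n"]
            assert res.loc[fam, "bp_overlapping"] == row["bp"]


class TestShuffle:
    def test_degenerate_full_length_copy_always_at_zero(self):
        genome = GenomeTable({"chr1": 100})
        cat = make_catalog([("chr1", 0, 100, "A")])
        for seed in range(5):
            sh = enr.shuffle_te_positions(cat, genome, seed)
            assert sh.df.iloc[0]["start"] == 0

    def test_copy_longer_than_chromosome_errors(self):
        genome = GenomeTable({"chr1": 50})
        cat = make_catalog([("chr1", 0, 100, "A")])
        # catalog construction against the genome already rejects this; unbound
        # catalogs are caught at shuffle time
        with pytest.raises(Exception):
            enr.shuffle_te_positions(make_catalog([("chr1", 0, 100, "A")]), genome, 0)

    def test_label_permutation_single_copy_identity(self):
        genome = GenomeTable({"chr1": 1000})
        cat = make_catalog([("chr1", 10, 20, "A")])
        sh = enr.shuffle_te_positions(cat, genome, 3, mode="label_permutation")
        pd.testing.assert_frame_equal(sh.df, cat.df)

    def test_positional_start_distribution_uniform(self):
        """10 bp copy on a 1 kb chromosome: empirical starts uniform over 0..990."""
        genome = GenomeTable({"chr1": 1_000})
        # 10,000 identical copies: one shuffle call places each independently
        cat = make_catalog([("chr1", 0, 10, "A")] * 10_000)
        starts = enr.shuffle_te_positions(cat, genome, 12345).df["start"].to_numpy()
        assert starts.min() >= 0 and starts.max() <= 990
        counts, _ = np.histogram(starts, bins=np.linspace(0, 991, 12))
        p = stats.chisquare(counts).pvalue
        assert p > 0.001

    def test_preserves_lengths_and_family_counts_per_chromosome(self):
        genome = GenomeTable({"chr1": 10_000, "chr2": 5_000})
        rng = np.random.default_rng(9)
        rows = [
            (f"chr{rng.integers(1, 3)}", s := int(rng.integers(0, 4_000)), s + int(rng.integers(1, 500)),
             f"F{rng.integers(0, 4)}")
            for _ in range(200)
        ]
        cat = make_catalog(rows)
        for mode in enr.MODES:
            sh = enr.shuffle_te_positions(cat, genome, 7, mode=mode)
            for chrom in ("chr1", "chr2"):
                a = cat.df[cat.df.chrom == chrom]
                b = sh.df[sh.df.chrom == chrom]
                assert sorted(a.end - a.start) == sorted(b.end - b.start)
            assert cat.df["family"].value_counts().equals(sh.df["family"].value_counts())

    def test_excluded_regions_never_hit(self):
        genome = GenomeTable({"chr1": 10_000})
        cat = make_catalog([("chr1", 0, 100, "A")] * 50)
        exclude = {"chr1": (np.array([2_000]), np.array([8_000]))}
        sh = enr.shuffle_te_positions(cat, genome, 5, exclude=exclude)
        assert not ((sh.df["start"] < 8_000) & (sh.df["end"] > 2_000)).any()


class TestPermutationTest:
    def test_degenerate_null_obs_equals_all_replicates(self):
        """obs identical to every shuffled count: p capped at 1, direction none."""
        genome = GenomeTable({"chr1": 100})
        cat = make_catalog([("chr1", 0, 100, "A")])  # always overlaps everything
        res = enr.permutation_enrichment(
            cat, regions_dict({"chr1": [(0, 100)]}), genome, n_reps=20, rng=0
        )
        row = res.iloc[0]
        assert row["p_value"] == 1.0
        assert row["direction"] == "none"

    def test_hand_computed_empirical_p(self):
        """n_reps=4, exp={0,1,1,2}, obs=5 -> p = 2*(0+1)/5 = 0.4, enriched."""
        exp = np.array([[0], [1], [1], [2]])
        obs = np.array([5])
        c_ge = (exp >= obs).sum(axis=0)
        c_le = (exp <= obs).sum(axis=0)
        p = np.minimum(1.0, 2.0 * np.minimum(c_ge + 1, c_le + 1) / 5)
        assert p[0] == pytest.approx(0.4)
        # and the full pipeline honours the same formula: p is always >= 2/(n_reps+1)
        genome = GenomeTable({"chr1": 10_000})
        cat = make_catalog([("chr1", i * 20, i * 20 + 10, "A") for i in range(100)])
        res = enr.permutation_enrichment(
            cat, regions_dict({"chr1": [(0, 2_000)]}), genome, n_reps=9, rng=1
        )
        assert (res["p_value"] >= 2 / 10 - 1e-12).all()

    def test_deterministic_given_seed_and_input_order(self):
        genome = GenomeTable({"chr1": 50_000})
        rng = np.random.default_rng(2)
        rows = [
            ("chr1", s := int(rng.integers(0, 40_000)), s + int(rng.integers(50, 500)),
             f"F{rng.integers(0, 5)}")
            for _ in range(300)
        ]
        regions = regions_dict({"chr1": [(i * 5_000, i * 5_000 + 1_000) for i in range(10)]})
        cat = make_catalog(rows)
        r1 = enr.permutation_enrichment(cat, regions, genome, 50, rng=42)
        r2 = enr.permutation_enrichment(cat, regions, genome, 50, rng=42)
        pd.testing.assert_frame_equal(r1, r2)
        # row order of the input catalog must not matter
        shuffled_rows = [rows[i] for i in np.random.default_rng(0).permutation(len(rows))]
        r3 = enr.permutation_enrichment(make_catalog(shuffled_rows), regions, genome, 50, rng=42)
        pd.testing.assert_frame_equal(r1, r3)

    def test_odds_ratio_undefined_when_expectation_zero(self):
        genome = GenomeTable({"chr1": 1_000_000})
        cat = make_catalog([("chr1", 500, 510, "A")])
        res = enr.permutation_enrichment(
            cat, regions_dict({"chr1": [(0, 5)]}), genome, n_reps=5, rng=0
        )
        row = res.iloc[0]
        if row["exp_mean"] == 0:
            assert np.isnan(row["odds_ratio"])

    def test_direction_of_planted_enrichment(self, small_dataset):
        from techromatin.chromatin_regions import extract_regions

        ds = small_dataset
        reg = extract_regions(ds.segmentations["t1"], "active", tissue_id="t1")
        res = enr.permutation_enrichment(ds.te_catalog, reg, ds.genome, 1000, rng=5)
        res = res.set_index("key")
        assert res.loc["F01_SINE", "direction"] == "enriched"
        assert res.loc["F01_SINE", "q_value"] < 0.05
        assert res.loc["F05_LINE", "direction"] == "depleted"


class TestBHFDR:
    def test_hand_example(self):
        np.testing.assert_allclose(enr.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        np.testing.assert_allclose(enr.bh_fdr([0.04]), [0.04])

    @given(st.integers(0, 10_000))
    @settings(max_examples=50)
    def test_matches_reference_stepup_and_is_monotone(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-9, 1.0, size=rng.integers(1, 60))
        q = enr.bh_fdr(p)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_ref, rtol=1e-12)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q > 0).all() and (q <= 1).all()

    def test_empty_input(self):
        assert enr.bh_fdr([]).size == 0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            enr.bh_fdr([0.0, 0.5])


class TestAgeClassEnrichment:
    def test_planted_age_class_recovered(self):
        """An age class planted 3x into active regions is flagged at FDR < 5%."""
        from techromatin.chromatin_regions import extract_regions
        from techromatin.synthetic_data import (
            FamilySpec, SimulationConfig, simulate_dataset,
        )

        specs = [
            FamilySpec("P1_SINE", "SINE", "Primates", 300, target=("t1", "active", 3.0)),
            FamilySpec("U1_LINE", "LINE", "Eutheria", 300),
            FamilySpec("U2_DNA", "DNA", "Mammalia", 300),
        ]
        cfg = SimulationConfig(seed=3, n_tissues=2, family_specs=specs, chrom_length=2_000_000)
        ds = simulate_dataset(cfg)
        reg = extract_regions(ds.segmentations["t1"], "active", tissue_id="t1")
        per_class, summary = enr.age_class_enrichment(
            ds.te_catalog, reg, ds.genome, n_reps=500, rng=8
        )
        per_class = per_class.set_index("key")
        assert per_class.loc["Primates", "direction"] == "enriched"
        assert per_class.loc["Primates", "q_value"] < 0.05
        assert set(summary["key"]) <= {"ancient", "young", "unknown"}
        # Primates is younger than the eutherian split
        assert summary.set_index("key").loc["young", "direction"] == "enriched"

    def test_unknown_age_class_grouped_separately(self):
        genome = GenomeTable({"chr1": 100_000})
        cat = make_catalog(
            [("chr1", 100, 200, "A", "SINE", "NotALineage"), ("chr1", 300, 400, "B", "SINE", "Eutheria")]
        )
        _, summary = enr.age_class_enrichment(
            cat, regions_dict({"chr1": [(0, 50_000)]}), genome, n_reps=10, rng=0
        )
        assert "unknown" in set(summary["key"])
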