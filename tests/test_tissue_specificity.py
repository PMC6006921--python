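import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from techromatin import tissue_specificity as ts
from techromatin.io_formats import ExpressionMatrix, GeneCatalog, GeneModel

from conftest import bitmask_union_bp


def gene(gid, chrom, start, end, strand="+", exons=None):
    exons = exons or [(start, end)]
    return GeneModel(gid, chrom, start, end, strand,
                     tuple(s for s, _ in exons), tuple(e for _, e in exons))


class TestZScores:
    def test_constant_row_is_all_na(self):
        m = pd.DataFrame([[2.0, 2.0, 2.0]], index=["F"], columns=["a", "b", "c"])
        assert ts.compute_zscores(m).isna().all().all()

    def test_hand_computed_row(self):
        """Row [1, 1, 4]: mean 2, sample sd sqrt(3) -> z = [-0.577, -0.577, 1.155]."""
        m = pd.DataFrame([[1.0, 1.0, 4.0]], index=["F"], columns=["a", "b", "c"])
        z = ts.compute_zscores(m).to_numpy()[0]
        np.testing.assert_allclose(z, [-1 / np.sqrt(3), -1 / np.sqrt(3), 2 / np.sqrt(3)], atol=1e-9)

    def test_short_row_is_all_na(self):
        m = pd.DataFrame([[1.0, 2.0, np.nan]], index=["F"], columns=["a", "b", "c"])
        assert ts.compute_zscores(m).isna().all().all()

    @given(st.integers(0, 10_000))
    @settings(max_examples=40)
    def test_rows_standardised_and_location_scale_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n_t = int(rng.integers(3, 9))
        row = rng.uniform(0.1, 5.0, n_t)
        if np.allclose(row.std(ddof=1), 0):
            row[0] += 1.0
        m = pd.DataFrame([row], index=["F"], columns=[f"t{i}" for i in range(n_t)])
        z = ts.compute_zscores(m).to_numpy()[0]
        assert abs(np.nanmean(z)) < 1e-9
        assert abs(np.nanstd(z, ddof=1) - 1) < 1e-9
        shift = float(rng.uniform(-3, 3))
        scale = float(rng.uniform(0.1, 10))
        z2 = ts.compute_zscores(m * scale + shift).to_numpy()[0]
        np.testing.assert_allclose(z, z2, atol=1e-9)

    def test_na_entries_ignored(self):
        m = pd.DataFrame([[1.0, np.nan, 2.0, 3.0]], index=["F"], columns=list("abcd"))
        z = ts.compute_zscores(m)
        assert np.isnan(z.iloc[0, 1])
        finite = z.iloc[0].dropna()
        assert abs(finite.mean()) < 1e-9


class TestNearestGene:
    @pytest.fixture(scope="class")
    @staticmethod
    def catalog():
        return GeneCatalog(
            [gene("g150", "chr1", 150, 1000), gene("g500", "chr1", 500, 1500),
             gene("g90", "chr1", 90, 95)]  # minus: tss = end-1 = 94... plus strand: tss=90
        )

    def test_tss_inside_interval_wins(self, catalog):
        # TE 100-200 contains TSS 150; TSS 90 is 10 away, TSS 500 is 301 away
        assert ts.assign_te_to_nearest_gene("chr1", 100, 200, catalog) == "g150"

    def test_gap_arithmetic(self):
        cat = GeneCatalog([gene("gRight", "chr1", 250, 400), gene("gLeft", "chr1", 90, 92)])
        # TE 100-200: right TSS 250 gap 51; left TSS 90 gap 10
        assert ts.assign_te_to_nearest_gene("chr1", 100, 200, cat) == "gLeft"

    def test_equidistant_tie_lexicographic(self):
        cat = GeneCatalog([gene("gB", "chr1", 300, 400), gene("gA", "chr1", 50, 100)])
        # TE 150-250: left TSS 50 gap 100... make symmetric: TSS 50 and 300 w.r.t. TE 150-201
        # left gap = 150-50=100, right gap = 300-200=100
        assert ts.assign_te_to_nearest_gene("chr1", 150, 201, cat) == "gA"

    def test_empty_catalog_errors(self):
        with pytest.raises(ValueError):
            ts.TSSIndex(GeneCatalog([]))


class TestCategorizeGenes:
    def make_assignments(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "tissue", "activity"])

    def test_four_way_rules(self):
        cat = GeneCatalog([gene(f"g{i}", "chr1", i * 1000, i * 1000 + 500) for i in range(4)])
        assignments = self.make_assignments(
            [("g0", "liver", "active"), ("g0", "lung", "active"),
             ("g1", "liver", "active"), ("g1", "lung", "repressed"),
             ("g2", "liver", "repressed")]
        )
        res = ts.categorize_genes(assignments, cat).set_index("gene_id")
        assert res.loc["g0", "category"] == 1
        assert res.loc["g1", "category"] == 2
        assert res.loc["g2", "category"] == 3
        assert res.loc["g3", "category"] == 4

    def test_categories_partition_catalog(self, small_dataset):
        from techromatin.chromatin_regions import extract_regions

        ds = small_dataset
        region_sets = [
            extract_regions(ds.segmentations[t], a, tissue_id=t)
            for t in ds.config.tissues for a in ("active", "repressed")
        ]
        assignments = ts.te_gene_assignments(ds.te_catalog, region_sets, ds.genes)
        cats = ts.categorize_genes(assignments, ds.genes)
        assert len(cats) == len(ds.genes)
        assert set(cats["category"]) <= {1, 2, 3, 4}


class TestGeneDensity:
    def test_isolated_gene_counts_own_exons(self):
        cat = GeneCatalog([gene("g", "chr1", 10_000, 20_000, exons=[(10_000, 10_700), (15_000, 15_800)])])
        assert ts.gene_density("g", cat) == 1_500

    def test_overlapping_exons_use_union_not_sum(self):
        cat = GeneCatalog(
            [gene("a", "chr1", 1_000, 2_000, exons=[(1_000, 1_600)]),
             gene("b", "chr1", 1_400, 2_400, exons=[(1_400, 2_000)])]
        )
        dens = ts.gene_densities(cat)
        assert dens["a"] == 1_000  # union of 1000-1600 and 1400-2000
        assert dens["b"] == 1_000

    @given(st.integers(0, 10_000))
    @settings(max_examples=25)
    def test_matches_bitmask_oracle_on_small_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        genes = []
        for i in range(int(rng.integers(1, 8))):
            start = int(rng.integers(0, 8_000))
            length = int(rng.integers(200, 2_000))
            ex_n = int(rng.integers(1, 4))
            bounds = np.sort(rng.choice(np.arange(start, start + length + 1), size=2 * ex_n, replace=False))
            exons = [(int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(ex_n)
                     if bounds[2 * k] < bounds[2 * k + 1]]
            if not exons:
                exons = [(start, start + length)]
            genes.append(gene(f"g{i}", "chr1", start, start + length, exons=exons))
        cat = GeneCatalog(genes)
        window = 1_000
        dens = ts.gene_densities(cat, window=window)
        all_exons = [(s, e) for g in genes for s, e in zip(g.exon_starts, g.exon_ends)]
        for g in genes:
            lo, hi = max(0, g.start - window), g.end + window
            clipped = [(max(s, lo), min(e, hi)) for s, e in all_exons if s < hi and e > lo]
            assert dens[g.gene_id] == bitmask_union_bp(clipped, 20_000)


def wilcoxon_enumeration_oracle(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments (no ties)."""
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes untied data"
    n1 = len(x)
    obs_u = sum(1 for xi in x for yi in y if xi > yi)
    mean_u = n1 * len(y) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1 for xi in xs for yi in ys if xi > yi)
        total += 1
        if abs(u - mean_u) >= abs(obs_u - mean_u) - 1e-12:
            count += 1
    return count / total


class TestRankSum:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exact_enumeration_for_small_groups(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 8)), int(rng.integers(2, 8))
        pooled = rng.permutation(np.arange(1, n1 + n2 + 1)).astype(float)
        x, y = list(pooled[:n1]), list(pooled[n1:])
        _, p = ts.rank_sum_test(x, y)
        assert p == pytest.approx(wilcoxon_enumeration_oracle(x, y), rel=1e-9)

    def test_degenerate_all_tied(self):
        assert ts.rank_sum_test([1.0, 1.0], [1.0, 1.0, 1.0])[1] == 1.0


def ols_normal_equations(X, y):
    """Closed-form OLS oracle: beta and standard errors from the normal equations."""
    Xd = np.column_stack([np.ones(len(y)), X])
    xtx_inv = np.linalg.inv(Xd.T @ Xd)
    beta = xtx_inv @ Xd.T @ y
    resid = y - Xd @ beta
    sigma2 = resid @ resid / (len(y) - Xd.shape[1])
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    return beta, se


class TestVarianceAnalysis:
    def make_inputs(self, n=60, seed=0, inflate_cat1=1.0):
        rng = np.random.default_rng(seed)
        cats = rng.choice([1, 2, 3, 4], size=n)
        nv = rng.gamma(2.0, 1.0, size=n) * np.where(cats == 1, inflate_cat1, 1.0)
        recs = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "normalized_variance": nv,
                "gene_length": rng.integers(1_000, 50_000, n),
                "gene_density": rng.integers(0, 10_000, n),
            }
        )
        cat_df = pd.DataFrame({"gene_id": recs["gene_id"], "category": cats})
        return recs, cat_df

    def test_ols_matches_normal_equations_oracle(self):
        recs, cats = self.make_inputs(n=12, seed=3)
        res = ts.variance_category_analysis(recs, cats)
        df = recs.merge(cats, on="gene_id")
        X = np.column_stack(
            [
                (df["category"] == 1).astype(float),
                (df["category"] == 2).astype(float),
                (df["category"] == 3).astype(float),
                df["gene_length"].astype(float),
                df["gene_density"].astype(float),
            ]
        )
        beta, se = ols_normal_equations(X, df["normalized_variance"].to_numpy())
        np.testing.assert_allclose(res.ols["coef"].to_numpy(), beta, rtol=1e-8)
        np.testing.assert_allclose(res.ols["se"].to_numpy(), se, rtol=1e-8)

    def test_null_case_small_coefficient(self):
        recs, cats = self.make_inputs(n=400, seed=1)
        res = ts.variance_category_analysis(recs, cats)
        coef = res.ols.loc["cat1", "coef"]
        assert abs(coef) < 3 * res.ols.loc["cat1", "se"]
        assert res.wilcoxon.set_index("contrast").loc["active_any_vs_rest", "p_value"] > 0.001

    def test_inflated_category_detected(self):
        recs, cats = self.make_inputs(n=600, seed=2, inflate_cat1=2.0)
        res = ts.variance_category_analysis(recs, cats)
        assert res.ols.loc["cat1", "coef"] > 0
        assert res.ols.loc["cat1", "p_value"] < 0.01

    def test_requires_two_populated_categories(self):
        recs, cats = self.make_inputs(n=10, seed=0)
        cats["category"] = 1
        with pytest.raises(ValueError):
            ts.variance_category_analysis(recs, cats)


class TestNormalizedVariance:
    def test_index_of_dispersion_and_cv2(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"a": [2.0, 0.0], "b": [4.0, 0.0]}, index=["g1", "g2"])
        )
        nv = ts.normalized_variance(expr)
        # g2 has grand mean 0 and is excluded
        assert list(nv.index) == ["g1"]
        assert nv.loc["g1", "normalized_variance"] == pytest.approx(2.0 / 3.0)
        nv2 = ts.normalized_variance(expr, method="cv2")
        assert nv2.loc["g1", "normalized_variance"] == pytest.approx(2.0 / 9.0)


class TestExpressionShift:
    def make_expr(self, n=100, t=5, seed=0, fold=1.0, focal="t0"):
        rng = np.random.default_rng(seed)
        base = np.exp(rng.normal(2, 1, size=n))
        tpm = base[:, None] * np.exp(rng.normal(0, 0.2, size=(n, t)))
        cols = [f"t{i}" for i in range(t)]
        df = pd.DataFrame(tpm, index=[f"g{i}" for i in range(n)], columns=cols)
        df[focal] *= fold
        return ExpressionMatrix(df)

    def test_identical_expression_gives_p_one(self):
        df = pd.DataFrame(
            np.full((5, 4), 3.0), index=[f"g{i}" for i in range(5)], columns=list("abcd")
        )
        res = ts.tissue_expression_shift([f"g{i}" for i in range(5)], "a", ExpressionMatrix(df))
        assert res.p_value == 1.0 and res.direction == "none"

    def test_planted_up_shift_detected(self):
        expr = self.make_expr(n=100, fold=3.0, focal="t0", seed=4)
        res = ts.tissue_expression_shift([f"g{i}" for i in range(100)], "t0", expr)
        assert res.direction == "up" and res.p_value < 0.01

    def test_small_gene_set_refused(self):
        expr = self.make_expr(n=10)
        with pytest.raises(ValueError, match=">= 3"):
            ts.tissue_expression_shift(["g0", "g1"], "t0", expr)

    def test_unknown_tissue_or_gene_rejected(self):
        expr = self.make_expr(n=10)
        with pytest.raises(ValueError):
            ts.tissue_expression_shift(["g0", "g1", "g2"], "nope", expr)
        with pytest.raises(ValueError):
            ts.tissue_expression_shift(["g0", "g1", "missing"], "t0", expr)
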