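import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dtialps import (
    alps_regressions,
    ancova_omnibus,
    bh_fdr,
    fit_glm,
    hemisphere_comparison,
    nonparametric_tests,
    planned_contrasts,
    vif,
)
from dtialps.stats import build_design, cohens_d_adjusted, dunn_posthoc

# 3 groups x 4 observations; one-way ANOVA by hand:
# group means 2.5/4.5/6.5, SSB = 32 (df 2), SSW = 15 (df 9), F = 16/(15/9) = 9.6
TOY_Y = [1, 2, 3, 4, 3, 4, 5, 6, 5, 6, 7, 8]
TOY_G = ["a"] * 4 + ["b"] * 4 + ["c"] * 4


class TestFitGlm:
    def test_exact_linear_function(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = 2.0 + 3.0 * X[:, 1]
        fit = fit_glm(y, X)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)
        assert fit.r2 == pytest.approx(1.0)

    def test_intercept_only_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_glm(y, np.ones((4, 1)))
        assert fit.r2 == pytest.approx(0.0)
        assert fit.coef[0] == pytest.approx(2.5)

    def test_normal_equations_oracle_six_points(self):
        """Coefficients equal (X'X)^-1 X'y computed independently."""
        X = np.array([[1, 0.0], [1, 1.0], [1, 2.0], [1, 3.0], [1, 4.0], [1, 5.0]])
        y = np.array([1.1, 1.9, 3.2, 3.8, 5.1, 5.9])
        fit = fit_glm(y, X)
        expected = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.coef, expected, atol=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 3))])
        y = rng.normal(size=50)
        fit = fit_glm(y, X, ["intercept", "x1", "x2", "x3"])
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.coef, ols.params, atol=1e-10)
        assert fit.r2 == pytest.approx(ols.rsquared)
        t, p = fit.t_test("x1")
        assert t == pytest.approx(ols.tvalues[1])
        assert p == pytest.approx(ols.pvalues[1])

    def test_rank_deficiency_names_aliased_column(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="aliased"):
            fit_glm(np.ones(10), X, ["intercept", "x", "x_copy"])

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            fit_glm([1.0, np.nan], np.ones((2, 1)))


class TestAncovaOmnibus:
    def test_identical_groups_zero_noise(self):
        df = pd.DataFrame({"alps": [1.5] * 12, "group": TOY_G, "age": np.tile([60.0, 65, 70, 75], 3), "sex": ["M", "F"] * 6})
        res = ancova_omnibus(df, "alps")
        assert res.F == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_f_on_toy_fixture(self):
        """Full-vs-reduced sums of squares by hand: F(2, 9) = 9.6."""
        df = pd.DataFrame({"y": TOY_Y, "group": TOY_G})
        res = ancova_omnibus(df, "y", covariates=())
        assert res.F == pytest.approx(9.6, rel=1e-12)
        assert (res.df1, res.df2) == (2, 9)
        assert res.p == pytest.approx(1.0 - sps.f.cdf(9.6, 2, 9), rel=1e-12)

    def test_matches_classic_anova_without_covariates(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"y": rng.normal(size=30), "group": ["a", "b", "c"] * 10})
        res = ancova_omnibus(df, "y", covariates=())
        f_scipy, p_scipy = sps.f_oneway(*[df.y[df.group == g] for g in "abc"])
        assert res.F == pytest.approx(f_scipy)
        assert res.p == pytest.approx(p_scipy)

    def test_covariate_adjustment_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "y": rng.normal(size=60),
                "group": ["a", "b", "c"] * 20,
                "age": rng.normal(70, 8, 60),
                "sex": rng.choice(["M", "F"], 60),
            }
        )
        res = ancova_omnibus(df, "y")
        X_full, _ = build_design(df, ("age", "sex"), group="group")
        X_red, _ = build_design(df, ("age", "sex"))
        full = sm.OLS(df.y, X_full).fit()
        red = sm.OLS(df.y, X_red).fit()
        f_expected = ((red.ssr - full.ssr) / 2) / (full.ssr / full.df_resid)
        assert res.F == pytest.approx(f_expected, rel=1e-10)

    def test_tiny_group_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2, 3], "group": ["a", "a", "b"], "age": [1.0, 2, 3], "sex": ["M"] * 3})
        with pytest.raises(ValueError, match="fewer than 2"):
            ancova_omnibus(df, "y")


class TestPlannedContrasts:
    def test_identical_groups(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=20)
        df = pd.DataFrame({"y": np.concatenate([vals, vals]), "group": ["a"] * 20 + ["b"] * 20})
        (res,) = planned_contrasts(df, "y", covariates=(), pairs=[("a", "b")])
        assert res.F == pytest.approx(0.0, abs=1e-10)
        assert res.d == pytest.approx(0.0, abs=1e-10)

    def test_pooled_sd_cohens_d_oracle(self):
        """Two groups with sample SD 1 and means 0 and 2: d = 2 exactly."""
        df = pd.DataFrame({"y": [-1.0, 0.0, 1.0, 1.0, 2.0, 3.0], "group": ["a"] * 3 + ["b"] * 3})
        d, _ = cohens_d_adjusted(df, "y", "group", ("a", "b"), covariates=())
        assert d == pytest.approx(2.0, rel=1e-12)

    def test_duplicate_pair_rejected(self):
        df = pd.DataFrame({"y": np.arange(8.0), "group": ["a", "b"] * 4})
        with pytest.raises(ValueError, match="duplicate"):
            planned_contrasts(df, "y", covariates=(), pairs=[("a", "b"), ("b", "a")])

    def test_fdr_applied_across_the_pair_family(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "y": np.concatenate([rng.normal(0, 1, 30), rng.normal(0.3, 1, 30), rng.normal(2.0, 1, 30)]),
                "group": ["a"] * 30 + ["b"] * 30 + ["c"] * 30,
            }
        )
        results = planned_contrasts(df, "y", covariates=(), pairs=[("a", "b"), ("a", "c"), ("b", "c")])
        raw = [r.p for r in results]
        np.testing.assert_allclose([r.p_fdr for r in results], bh_fdr(raw), atol=1e-15)
        assert all(r.p_fdr >= r.p for r in results)

    def test_study_pairs_default(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {
                "alps": rng.normal(1.5, 0.1, 40),
                "group": ["control", "PD-NC", "PDD", "DLB"] * 10,
                "age": rng.normal(70, 6, 40),
                "sex": rng.choice(["M", "F"], 40),
            }
        )
        labels = [r.label for r in planned_contrasts(df, "alps")]
        assert labels == [
            "control vs PD-NC",
            "control vs PDD",
            "control vs DLB",
            "PD-NC vs PDD",
            "PD-NC vs DLB",
            "PDD vs DLB",
        ]


def _bh_bruteforce(p):
    """Literal step-up definition: q_(i) = min over j>=i of p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    sorted_p = p[order]
    for i in range(m):
        q[i] = min(min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = q
    return out


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_hand_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4, atol=1e-15)

    def test_brute_force_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 12))
            np.testing.assert_allclose(bh_fdr(p), _bh_bruteforce(p), atol=1e-12)

    def test_permutation_equivariance(self):
        p = np.array([0.001, 0.2, 0.04, 0.9, 0.04])
        perm = np.array([3, 0, 4, 1, 2])
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]), atol=1e-15)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_bounded_between_raw_and_bonferroni(self, pvals):
        q = bh_fdr(pvals)
        p = np.asarray(pvals)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= np.minimum(p * len(p), 1.0) + 1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestAlpsRegressions:
    @staticmethod
    def _patients(n=60, seed=9):
        rng = np.random.default_rng(seed)
        alps = rng.normal(1.5, 0.15, n)
        return pd.DataFrame(
            {
                "group": rng.choice(["PD-NC", "PDD", "DLB"], n),
                "alps": alps,
                "age": rng.normal(70, 7, n),
                "sex": rng.choice(["M", "F"], n),
                "complexity": rng.normal(0.3, 0.05, n),
                "exact": 2.0 + 10.0 * alps,
                "noise": rng.normal(size=n),
            }
        )

    def test_exact_linear_outcome(self):
        out = alps_regressions(self._patients(), ["exact"], {"none": ()})
        row = out.iloc[0]
        assert row.r2 == pytest.approx(1.0)
        assert row.beta_alps == pytest.approx(10.0)
        assert row.p < 1e-30

    def test_rows_per_outcome_and_covariate_set(self):
        out = alps_regressions(self._patients(), ["exact", "noise"])
        assert len(out) == 6
        assert set(out.covariate_set) == {"none", "age", "age_sex_complexity"}

    def test_small_n_flagged_and_out_of_family(self):
        df = self._patients(n=30)
        df.loc[df.index[:25], "sparse"] = np.nan
        out = alps_regressions(df, ["exact", "sparse"], {"none": ()})
        sparse = out[out.outcome == "sparse"].iloc[0]
        assert bool(sparse.flagged) and np.isnan(sparse.p_fdr)
        exact = out[out.outcome == "exact"].iloc[0]
        assert not exact.flagged

    def test_nested_covariates_never_increase_fit_error(self):
        """Adding covariates cannot reduce R^2 of a nested least-squares fit."""
        df = self._patients()
        out = alps_regressions(df, ["noise"], {"none": (), "age": ("age",), "full": ("age", "sex", "complexity")})
        r2 = out.set_index("covariate_set").r2
        assert r2["age"] >= r2["none"] - 1e-12
        assert r2["full"] >= r2["age"] - 1e-12


class TestVif:
    def test_orthogonal_predictors(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        np.testing.assert_allclose(vif(X).to_numpy(), 1.0, atol=1e-12)

    def test_near_collinear_blows_up(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=200)
        X = pd.DataFrame({"x1": x, "x2": x + rng.normal(0, 1e-3, 200)})
        assert (vif(X) > 10).all()

    def test_auxiliary_regression_oracle(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        X["b"] += 0.6 * X["a"]
        got = vif(X)
        for col in X.columns:
            others = X.drop(columns=col).to_numpy()
            aux = sm.OLS(X[col], sm.add_constant(others)).fit()
            assert got[col] == pytest.approx(1.0 / (1.0 - aux.rsquared), rel=1e-8)

    def test_perfect_collinearity_named(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "twice_a": [2.0, 4, 6, 8], "b": [1.0, 0, 1, 0]})
        with pytest.raises(ValueError, match="collinear"):
            vif(X)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            vif(pd.DataFrame({"a": [1.0, 1, 1], "b": [1.0, 2, 3]}))


class TestHemisphereComparison:
    def test_equal_hemispheres(self):
        t, p = hemisphere_comparison([1.5, 1.6, 1.4], [1.5, 1.6, 1.4])
        assert t == 0.0 and p == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.raises(ValueError, match="zero variance"):
            hemisphere_comparison([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])

    def test_five_pair_hand_formula(self):
        """t = mean(d) / (sd(d)/sqrt(n)) on differences (1,2,3,4,5)."""
        left = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        right = left - np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        t, p = hemisphere_comparison(left, right)
        d = left - right
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert t == pytest.approx(expected, rel=1e-12)
        assert t == pytest.approx(3.0 / (np.sqrt(2.5) / np.sqrt(5)), rel=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(t, 4), rel=1e-12)


class TestNonparametric:
    def test_two_identical_samples(self):
        res = nonparametric_tests([1.0, 2, 3, 4, 1, 2, 3, 4], ["a"] * 4 + ["b"] * 4)
        assert res["statistic_name"] == "W"
        assert res["p"] > 0.9

    def test_three_group_hand_ranks(self):
        """H from the rank formula computed by hand (no ties)."""
        vals = [1.0, 2, 3, 4, 5, 6, 7, 8, 9]
        grp = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        res = nonparametric_tests(vals, grp)
        ranks = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        n = 9
        h = 12.0 / (n * (n + 1)) * sum(3 * np.mean(r) ** 2 for r in ranks.values()) - 3 * (n + 1)
        assert res["statistic"] == pytest.approx(h, rel=1e-12)

    def test_dunn_identical_groups_p_near_one(self):
        """Groups holding the same values have equal rank means: z = 0, p = 1."""
        vals = np.tile(np.random.default_rng(12).normal(size=20), 3)
        grp = np.repeat(["a", "b", "c"], 20)
        dunn = dunn_posthoc(vals, grp)
        np.testing.assert_allclose(dunn.z, 0.0, atol=1e-12)
        np.testing.assert_allclose(dunn.p_fdr, 1.0, atol=1e-12)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            nonparametric_tests([1.0] * 6, ["a"] * 3 + ["b"] * 3)

    def test_kruskal_matches_scipy_with_ties(self):
        rng = np.random.default_rng(13)
        vals = rng.integers(0, 5, 30).astype(float)
        grp = np.repeat(["a", "b", "c"], 10)
        res = nonparametric_tests(vals, grp)
        h, p = sps.kruskal(*[vals[grp == g] for g in "abc"])
        assert res["statistic"] == pytest.approx(h)
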