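import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from fastdki.stats import (DegenerateDataError, GroupSample, SeparationError,
                           dunn_pairwise, fit_multinomial, kruskal_wallis,
                           md_display_scale, pearson_r, pool_nonenhancing)
from helpers import (brute_dunn_z, brute_kruskal_h, group_relabelings,
                     simulate_multinomial_lesions)


def _g(label, values, pids=None):
    return GroupSample(label, np.asarray(values, float), pids)


class TestKruskalWallis:
    def test_hand_computed_example(self):
        res = kruskal_wallis([_g("a", [1, 2, 3]), _g("b", [4, 5, 6]),
                              _g("c", [7, 8, 9])])
        assert res.statistic == pytest.approx(7.2, abs=1e-12)
        assert res.df == 2

    def test_exchangeable_groups_give_zero(self):
        res = kruskal_wallis([_g("a", [1, 2, 3, 4]), _g("b", [1, 2, 3, 4])])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([_g("a", [1, 2, 3])])

    def test_all_identical_values_undefined(self):
        with pytest.raises(DegenerateDataError):
            kruskal_wallis([_g("a", [5, 5]), _g("b", [5, 5])])

    def test_matches_direct_formula_over_exhaustive_relabelings(self):
        """H agrees with an independently coded rank formula for every
        assignment of 8 values (with ties) into groups of sizes (3, 3, 2)."""
        values = np.array([1.0, 2.0, 2.0, 3.5, 4.0, 5.0, 5.0, 7.0])
        sizes = (3, 3, 2)
        checked = 0
        for assignment in group_relabelings(sizes):
            groups = [values[list(idx)] for idx in assignment]
            if all(np.ptp(np.concatenate(groups)) > 0 for _ in [0]):
                try:
                    h = kruskal_wallis([_g(str(i), g) for i, g in
                                        enumerate(groups)]).statistic
                except DegenerateDataError:
                    continue
                assert h == pytest.approx(brute_kruskal_h(groups), abs=1e-12)
                checked += 1
        assert checked == 560


class TestDunnPairwise:
    def test_hand_computed_z_and_bonferroni(self):
        table = dunn_pairwise([_g("a", [1, 2, 3]), _g("b", [4, 5, 6]),
                               _g("c", [7, 8, 9])])
        row = table[(table.group_a == "a") & (table.group_b == "c")].iloc[0]
        assert abs(row.z) == pytest.approx(6 / np.sqrt(5), abs=1e-12)
        assert row.p_raw == pytest.approx(0.00729, abs=5e-5)
        assert row.p_adjusted == pytest.approx(0.0219, abs=2e-4)

    def test_identical_groups_adjusted_p_one(self):
        table = dunn_pairwise([_g("a", [1, 2, 3, 4]), _g("b", [1, 2, 3, 4])])
        assert (table.p_adjusted == 1.0).all()

    def test_five_groups_give_ten_pairs(self, rng):
        groups = [_g(str(i), rng.normal(i, 1, 12)) for i in range(5)]
        table = dunn_pairwise(groups)
        assert len(table) == 10

    def test_bonferroni_monotone_and_capped(self, rng):
        groups = [_g(str(i), rng.normal(0, 1, 10)) for i in range(4)]
        table = dunn_pairwise(groups)
        assert (table.p_adjusted >= table.p_raw).all()
        assert (table.p_adjusted <= 1.0).all()

    def test_z_matches_direct_formula_with_ties(self, rng):
        values = rng.integers(0, 6, 20).astype(float)  # heavy ties
        groups_np = [values[:8], values[8:14], values[14:]]
        table = dunn_pairwise([_g(str(i), g) for i, g in enumerate(groups_np)],
                              adjust="none")
        for k, (i, j) in enumerate([(0, 1), (0, 2), (1, 2)]):
            assert table.iloc[k].z == pytest.approx(
                brute_dunn_z(groups_np, i, j), abs=1e-12)


class TestPooling:
    def test_printed_group_sizes_and_means_mk(self):
        pooled = pool_nonenhancing(_g("FLAIR-L", np.full(832, 0.565)),
                                   _g("BH", np.full(667, 0.549)))
        assert pooled.label == "NE-L"
        assert pooled.n == 1499
        assert round(pooled.values.mean(), 3) == 0.558

    def test_printed_group_sizes_and_means_md(self):
        pooled = pool_nonenhancing(_g("FLAIR-L", np.full(832, 0.976)),
                                   _g("BH", np.full(667, 0.957)))
        assert round(pooled.values.mean(), 3) == 0.968

    def test_size_weighted_mean_exact(self, rng):
        a = _g("FLAIR-L", rng.normal(1, 0.2, 50))
        b = _g("BH", rng.normal(2, 0.2, 30))
        pooled = pool_nonenhancing(a, b)
        expected = (a.values.sum() + b.values.sum()) / 80
        assert pooled.values.mean() == pytest.approx(expected, rel=1e-15)
        assert pooled.n == 80


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_bivariate_normal_recovery(self):
        """A 222-sample draw at rho = -0.47 (37 patients x 6 ROIs) lands
        within +-0.1 of the generating correlation."""
        rng = np.random.default_rng(1234)
        cov = [[1, -0.47], [-0.47, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=222)
        r, p = pearson_r(xy[:, 0], xy[:, 1])
        assert abs(r - (-0.47)) < 0.1
        assert p < 0.001


def test_md_display_scale():
    assert md_display_scale(0.747) == pytest.approx(74.7)
    assert md_display_scale(0.0) == 0.0
    np.testing.assert_allclose(md_display_scale([0.5, 1.0]), [50.0, 100.0])


class TestFitMultinomial:
    def test_two_categories_reduce_to_binary_logit(self):
        rng = np.random.default_rng(5)
        df = simulate_multinomial_lesions(1500, rng, beta_bh_mk=np.log(0.191))
        df = df[df.category.isin(["FLAIR-L", "BH"])]
        fit = fit_multinomial(df, terms=("mean_mkt",),
                              categories=("FLAIR-L", "BH"), cluster=None)
        y = (df.category == "BH").astype(int).to_numpy()
        x = sm.add_constant(df[["mean_mkt"]].astype(float))
        ref = sm.Logit(y, x).fit(disp=0, method="newton")
        np.testing.assert_allclose(fit.params["BH"].to_numpy(),
                                   ref.params.to_numpy(), atol=1e-6)

    def test_zero_variance_predictor_rejected(self):
        df = pd.DataFrame({
            "category": ["FLAIR-L"] * 5 + ["BH"] * 5,
            "mean_mkt": np.ones(10),
            "patient_id": list("abcdeabcde"),
        })
        with pytest.raises(DegenerateDataError):
            fit_multinomial(df, terms=("mean_mkt",),
                            categories=("FLAIR-L", "BH"))

    def test_perfect_separation_detected(self):
        x = np.concatenate([np.linspace(0, 0.4, 30), np.linspace(0.6, 1.0, 30)])
        df = pd.DataFrame({
            "category": ["FLAIR-L"] * 30 + ["BH"] * 30,
            "mean_mkt": x,
            "patient_id": [str(i % 7) for i in range(60)],
        })
        with pytest.raises(SeparationError):
            fit_multinomial(df, terms=("mean_mkt",),
                            categories=("FLAIR-L", "BH"), cluster=None)

    def test_singleton_clusters_match_heteroskedastic_covariance(self):
        rng = np.random.default_rng(6)
        df = simulate_multinomial_lesions(600, rng, beta_bh_mk=-1.0)
        df["patient_id"] = np.arange(len(df)).astype(str)  # one obs per cluster
        fit = fit_multinomial(df, terms=("mean_mkt",),
                              categories=("FLAIR-L", "CE-L", "BH"))
        y = pd.Categorical(df.category,
                           categories=["FLAIR-L", "CE-L", "BH"]).codes
        x = sm.add_constant(df[["mean_mkt"]].astype(float))
        ref = sm.MNLogit(y, x).fit(disp=0, method="newton", cov_type="HC0")
        np.testing.assert_allclose(np.asarray(fit.bse), np.asarray(ref.bse),
                                   rtol=0.02)

    def test_odds_ratio_table_shape_and_exp_consistency(self):
        rng = np.random.default_rng(7)
        df = simulate_multinomial_lesions(2000, rng, beta_bh_mk=np.log(0.191))
        fit = fit_multinomial(df, terms=("mean_mkt",),
                              categories=("FLAIR-L", "CE-L", "BH"))
        assert fit.reference == "FLAIR-L"
        tab = fit.table("mean_mkt")
        assert set(tab.category) == {"CE-L", "BH"}
        for _, row in tab.iterrows():
            assert row.odds_ratio == pytest.approx(np.exp(row.coef))
            assert row.ci_low < row.odds_ratio < row.ci_high

    def test_reference_must_be_modeled(self):
        df = simulate_multinomial_lesions(200, np.random.default_rng(8), -1.0)
        with pytest.raises(ValueError):
            fit_multinomial(df, reference="HC-WM")
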