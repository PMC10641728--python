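import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from qeegpod.stats import (
    GroupComparison,
    anova_oneway,
    fisher_exact_2x2,
    incidence,
    proportion_compare,
    sample_size_two_proportions,
    summarize_groups,
    welch_t_from_summary,
    welch_t_test,
)


class TestWelch:
    def test_identical_summaries_give_t0_p1(self):
        t, df, p = welch_t_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_summary_example(self):
        t, df, p = welch_t_from_summary(0.0, 1.0, 10, 1.0, 1.0, 10)
        assert t == pytest.approx(-0.7071067811865475, rel=1e-12)
        assert df == pytest.approx(18.0, rel=1e-12)
        assert p == pytest.approx(0.4885543248, rel=1e-8)

    def test_hand_computed_samples_example_matches_scipy(self):
        t, df, p = welch_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674234614, rel=1e-8)
        assert df == pytest.approx(4.0, rel=1e-12)
        assert p == pytest.approx(0.02131164, rel=1e-6)
        ref = sps.ttest_ind([1, 2, 3], [4, 5, 6], equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_group_vs_itself_p1(self):
        x = [1.0, 2.0, 4.0, 7.0]
        t, _, p = welch_t_test(x, x)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_samples_route_equals_summary_route_exactly(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=12), rng.normal(1.0, 2.0, size=9)
        sx = np.std(x, ddof=1) / np.sqrt(x.size)
        sy = np.std(y, ddof=1) / np.sqrt(y.size)
        assert welch_t_test(x, y) == welch_t_from_summary(
            x.mean(), sx, x.size, y.mean(), sy, y.size
        )

    def test_permutation_within_groups_invariant(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=8), rng.normal(size=8)
        a = welch_t_test(x, y)
        b = welch_t_test(rng.permutation(x), rng.permutation(y))
        assert a == pytest.approx(b, rel=1e-12)

    def test_published_sef95_summaries_reproduce_reported_significance(self):
        """Welch from the printed SEF95 mean ± SEM rows lands at p ~ 4e-4,
        consistent with the reported 0.0003 at the printed rounding."""
        t, df, p = welch_t_from_summary(9.46, 0.75, 24, 14.31, 1.01, 22)
        assert t < 0
        assert 1e-4 < p < 1e-3

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t_from_summary(0, 1, 1, 1, 1, 10)
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_zero_variance_both_groups_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            welch_t_test([2.0, 2.0], [3.0, 3.0])


class TestAnova:
    def test_identical_groups_f0_p1(self):
        f, df1, df2, p = anova_oneway([1, 2, 3], [1, 2, 3], [1, 2, 3])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert (df1, df2) == (2, 6)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example_matches_scipy(self):
        f, df1, df2, p = anova_oneway([1, 2, 3], [2, 3, 4], [5, 6, 7])
        assert f == pytest.approx(13.0, rel=1e-12)
        assert (df1, df2) == (2, 6)
        assert p == pytest.approx(0.006591796875, rel=1e-9)
        ref = sps.f_oneway([1, 2, 3], [2, 3, 4], [5, 6, 7])
        assert f == pytest.approx(ref.statistic, rel=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_groups_error(self):
        with pytest.raises(ValueError, match="within-group variance"):
            anova_oneway([2, 2, 2], [2, 2, 2])

    def test_two_groups_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=10), rng.normal(0.5, 1.0, size=10)
        f, _, _, p_f = anova_oneway(x, y)
        t = sps.ttest_ind(x, y, equal_var=True)
        assert f == pytest.approx(t.statistic**2, rel=1e-10)
        assert p_f == pytest.approx(t.pvalue, rel=1e-10)


class TestProportions:
    def test_equal_proportions_or1_p1(self):
        out = proportion_compare(5, 10, 5, 10)
        assert out["odds_ratio"] == pytest.approx(1.0)
        assert out["p_fisher"] == pytest.approx(1.0)

    def test_enumerated_fisher_small_table(self):
        # support {0,1,2} with probabilities 1/6, 4/6, 1/6 -> two-sided 1/3
        assert fisher_exact_2x2(2, 2, 0, 2) == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_fisher_matches_scipy_on_grid(self):
        for k1, n1, k2, n2 in [(10, 24, 1, 22), (3, 8, 5, 9), (0, 5, 4, 7), (7, 12, 2, 15)]:
            ours = fisher_exact_2x2(k1, n1, k2, n2)
            ref = sps.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]]).pvalue
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_study_incidence_table_strongly_significant(self):
        out = proportion_compare(10, 24, 1, 22)
        assert out["p_fisher"] < 0.01
        assert out["p_chi2"] < 0.01
        assert out["odds_ratio"] > 1

    def test_hypergeometric_enumeration_sums_to_one(self):
        for n1, n2, k in [(24, 22, 11), (10, 10, 7), (5, 30, 4)]:
            support = np.arange(max(0, k - n2), min(n1, k) + 1)
            total = sps.hypergeom.pmf(support, n1 + n2, k, n1).sum()
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            proportion_compare(5, 0, 1, 10)
        with pytest.raises(ValueError):
            proportion_compare(11, 10, 1, 10)


class TestIncidence:
    @pytest.mark.parametrize(
        "k,n,display", [(10, 24, 41.7), (1, 22, 4.5), (0, 22, 0.0)]
    )
    def test_display_rounding(self, k, n, display):
        assert incidence(k, n)["display"] == display

    def test_full_precision_kept(self):
        assert incidence(10, 24)["percent"] == pytest.approx(1000 / 24)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            incidence(0, 0)


class TestSampleSize:
    def test_unpooled_normal_formula(self):
        out = sample_size_two_proportions(0.35, 0.05, 0.05, 0.80, "unpooled-normal")
        assert out["n_per_group"] == 24
        # direct formula evaluation as the oracle
        za, zb = sps.norm.ppf(0.975), sps.norm.ppf(0.80)
        exact = (za + zb) ** 2 * (0.35 * 0.65 + 0.05 * 0.95) / 0.30**2
        assert out["exact"] == pytest.approx(exact, rel=1e-12)

    def test_arcsine_formula(self):
        out = sample_size_two_proportions(0.35, 0.05, 0.05, 0.80, "arcsine")
        assert out["n_per_group"] == 12
        h = 2 * np.arcsin(np.sqrt(0.35)) - 2 * np.arcsin(np.sqrt(0.05))
        za, zb = sps.norm.ppf(0.975), sps.norm.ppf(0.80)
        assert out["exact"] == pytest.approx((za + zb) ** 2 / h**2, rel=1e-12)

    def test_arcsine_matches_statsmodels_convention(self):
        statsmodels = pytest.importorskip("statsmodels.stats.power")
        h = 2 * np.arcsin(np.sqrt(0.35)) - 2 * np.arcsin(np.sqrt(0.05))
        nobs = statsmodels.NormalIndPower().solve_power(
            effect_size=h, alpha=0.05, power=0.80, ratio=1.0, alternative="two-sided"
        )
        ours = sample_size_two_proportions(0.35, 0.05, 0.05, 0.80, "arcsine")["exact"]
        # statsmodels scales the variance by 2 for the two-sample design
        assert ours == pytest.approx(nobs / 2.0, rel=1e-4)

    def test_equal_proportions_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            sample_size_two_proportions(0.3, 0.3)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            sample_size_two_proportions(0.35, 0.05, method="exactish")


class TestGroupComparisonModel:
    def _frame(self, rng, n1=6, n2=5, shift=0.0):
        rows = []
        for i in range(n1):
            rows.append({"group": "g1", "delta_percent": rng.normal(70, 5),
                         "sef95_hz": rng.normal(10, 1)})
        for i in range(n2):
            rows.append({"group": "g2", "delta_percent": rng.normal(70 + shift, 5),
                         "sef95_hz": rng.normal(10 - shift / 5, 1)})
        return pd.DataFrame(rows)

    def test_two_identical_groups_all_p_one(self):
        base = pd.DataFrame(
            {"delta_percent": [60.0, 70.0, 80.0], "sef95_hz": [8.0, 10.0, 12.0]}
        )
        df = pd.concat(
            [base.assign(group="g1"), base.assign(group="g2")], ignore_index=True
        )
        res = GroupComparison.from_dataframe(df).fit()
        assert np.allclose(res.p_values.to_numpy(), 1.0)

    def test_summaries_match_brute_force(self):
        rng = np.random.default_rng(3)
        df = self._frame(rng)
        res = GroupComparison.from_dataframe(df).fit()
        g1 = df[df.group == "g1"]["delta_percent"]
        assert res.table.loc["delta_percent", "mean_g1"] == pytest.approx(
            g1.mean(), abs=1e-9
        )
        assert res.table.loc["delta_percent", "sem_g1"] == pytest.approx(
            g1.std(ddof=1) / np.sqrt(len(g1)), abs=1e-9
        )

    def test_group_of_one_rejected(self):
        df = pd.DataFrame({"group": ["a", "a", "b"], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="size 1"):
            GroupComparison.from_dataframe(df)

    def test_three_groups_use_anova(self):
        rng = np.random.default_rng(4)
        df = pd.concat([
            self._frame(rng),
            pd.DataFrame({"group": "g3", "delta_percent": rng.normal(75, 5, 4),
                          "sef95_hz": rng.normal(9, 1, 4)}),
        ], ignore_index=True)
        res = GroupComparison.from_dataframe(df).fit()
        assert (res.table["test"] == "anova").all()

    def test_holm_adjustment_monotone_and_bounded(self):
        rng = np.random.default_rng(5)
        res = GroupComparison.from_dataframe(self._frame(rng, shift=8.0)).fit()
        adj = res.holm_adjusted()
        assert ((adj >= res.p_values - 1e-15) & (adj <= 1.0)).all()

    def test_display_table_rounding_style(self):
        rng = np.random.default_rng(6)
        res = GroupComparison.from_dataframe(self._frame(rng)).fit()
        disp = res.display_table()
        assert "±" in disp.iloc[0, 0]
        assert len(disp["p value"].iloc[0].split(".")[1]) == 4

    def test_summarize_groups_from_dataframe(self):
        rng = np.random.default_rng(7)
        res = summarize_groups(self._frame(rng, shift=20.0))
        assert res.table.loc["delta_percent", "p_value"] < 0.05
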