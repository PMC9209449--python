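"""Univariate inference: sequential ANOVA, effect sizes, the normality
decision tree, rank tests and multiple-comparison machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epicarp import (
    TwoWayAnova,
    bh_adjust,
    dunn_posthoc,
    kruskal_wallis,
    normality_gate,
    omega_squared_ratio,
    round_sig,
    tukey_hsd,
)
from epicarp.errors import ParameterError, ValidationError


def _design(n_per_cell=3, seed=0):
    rng = np.random.default_rng(seed)
    a = np.repeat(["u", "v", "w", "x"], 2 * n_per_cell)
    b = np.tile(np.repeat(["1", "2"], n_per_cell), 4)
    y = rng.normal(size=len(a)) + (a == "u") * 1.5 + (b == "2") * 0.5
    return y, a, b


class TestTwoWayAnova:
    def test_matches_statsmodels_type_i(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        y, a, b = _design()
        mine = TwoWayAnova(y, a, b).fit()
        ref = anova_lm(
            smf.ols("y ~ C(a) + C(b) + C(a):C(b)", data=pd.DataFrame({"y": y, "a": a, "b": b})).fit(),
            typ=1,
        )
        np.testing.assert_allclose(mine.table["sum_sq"], ref["sum_sq"], rtol=1e-10)
        np.testing.assert_allclose(mine.table["F"][:3], ref["F"][:3], rtol=1e-10)
        np.testing.assert_allclose(mine.table["p"][:3], ref["PR(>F)"][:3], rtol=1e-10)

    def test_matches_statsmodels_on_unbalanced_data(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        y, a, b = _design(seed=5)
        keep = np.ones(len(y), bool)
        keep[[0, 7, 13, 20]] = False
        mine = TwoWayAnova(y[keep], a[keep], b[keep]).fit()
        ref = anova_lm(
            smf.ols(
                "y ~ C(a) + C(b) + C(a):C(b)",
                data=pd.DataFrame({"y": y[keep], "a": a[keep], "b": b[keep]}),
            ).fit(),
            typ=1,
        )
        np.testing.assert_allclose(mine.table["sum_sq"], ref["sum_sq"], rtol=1e-9)

    def test_balanced_cell_means_decomposition(self):
        """Zero-noise 2x2 design: SS match the closed-form decomposition."""
        # cell means: rows (a1,a2) x cols (b1,b2) = [[1, 3], [5, 7]], n=2 each
        y = np.array([1, 1, 3, 3, 5, 5, 7, 7], dtype=float)
        a = np.array(["a1", "a1", "a1", "a1", "a2", "a2", "a2", "a2"])
        b = np.array(["b1", "b1", "b2", "b2", "b1", "b1", "b2", "b2"])
        res = TwoWayAnova(y, a, b).fit()
        # grand mean 4; main effect A: 2*(2^2)*2 = 32; B: 2*(1^2)*2*2 = 8
        assert res.table.loc["A", "sum_sq"] == pytest.approx(32.0)
        assert res.table.loc["B", "sum_sq"] == pytest.approx(8.0)
        assert res.table.loc["A:B", "sum_sq"] == pytest.approx(0.0)
        assert res.table.loc["Residual", "sum_sq"] == pytest.approx(0.0)

    def test_observation_order_is_irrelevant(self):
        y, a, b = _design(seed=2)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(y))
        r1 = TwoWayAnova(y, a, b).fit()
        r2 = TwoWayAnova(y[perm], a[perm], b[perm]).fit()
        pd.testing.assert_frame_equal(r1.table, r2.table, rtol=1e-10)

    def test_ss_additivity_and_df_sum(self):
        y, a, b = _design(seed=7)
        res = TwoWayAnova(y, a, b).fit()
        assert res.table["sum_sq"].sum() == pytest.approx(res.ss_total, rel=1e-10)
        assert res.table["df"].sum() == len(y) - 1

    def test_constant_response_is_degenerate_not_crashing(self):
        y = np.ones(16)
        a = np.repeat(["u", "v"], 8)
        b = np.tile(np.repeat(["1", "2"], 4), 2)
        res = TwoWayAnova(y, a, b).fit()
        assert res.ss_total == pytest.approx(0.0)
        assert res.table["F"][:3].isna().all()

    def test_empty_cell_is_named(self):
        y = np.arange(6, dtype=float)
        a = np.array(["u", "u", "u", "v", "v", "v"])
        b = np.array(["1", "1", "2", "1", "1", "1"])  # cell (v, 2) empty
        with pytest.raises(ValidationError, match="v.*2|2.*v"):
            TwoWayAnova(y, a, b).fit()

    def test_sqrt_transformation_applied(self):
        y, a, b = _design(seed=11)
        y = y - y.min() + 1
        direct = TwoWayAnova(np.sqrt(y), a, b).fit()
        via_flag = TwoWayAnova(y, a, b).fit(transformation="sqrt")
        pd.testing.assert_frame_equal(direct.table, via_flag.table)
        assert via_flag.transformation == "sqrt"


class TestOmegaSquared:
    def test_zero_when_f_is_one(self):
        y, a, b = _design(seed=13)
        res = TwoWayAnova(y, a, b).fit()
        table = res.table.copy()
        # force MS_effect == MS_error for factor A
        table.loc["A", "mean_sq"] = table.loc["Residual", "mean_sq"]
        res.table = table
        assert res.omega_squared()["A"] == pytest.approx(0.0)

    def test_printed_f_statistics_reproduce_the_ratio(self):
        # two effects of df 3 sharing one error term: 3(18.58-1)/(3(5.00-1))
        assert omega_squared_ratio(3, 18.58, 3, 5.00) == pytest.approx(4.4)

    def test_ratio_identity_matches_full_omega_computation(self):
        """df_a(F_a-1)/df_b(F_b-1) equals the omega-squared ratio whenever the
        two effects share the error term (algebraic cancellation)."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            y, a, b = _design(seed=int(rng.integers(1_000_000)))
            res = TwoWayAnova(y, a, b).fit()
            omega = res.omega_squared()
            if abs(omega["B"]) < 1e-9:
                continue
            t = res.table
            identity = (t.loc["A", "df"] * (t.loc["A", "F"] - 1)) / (
                t.loc["B", "df"] * (t.loc["B", "F"] - 1)
            )
            assert omega["A"] / omega["B"] == pytest.approx(identity, rel=1e-9)

    def test_reciprocal_ratios_multiply_to_one(self):
        y, a, b = _design(seed=19)
        res = TwoWayAnova(y, a, b).fit()
        omega = res.omega_squared()
        raw = omega["A"] / omega["B"]
        assert raw * (omega["B"] / omega["A"]) == pytest.approx(1.0)


class TestNormalityGate:
    def test_normal_sample_keeps_anova(self):
        rng = np.random.default_rng(10)
        decision = normality_gate(rng.normal(size=100))
        assert decision.branch == "anova"

    def test_squared_normal_takes_sqrt_branch(self):
        rng = np.random.default_rng(20)
        y = rng.normal(4, 1, size=200) ** 2
        decision = normality_gate(y)
        assert decision.branch == "sqrt_anova"
        assert decision.shapiro_p_raw < 0.05 <= decision.shapiro_p_sqrt

    def test_heavy_tailed_sample_falls_back_to_ranks(self):
        rng = np.random.default_rng(30)
        decision = normality_gate(np.abs(rng.standard_cauchy(size=150)))
        assert decision.branch == "kruskal_wallis"

    def test_too_few_observations_rejected(self):
        with pytest.raises(ParameterError):
            normality_gate([1.0, 2.0])


class TestRankTests:
    def test_two_groups_equal_rank_sum_chi_square(self):
        """With two groups the Kruskal-Wallis statistic is the chi-square form
        of the Wilcoxon rank-sum test (z^2)."""
        rng = np.random.default_rng(4)
        g1, g2 = rng.normal(size=12), rng.normal(1.0, 1, size=10)
        h, df, p = kruskal_wallis([g1, g2])
        assert df == 1
        # normal-approximation z from the rank-sum statistic, no ties
        n1, n2 = len(g1), len(g2)
        ranks = stats.rankdata(np.concatenate([g1, g2]))
        r1 = ranks[:n1].sum()
        z = (r1 - n1 * (n1 + n2 + 1) / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert h == pytest.approx(z**2, rel=1e-10)

    def test_fully_separated_groups_are_significant(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)
        assert p < 0.05

    def test_dunn_identical_groups_give_z_zero(self):
        out = dunn_posthoc([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert out["z"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_dunn_hand_computed_example(self):
        """Three groups without ties: z from rank means by direct computation."""
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
        out = dunn_posthoc(groups, labels=["a", "b", "c"])
        n = 9
        var_unit = n * (n + 1) / 12.0
        z_ab = (2.0 - 5.0) / np.sqrt(var_unit * (2 / 3))
        row = out[(out["group_1"] == "a") & (out["group_2"] == "b")].iloc[0]
        assert row["z"] == pytest.approx(z_ab)
        assert row["p"] == pytest.approx(2 * stats.norm.sf(abs(z_ab)))

    def test_dunn_q_values_are_bh_of_p(self):
        rng = np.random.default_rng(6)
        out = dunn_posthoc([rng.normal(size=6) for _ in range(4)])
        np.testing.assert_allclose(out["q"], bh_adjust(out["p"].to_numpy()))


class TestBhAdjust:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.42]), [0.42])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_manual_step_up_on_random_sets(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            m = len(p)
            order = np.argsort(p)
            q_sorted = np.minimum.accumulate(
                (p[order] * m / np.arange(1, m + 1))[::-1]
            )[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q_sorted, 1.0)
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.5, 1.2])


class TestTukey:
    def test_matches_scipy_on_balanced_groups(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(loc, 1, size=8) for loc in (0, 0.5, 2.0)]
        mine = tukey_hsd(groups, labels=["a", "b", "c"])
        ref = stats.tukey_hsd(*groups)
        for row_idx, (i, j) in enumerate([(0, 1), (0, 2), (1, 2)]):
            assert mine["p_adj"].iloc[row_idx] == pytest.approx(
                ref.pvalue[i, j], abs=1e-9
            )

    def test_two_groups_reduce_to_t_test(self):
        """With k=2 the studentized range q equals t*sqrt(2), so the Tukey p
        equals the pooled two-sample t-test p."""
        rng = np.random.default_rng(12)
        g1, g2 = rng.normal(size=10), rng.normal(0.8, 1, size=10)
        mine = tukey_hsd([g1, g2])
        t, p = stats.ttest_ind(g1, g2)
        assert mine["q_stat"].iloc[0] == pytest.approx(abs(t) * np.sqrt(2), rel=1e-10)
        assert mine["p_adj"].iloc[0] == pytest.approx(p, rel=1e-6)

    def test_identical_groups_not_significant(self):
        out = tukey_hsd([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert out["p_adj"].iloc[0] == pytest.approx(1.0)

    def test_p_ordering_follows_mean_differences_for_equal_n(self):
        rng = np.random.default_rng(14)
        groups = [rng.normal(loc, 1, size=6) for loc in (0, 1, 3)]
        out = tukey_hsd(groups)
        order_by_diff = out["mean_diff"].abs().sort_values(ascending=False).index
        order_by_p = out["p_adj"].sort_values().index
        assert list(order_by_diff) == list(order_by_p)


def test_round_sig_reporting_convention():
    assert round_sig(4.395, 2) == 4.4
    assert round_sig(0.06789, 2) == 0.068
    assert round_sig(5.529, 2) == 5.5
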