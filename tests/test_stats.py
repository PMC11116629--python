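"""ROUT outlier removal, ANOVA/Tukey-Kramer, t-tests, normality checks."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from heartregen.stats import (
    normality_tests,
    one_way_anova_tukey,
    rout_outliers,
    ttest_unpaired,
    two_way_anova_tukey,
)


class TestRout:
    def test_identical_values_have_no_outliers(self):
        res = rout_outliers([5.0, 5.0, 5.0, 5.0])
        assert res.n_outliers == 0
        assert res.rsdr == 0.0

    def test_single_gross_outlier_flagged(self):
        # Brute-force oracle: robust centre ~1, RSDR from the inliers ~0.12,
        # so only |50 - 1| / 0.12 ~ 400 sigma exceeds any FDR cut.
        values = [1.0, 1.1, 0.9, 1.05, 0.95, 50.0]
        res = rout_outliers(values)
        np.testing.assert_array_equal(res.outlier_flag, [False] * 5 + [True])
        assert res.robust_center == pytest.approx(1.0, abs=0.02)

    def test_false_flag_rate_on_clean_normal_data(self):
        x = np.random.default_rng(123).standard_normal(10_000)
        res = rout_outliers(x, q=0.01)
        assert res.outlier_flag.mean() <= 0.02

    def test_stable_on_clean_remainder(self):
        values = np.array([1.0, 1.1, 0.9, 1.05, 0.95, 1.02, 0.97, 50.0])
        first = rout_outliers(values)
        remainder = values[~first.outlier_flag]
        second = rout_outliers(remainder)
        assert second.n_outliers == 0

    def test_invariant_to_input_order(self, rng):
        values = np.array([1.0, 1.1, 0.9, 1.05, 0.95, 50.0, 1.02])
        perm = rng.permutation(len(values))
        res1 = rout_outliers(values)
        res2 = rout_outliers(values[perm])
        np.testing.assert_array_equal(res1.outlier_flag[perm], res2.outlier_flag)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rout_outliers([1.0, 2.0])
        with pytest.raises(ValueError):
            rout_outliers([1.0, 2.0, 3.0], q=0.0)


def _two_way_table(rng, n=8, effects=None):
    rows = []
    effects = effects or {}
    for g in ("a", "b", "c"):
        for tp in ("TP1", "TP2", "TP3"):
            mu = effects.get((g, tp), 0.0)
            for v in mu + rng.standard_normal(n):
                rows.append({"normalized_area": v, "group": g, "timepoint": tp})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_df_bookkeeping_and_balanced_type_identity(self, rng):
        df = _two_way_table(rng)
        res2 = two_way_anova_tukey(df, ss_type=2)
        res1 = two_way_anova_tukey(df, ss_type=1)
        assert res2.table["df"].sum() == len(df) - 1
        for effect in ("group", "timepoint", "group:timepoint"):
            assert res2.table.loc[effect, "sum_sq"] == pytest.approx(res1.table.loc[effect, "sum_sq"])

    def test_null_data_interaction_not_significant(self, rng):
        res = two_way_anova_tukey(_two_way_table(rng, n=10))
        assert res.table.loc["group:timepoint", "PR(>F)"] > 0.01
        assert ((res.comparisons["p_adj"] >= 0) & (res.comparisons["p_adj"] <= 1)).all()

    def test_strong_group_effect_detected_within_timepoint(self, rng):
        df = _two_way_table(rng, n=10, effects={("a", "TP1"): 5.0})
        res = two_way_anova_tukey(df)
        comp = res.comparisons
        at_tp1 = comp[(comp["timepoint"] == "TP1") & (comp["group1"] == "a")]
        assert (at_tp1["p_adj"] < 0.001).all()

    def test_empty_cell_reported(self, rng):
        df = _two_way_table(rng)
        df = df[~((df["group"] == "b") & (df["timepoint"] == "TP2"))]
        with pytest.raises(ValueError, match="empty design cells"):
            two_way_anova_tukey(df)

    def test_pvalues_match_statsmodels_tukeyhsd_on_one_way(self, rng):
        # independent cross-check of the Tukey-Kramer computation
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate([rng.normal(0, 1, 12), rng.normal(1, 1, 9), rng.normal(0.5, 1, 15)])
        groups = np.array(["a"] * 12 + ["b"] * 9 + ["c"] * 15)
        mine = one_way_anova_tukey(values, groups)
        ref = pairwise_tukeyhsd(values, groups)
        np.testing.assert_allclose(np.sort(mine.comparisons["p_adj"]), np.sort(ref.pvalues), atol=1e-6)


class TestOneWayAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 12)
        res = one_way_anova_tukey(np.concatenate([a, b]), ["a"] * 10 + ["b"] * 12)
        t, _, p_t = ttest_unpaired(a, b)
        assert res.table.loc["group", "F"] == pytest.approx(t**2, rel=1e-10)
        assert res.table.loc["group", "PR(>F)"] == pytest.approx(p_t, rel=1e-10)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(200):
            vals = rng.standard_normal(30)
            res = one_way_anova_tukey(vals, np.repeat(["a", "b", "c"], 10))
            ps.append(res.table.loc["group", "PR(>F)"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_shifted_group_flagged_in_both_comparisons(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0, 1, 12), rng.normal(0, 1, 12), rng.normal(3, 1, 12)])
        res = one_way_anova_tukey(vals, np.repeat(["a", "b", "c"], 12))
        comp = res.comparisons
        involving_c = comp[(comp["group1"] == "c") | (comp["group2"] == "c")]
        assert (involving_c["p_adj"] < 0.01).all()
        other = comp[(comp["group1"] != "c") & (comp["group2"] != "c")]
        assert (other["p_adj"] > 0.01).all()

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            one_way_anova_tukey([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestTtest:
    def test_identical_samples(self):
        t, df, p = ttest_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, df, p) == (0.0, 4.0, 1.0)

    def test_matches_closed_form_on_three_point_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([11.01, 12.0, 12.99])
        t, df, p = ttest_unpaired(a, b)
        sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert df == 4.0
        assert p == pytest.approx(2 * sps.t.sf(abs(t_hand), 4), abs=1e-12)
        assert p < 0.001

    def test_zero_variance_limits(self):
        assert ttest_unpaired([2.0, 2.0], [2.0, 2.0]) == (0.0, 2.0, 1.0)
        t, _, p = ttest_unpaired([2.0, 2.0], [3.0, 3.0])
        assert math.isinf(t) and p == 0.0

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(11)
        a = rng.standard_normal((1000, 20))
        b = rng.standard_normal((1000, 20))
        res = sps.ttest_ind(a, b, axis=1)
        # sanity: vectorized scipy agrees with our scalar wrapper on one row
        t0, _, p0 = ttest_unpaired(a[0], b[0])
        assert t0 == pytest.approx(res.statistic[0])
        rate = float((res.pvalue < 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_welch_reduces_df(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0, 5, 25)
        _, df_w, _ = ttest_unpaired(a, b, welch=True)
        assert df_w < 33


class TestNormality:
    def test_normal_samples_rarely_rejected(self):
        rng = np.random.default_rng(5)
        ok = 0
        for _ in range(100):
            res = normality_tests(rng.standard_normal(100))
            ok += (res.anderson_darling_p > 0.01) and (res.shapiro_p > 0.01)
        assert ok >= 95

    def test_exponential_samples_rejected(self):
        rng = np.random.default_rng(6)
        bad = 0
        for _ in range(100):
            res = normality_tests(rng.exponential(1.0, 100))
            bad += (res.anderson_darling_p < 0.01) and (res.shapiro_p < 0.01)
        assert bad >= 95

    def test_small_or_constant_samples_reported_missing(self):
        assert not normality_tests([1.0, 2.0, 3.0, 4.0, 5.0]).available
        assert not normality_tests(np.ones(50)).available
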