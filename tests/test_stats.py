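"""Statistics layer: pooled t tests, ANOVA, Bonferroni, ANCOVA, slope tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from oracles import anova_2x2_oracle
from rodflux.stats import (
    GroupSummary,
    ancova_one_way,
    bonferroni_posthoc,
    regression_slope_test,
    t_from_summary,
    t_test,
    two_way_anova,
)


class TestTFromSummary:
    def test_conductance_density_groups(self):
        res = t_from_summary(GroupSummary(14.50, 2.80, 5), GroupSummary(6.62, 3.29, 5))
        assert res.t == pytest.approx(1.82, abs=0.01)
        assert res.df == 8

    def test_unequal_n_kd_groups(self):
        res = t_from_summary(GroupSummary(990.25, 137.58, 8), GroupSummary(932.79, 203.36, 14))
        assert res.t == pytest.approx(0.198, abs=0.001)
        assert res.df == 20

    def test_identical_groups(self):
        g = GroupSummary(5.0, 1.0, 10)
        res = t_from_summary(g, g)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_pooled_equals_welch_for_equal_n(self, rng):
        for _ in range(20):
            m1, m2 = rng.normal(0, 5, 2)
            s1, s2 = rng.uniform(0.5, 3, 2)
            g1, g2 = GroupSummary(m1, s1, 9), GroupSummary(m2, s2, 9)
            assert t_from_summary(g1, g2, "pooled").t == pytest.approx(
                t_from_summary(g1, g2, "welch").t
            )

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            GroupSummary(1.0, 0.5, 1)


class TestTTest:
    def test_consistency_with_summary_path(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.4, 1.3, 11)
        raw = t_test(a, b)
        summ = t_from_summary(GroupSummary.from_samples(a), GroupSummary.from_samples(b))
        assert raw.t == pytest.approx(summ.t)
        assert raw.p == pytest.approx(summ.p)

    def test_degenerate_variance_flagged(self):
        res = t_test([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res.degenerate
        assert res.p == 1.0

    def test_type_one_error_rate(self, rng):
        """Under the null the rejection rate at alpha=0.05 is 0.05 +/- 0.02."""
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            if t_test(rng.normal(0, 1, 10), rng.normal(0, 1, 12)).p < 0.05:
                rejections += 1
        assert abs(rejections / n_rep - 0.05) <= 0.02

    def test_power_monotone_in_shift(self, rng):
        rates = []
        for shift in (0.0, 0.7, 1.5):
            rej = sum(
                t_test(rng.normal(0, 1, 12), rng.normal(shift, 1, 12)).p < 0.05
                for _ in range(150)
            )
            rates.append(rej / 150)
        assert rates[0] < rates[1] < rates[2]


def balanced_2x2(rng, effect_a=0.0, effect_b=0.0, n=6):
    rows = []
    for ga, a in (("WT", 0.0), ("MUT", effect_a)):
        for gb, b in (("K10", 0.0), ("K40", effect_b)):
            for v in rng.normal(a + b, 1.0, n):
                rows.append({"value": v, "genotype": ga, "k_level": gb})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_matches_closed_form_oracle(self, rng):
        tab = balanced_2x2(rng, effect_a=1.0, effect_b=0.5)
        res = two_way_anova(tab)
        oracle = anova_2x2_oracle(tab)
        for key, f in oracle.items():
            assert res.effects[key].f == pytest.approx(f, rel=1e-9)

    def test_collapsed_factor_reduces_to_one_way(self, rng):
        tab = balanced_2x2(rng, effect_a=1.0)
        tab = tab[tab["k_level"] == "K10"].reset_index(drop=True)
        res = two_way_anova(tab)
        f_one_way, _ = sp_stats.f_oneway(
            tab.loc[tab["genotype"] == "WT", "value"], tab.loc[tab["genotype"] == "MUT", "value"]
        )
        assert res.effects["genotype"].f == pytest.approx(f_one_way, rel=1e-9)

    def test_both_factors_constant_rejected(self):
        tab = pd.DataFrame({"value": [1.0, 2.0], "genotype": ["WT", "WT"], "k_level": ["K10", "K10"]})
        with pytest.raises(ValueError):
            two_way_anova(tab)

    def test_empty_cell_reported(self, rng):
        tab = balanced_2x2(rng)
        tab = tab[~((tab["genotype"] == "WT") & (tab["k_level"] == "K40"))]
        with pytest.raises(ValueError, match="empty"):
            two_way_anova(tab)

    def test_null_p_values_roughly_uniform(self, rng):
        """Null simulation: genotype-effect p approximately uniform (KS check)."""
        ps = [two_way_anova(balanced_2x2(rng, n=4)).effects["genotype"].p for _ in range(300)]
        assert sp_stats.kstest(ps, "uniform").pvalue > 0.01


class TestBonferroni:
    def test_single_comparison_unchanged(self, rng):
        tab = balanced_2x2(rng, effect_a=1.0)
        res = two_way_anova(tab)
        out = bonferroni_posthoc(tab, res, [(("WT", "K10"), ("MUT", "K10"))])
        assert out[0].p_adjusted == pytest.approx(out[0].p_raw)

    def test_k_comparisons_scale_p(self, rng):
        tab = balanced_2x2(rng, effect_a=1.0)
        res = two_way_anova(tab)
        comp = (("WT", "K10"), ("MUT", "K10"))
        out = bonferroni_posthoc(tab, res, [comp, comp, comp])
        assert out[0].p_adjusted == pytest.approx(min(1.0, 3 * out[0].p_raw))

    def test_absent_cell_rejected(self, rng):
        tab = balanced_2x2(rng)
        res = two_way_anova(tab)
        with pytest.raises(ValueError):
            bonferroni_posthoc(tab, res, [(("WT", "K99"), ("MUT", "K10"))])

    def test_detects_effect_only_at_high_k(self, rng):
        # true genotype difference only in the K40 cell
        rows = []
        for ga, eff in (("WT", 0.0), ("MUT", -2.0)):
            for gb in ("K10", "K40"):
                mu = eff if gb == "K40" else 0.0
                for v in rng.normal(mu, 1.0, 15):
                    rows.append({"value": v, "genotype": ga, "k_level": gb})
        tab = pd.DataFrame(rows)
        res = two_way_anova(tab)
        out = bonferroni_posthoc(
            tab, res, [(("WT", "K10"), ("MUT", "K10")), (("WT", "K40"), ("MUT", "K40"))]
        )
        assert out[0].p_adjusted > 0.05
        assert out[1].p_adjusted < 0.01


class TestAncova:
    def test_zero_forced_slope_equals_one_way_anova(self, rng):
        y = rng.normal(0, 1, 30)
        g = np.repeat(["A", "B", "C"], 10)
        x = rng.normal(0, 1, 30)
        res = ancova_one_way(y, g, x, force_slope=0.0)
        f_one_way, p_one_way = sp_stats.f_oneway(y[g == "A"], y[g == "B"], y[g == "C"])
        assert res.f == pytest.approx(f_one_way, rel=1e-9)
        assert res.p == pytest.approx(p_one_way, rel=1e-9)

    def test_matches_brute_force_nested_models(self, rng):
        n = 40
        g = np.repeat(["A", "B"], n // 2)
        x = rng.normal(0, 1, n)
        y = 0.8 * x + (g == "B") * 0.9 + rng.normal(0, 1, n)
        res = ancova_one_way(y, g, x)
        # independent oracle: residual sums of squares via lstsq design matrices
        d_full = np.column_stack([np.ones(n), g == "B", x])
        d_red = np.column_stack([np.ones(n), x])
        rss_f = np.sum((y - d_full @ np.linalg.lstsq(d_full, y, rcond=None)[0]) ** 2)
        rss_r = np.sum((y - d_red @ np.linalg.lstsq(d_red, y, rcond=None)[0]) ** 2)
        f_oracle = (rss_r - rss_f) / (rss_f / (n - 3))
        assert res.f == pytest.approx(f_oracle, rel=1e-9)

    def test_homogeneity_pretest_rejects_unequal_slopes(self, rng):
        n = 60
        g = np.repeat(["A", "B"], n // 2)
        x = rng.uniform(0, 2, n)
        slope = np.where(g == "A", 0.2, 2.0)
        y = slope * x + rng.normal(0, 0.3, n)
        res = ancova_one_way(y, g, x)
        assert res.homogeneity_p < 0.01

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            ancova_one_way([1.0, 2.0, 3.0, 4.0], ["A", "A", "B", "B"], [1.0, 1.0, 1.0, 1.0])


class TestRegressionSlope:
    def test_exact_line_flagged(self):
        res = regression_slope_test([0.0, 1.0, 2.0, 3.0], [1.0, 3.0, 5.0, 7.0])
        assert res.exact
        assert np.isinf(res.t)
        assert res.p == 0.0
        assert res.df == 2

    def test_null_rejection_rate(self, rng):
        n_rep = 500
        rej = 0
        for _ in range(n_rep):
            x = rng.uniform(0, 1, 12)
            y = rng.normal(0, 1, 12)
            if regression_slope_test(x, y).p < 0.05:
                rej += 1
        assert abs(rej / n_rep - 0.05) <= 0.02

    def test_expected_t_monte_carlo(self, rng):
        # n=14 design with slope/noise chosen so E[t] ~ 3.5
        x = np.linspace(0, 1, 14)
        sxx = np.sqrt(np.sum((x - x.mean()) ** 2))
        sigma = 0.2
        slope = 3.5 * sigma / sxx
        ts = []
        for _ in range(400):
            y = slope * x + rng.normal(0, sigma, 14)
            ts.append(regression_slope_test(x, y).t)
        assert np.mean(ts) == pytest.approx(3.5, abs=0.35)

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            regression_slope_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
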