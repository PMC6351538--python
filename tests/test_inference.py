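"""Transforms, stratified ANOVAs, per-site t-tests, EF-rainfall regression."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from patchflux.inference import (
    DesignError,
    RegressionError,
    TransformError,
    blocked_oneway_anova,
    regress_ef_on_rainfall,
    site_ttest,
    splitplot_anova,
    transform_response,
    transformed_values,
)


def splitplot_frame(y, blocks=2, mains=2, subs=2, reps=1):
    rows = []
    it = iter(np.asarray(y, dtype=float).ravel())
    for b in range(blocks):
        for a in range(mains):
            for n in range(subs):
                for r in range(reps):
                    rows.append(
                        {"location": f"L{b}", "condition": f"C{a}",
                         "nitrogen": f"N{n}", "y": next(it)}
                    )
    return pd.DataFrame(rows)


class TestTransforms:
    def test_log_of_one_with_zero_offset(self):
        (t,) = transform_response([1.0], "log_offset", 0.0)
        assert t.transformed == 0.0 and t.param == 0.0

    def test_log_offset_calculator_example(self):
        (t,) = transform_response([0.02], "log_offset", 0.01)
        assert t.transformed == pytest.approx(math.log(0.03), rel=1e-12)
        assert t.transformed == pytest.approx(-3.5066, abs=1e-4)

    def test_sqrt_without_shift(self):
        (t,) = transform_response([4.0], "sqrt_shift", 0.0)
        assert t.transformed == 2.0

    def test_default_log_offset_is_half_smallest_positive(self):
        ts = transform_response([2.0, 0.5, 8.0], "log_offset")
        assert all(t.param == 0.25 for t in ts)
        assert ts[1].transformed == pytest.approx(math.log(0.75))

    def test_default_sqrt_shift_zeroes_the_minimum(self):
        ts = transform_response([-0.3, 0.1, 2.0], "sqrt_shift")
        assert ts[0].param == pytest.approx(0.3)
        assert ts[0].transformed == 0.0

    def test_nonpositive_after_offset_raises_with_location(self):
        with pytest.raises(TransformError, match="index 1"):
            transform_response([1.0, -0.5], "log_offset", 0.1)


class TestSplitPlotAnova:
    def test_all_equal_responses_give_zero_ss_and_undefined_f(self):
        table = splitplot_anova(splitplot_frame([7.0] * 16, reps=2))
        assert (table["sum_sq"] == 0).all()
        assert table["F"].isna().all()

    def test_degrees_of_freedom_sum_to_n_minus_1(self):
        rng = np.random.default_rng(0)
        d = splitplot_frame(rng.normal(size=3 * 2 * 2 * 4), blocks=3, reps=4)
        table = splitplot_anova(d)
        assert table["df"].sum() == len(d) - 1

    def test_ss_decomposition_sums_to_total(self):
        rng = np.random.default_rng(1)
        d = splitplot_frame(rng.normal(size=4 * 2 * 2 * 3), blocks=4, reps=3)
        table = splitplot_anova(d)
        total = float(((d["y"] - d["y"].mean()) ** 2).sum())
        assert table["sum_sq"].sum() == pytest.approx(total, rel=1e-9)

    def test_matches_brute_force_marginal_means_oracle(self):
        """Small integer dataset: SS from first-principles marginal means."""
        # 2 locations x 2 conditions x 2 N levels x 2 reps
        y = np.array(
            [[[ [3, 5], [8, 6] ], [ [2, 4], [9, 7] ]],
             [[[ 4, 6], [10, 8] ], [ [1, 3], [7, 9] ]]], dtype=float
        )  # shape (b, a, n, r)
        d = splitplot_frame(y, blocks=2, reps=2)
        table = splitplot_anova(d).set_index("source")

        grand = y.mean()
        ss_block = 2 * 2 * 2 * ((y.mean(axis=(1, 2, 3)) - grand) ** 2).sum()
        ss_main = 2 * 2 * 2 * ((y.mean(axis=(0, 2, 3)) - grand) ** 2).sum()
        m_ba = y.mean(axis=(2, 3))
        ss_mpe = 2 * 2 * (
            (m_ba - y.mean(axis=(1, 2, 3))[:, None] - y.mean(axis=(0, 2, 3))[None, :] + grand) ** 2
        ).sum()
        ss_sub = 2 * 2 * 2 * ((y.mean(axis=(0, 1, 3)) - grand) ** 2).sum()
        m_an = y.mean(axis=(0, 3))
        ss_int = 2 * 2 * (
            (m_an - y.mean(axis=(0, 2, 3))[:, None] - y.mean(axis=(0, 1, 3))[None, :] + grand) ** 2
        ).sum()
        assert table.loc["Location", "sum_sq"] == pytest.approx(ss_block, rel=1e-12)
        assert table.loc["Condition", "sum_sq"] == pytest.approx(ss_main, rel=1e-12)
        assert table.loc["MainPlotError", "sum_sq"] == pytest.approx(ss_mpe, rel=1e-12)
        assert table.loc["Nitrogen", "sum_sq"] == pytest.approx(ss_sub, rel=1e-12)
        assert table.loc["Condition:Nitrogen", "sum_sq"] == pytest.approx(ss_int, rel=1e-12)
        # declared error strata
        assert table.loc["Condition", "F"] == pytest.approx(
            (ss_main / 1) / (ss_mpe / 1), rel=1e-12
        )

    def test_matches_statsmodels_type1_on_balanced_data(self):
        """Independent cross-check: OLS sequential SS on a balanced design."""
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(7)
        d = splitplot_frame(rng.normal(size=5 * 2 * 3 * 2), blocks=5, subs=3, reps=2)
        ours = splitplot_anova(d).set_index("source")
        fit = smf.ols(
            "y ~ C(location) + C(condition) + C(location):C(condition)"
            " + C(nitrogen) + C(condition):C(nitrogen)",
            data=d,
        ).fit()
        sm_tab = anova_lm(fit, typ=1)
        pairs = {
            "Location": "C(location)",
            "Condition": "C(condition)",
            "MainPlotError": "C(location):C(condition)",
            "Nitrogen": "C(nitrogen)",
            "Condition:Nitrogen": "C(condition):C(nitrogen)",
            "Residual": "Residual",
        }
        for ours_name, sm_name in pairs.items():
            assert ours.loc[ours_name, "sum_sq"] == pytest.approx(
                float(sm_tab.loc[sm_name, "sum_sq"]), rel=1e-9
            )
            assert ours.loc[ours_name, "df"] == int(sm_tab.loc[sm_name, "df"])

    def test_single_location_raises(self):
        with pytest.raises(DesignError):
            splitplot_anova(splitplot_frame(np.arange(8.0), blocks=1, reps=2))

    def test_empty_cell_raises(self):
        d = splitplot_frame(np.arange(16.0), reps=2)
        with pytest.raises(DesignError):
            splitplot_anova(d.iloc[:-2])

    def test_condition_p_consistent_with_restricted_permutation(self):
        """Parametric p vs exact within-location label-swap permutation."""
        rng = np.random.default_rng(42)
        b, r = 6, 2
        d = splitplot_frame(rng.normal(size=b * 2 * 2 * r), blocks=b, reps=r)
        d.loc[d["condition"] == "C0", "y"] += 0.8  # moderate effect
        obs = splitplot_anova(d).set_index("source").loc["Condition", "F"]
        f_perm = []
        for flips in itertools.product([False, True], repeat=b):
            perm = d.copy()
            for i, flip in enumerate(flips):
                if flip:
                    mask = perm["location"] == f"L{i}"
                    perm.loc[mask, "condition"] = perm.loc[mask, "condition"].map(
                        {"C0": "C1", "C1": "C0"}
                    )
            f_perm.append(splitplot_anova(perm).set_index("source").loc["Condition", "F"])
        p_perm = float(np.mean(np.asarray(f_perm) >= obs - 1e-12))
        p_param = splitplot_anova(d).set_index("source").loc["Condition", "p"]
        assert abs(p_param - p_perm) < 0.15


class TestBlockedOneWayAnova:
    def frame(self, y, blocks, treats, reps=1):
        rows = []
        it = iter(np.asarray(y, dtype=float).ravel())
        for b in range(blocks):
            for t in range(treats):
                for _ in range(reps):
                    rows.append({"location": f"L{b}", "condition": f"T{t}", "y": next(it)})
        return pd.DataFrame(rows)

    def test_identical_treatment_values_give_zero_f(self):
        # treatment marginal means equal, some within-block scatter left
        d = self.frame([1, 2, 2, 1, 5, 5], blocks=3, treats=2)
        table = blocked_oneway_anova(d).set_index("source")
        assert table.loc["Condition", "sum_sq"] == 0.0
        assert table.loc["Condition", "F"] == 0.0

    def test_hand_rcbd_oracle(self):
        # 3 blocks x 2 treatments, integers: y = [[2,4],[3,7],[4,6]]
        # grand=4.3333; SS_block = 2*((3-ybar)^2+(5-ybar)^2+(5-ybar)^2) = 2*(16/9+4/9+4/9)
        d = self.frame([2, 4, 3, 7, 4, 6], blocks=3, treats=2)
        table = blocked_oneway_anova(d).set_index("source")
        ybar = 26 / 6
        ss_block = 2 * ((3 - ybar) ** 2 + (5 - ybar) ** 2 + (5 - ybar) ** 2)
        ss_treat = 3 * ((3 - ybar) ** 2 + (17 / 3 - ybar) ** 2)
        ss_total = sum((v - ybar) ** 2 for v in [2, 4, 3, 7, 4, 6])
        assert table.loc["Location", "sum_sq"] == pytest.approx(ss_block, rel=1e-12)
        assert table.loc["Condition", "sum_sq"] == pytest.approx(ss_treat, rel=1e-12)
        assert table.loc["Residual", "sum_sq"] == pytest.approx(
            ss_total - ss_block - ss_treat, rel=1e-12
        )
        assert table["df"].tolist() == [2, 1, 2]

    def test_f_equals_paired_t_squared(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=6)
        b = a + rng.normal(0.5, 0.4, size=6)
        d = self.frame(np.column_stack([a, b]), blocks=6, treats=2)
        table = blocked_oneway_anova(d).set_index("source")
        t_res = stats.ttest_rel(a, b)
        assert table.loc["Condition", "F"] == pytest.approx(t_res.statistic**2, rel=1e-10)
        assert table.loc["Condition", "p"] == pytest.approx(t_res.pvalue, rel=1e-10)

    def test_missing_cell_raises(self):
        d = self.frame([1, 2, 3, 4], blocks=2, treats=2).iloc[:-1]
        with pytest.raises(DesignError):
            blocked_oneway_anova(d)


class TestSiteTTest:
    def test_identical_groups(self):
        res = site_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], site_id="s")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.letters == ("a", "a")

    def test_zero_variance_equal_means_convention(self):
        res = site_ttest([2.0, 2.0], [2.0, 2.0])
        assert (res.statistic, res.p) == (0.0, 1.0)

    def test_separated_groups_get_different_letters(self):
        res = site_ttest([101.0, 102.0, 103.0], [1.0, 2.0, 3.0])
        assert res.p < 0.001
        assert res.letters == ("a", "b")

    def test_pooled_t_matches_closed_form(self):
        x, z = [1.0, 2.0, 4.0], [3.0, 5.0, 7.0, 9.0]
        res = site_ttest(x, z)
        nx, nz = 3, 4
        sp2 = ((nx - 1) * np.var(x, ddof=1) + (nz - 1) * np.var(z, ddof=1)) / (nx + nz - 2)
        t_expect = (np.mean(x) - np.mean(z)) / math.sqrt(sp2 * (1 / nx + 1 / nz))
        assert res.statistic == pytest.approx(t_expect, rel=1e-12)
        assert res.df == nx + nz - 2

    def test_type_i_error_near_alpha_under_null(self):
        """n=5 per group, 2000 null simulations: rejection rate ~ 5%."""
        rng = np.random.default_rng(99)
        rej = 0
        sims = 2000
        for _ in range(sims):
            if site_ttest(rng.normal(size=5), rng.normal(size=5)).p < 0.05:
                rej += 1
        assert abs(rej / sims - 0.05) < 0.02

    def test_welch_differs_under_variance_imbalance(self):
        x = [0.0, 0.1, 0.2, 0.1, 0.0]
        z = [5.0, -3.0, 9.0, -6.0, 4.0]
        pooled = site_ttest(x, z)
        welch = site_ttest(x, z, welch=True)
        assert pooled.df != welch.df


class TestRainfallRegression:
    def test_exact_linear_relationship_recovered(self):
        rain = [100, 200, 300, 400, 500]
        ef = [0.05 + 0.0086 * r for r in rain]
        reg = regress_ef_on_rainfall(ef, rain, condition="LVC")
        assert reg.slope == pytest.approx(0.0086, rel=1e-12)
        assert reg.intercept == pytest.approx(0.05, rel=1e-9)
        assert reg.r_squared == pytest.approx(1.0)

    def test_constant_ef_gives_zero_slope_and_r2(self):
        reg = regress_ef_on_rainfall([0.3, 0.3, 0.3, 0.3], [10, 20, 30, 40])
        assert (reg.slope, reg.r_squared) == (0.0, 0.0)

    def test_simulated_recovery_of_generating_slope(self):
        """7 sites generated at slope 0.0086 + noise: estimate within 10%."""
        rng = np.random.default_rng(5)
        rain = np.linspace(80, 600, 7)
        ef = 0.02 + 0.0086 * rain + rng.normal(0, 0.05, size=7)
        reg = regress_ef_on_rainfall(ef, rain, condition="LVC")
        assert abs(reg.slope - 0.0086) / 0.0086 < 0.10

    def test_too_few_sites_raises(self):
        with pytest.raises(RegressionError):
            regress_ef_on_rainfall([0.1, 0.2], [10, 20])


def test_transformed_values_roundtrip_invertible():
    vals = np.array([0.02, -0.1, 3.0, 0.5])
    out = transform_response(vals, "sqrt_shift")
    s = out[0].param
    back = np.array([t.transformed**2 - s for t in out])
    np.testing.assert_allclose(back, vals, atol=1e-12)
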