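import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdxtrial import (
    TrialDataError,
    adjust_pvalues,
    endpoint_values,
    fit_lmm,
    mixed_anova,
    one_way_test,
    permutation_curve_test,
    scheirer_ray_hare,
)
from pdxtrial.trial_data import TrialDataset
from conftest import make_trial


class TestEndpoints:
    def test_slope_log_exact_on_exponential_growth(self):
        days = [0, 7, 14]
        ds = make_trial({"A": [[100 * np.exp(0.1 * d) for d in days]]}, days,
                        control=None)
        vals = endpoint_values(ds, "growth_rate", "slope_log")
        assert vals["value"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_constant_volume_rate_zero_all_methods(self):
        ds = make_trial({"A": [[100, 100, 100]]}, [0, 7, 14], control=None)
        for m in ("slope_log", "ratio_log", "diff"):
            assert endpoint_values(ds, "growth_rate", m)["value"].iloc[0] == \
                pytest.approx(0.0, abs=1e-12)

    def test_ratio_log_arithmetic(self):
        ds = make_trial({"A": [[100, 400]]}, [0, 21], control=None)
        vals = endpoint_values(ds, "growth_rate", "ratio_log")
        assert vals["value"].iloc[0] == pytest.approx(np.log(4) / 21)

    def test_nonpositive_volume_excluded_under_log(self):
        ds = make_trial({"A": [[100, 0, 50], [100, 110, 120]]}, [0, 7, 14],
                        control=None)
        vals = endpoint_values(ds, "growth_rate", "slope_log")
        assert len(vals) == 1
        assert vals.attrs["excluded"][0][3] == "non-positive volume"

    def test_end_volume_uses_last_shared_day(self):
        ds = make_trial({"A": [[100, 150, 200], [100, 160, 210]]}, [0, 7, 14],
                        control=None)
        vals = endpoint_values(ds, "end_volume")
        assert sorted(vals["value"]) == [200, 210]


class TestOneWay:
    def test_identical_groups_give_f_zero_p_one(self):
        r = one_way_test({"A": [1, 2, 3], "B": [1, 2, 3]})
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_kruskal_wallis_closed_form_oracle(self):
        # ranks 1..6 without ties: H = 12/(6*7) * (36/3 + 225/3) - 3*7
        r = one_way_test({"A": [1, 2, 3], "B": [4, 5, 6]}, parametric=False)
        expected = 12 / (6 * 7) * (6**2 / 3 + 15**2 / 3) - 3 * 7
        assert r.statistic == pytest.approx(expected)
        assert r.df == (1.0,)

    def test_constant_data_degenerates(self):
        with pytest.raises(TrialDataError, match="identical"):
            one_way_test({"A": [5, 5], "B": [5, 5]})
        r = one_way_test({"A": [5, 5], "B": [5, 5]}, parametric=False)
        assert (r.statistic, r.p_value) == (0.0, 1.0)

    def test_kw_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.normal(size=7) for k in "ABC"}
        h1 = one_way_test(groups, parametric=False).statistic
        h2 = one_way_test(
            {k: np.exp(3 * v) for k, v in groups.items()}, parametric=False
        ).statistic
        assert h1 == pytest.approx(h2, abs=1e-12)


def _rank_anova_oracle(values, fa, fb):
    """Naive rank two-way ANOVA via OLS on a balanced grid."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"r": stats.rankdata(values), "a": fa, "b": fb})
    fit = smf.ols("r ~ C(a) * C(b)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    ms_total = df["r"].var(ddof=1)
    return {
        "A": tab.loc["C(a)", "sum_sq"] / ms_total,
        "B": tab.loc["C(b)", "sum_sq"] / ms_total,
        "A:B": tab.loc["C(a):C(b)", "sum_sq"] / ms_total,
    }


class TestScheirerRayHare:
    def test_single_level_second_factor_reduces_to_kruskal_wallis(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=30)
        fa = np.repeat(["a", "b", "c"], 10)
        fb = np.repeat(["only"], 30)
        r = scheirer_ray_hare(v, fa, fb)
        h, p = stats.kruskal(v[:10], v[10:20], v[20:])
        row = r.terms[r.terms["term"] == "A"].iloc[0]
        assert row["statistic"] == pytest.approx(h, abs=1e-9)
        assert row["p"] == pytest.approx(p, abs=1e-9)

    def test_constant_values_all_h_zero(self):
        r = scheirer_ray_hare([3.0] * 8, ["a", "a", "b", "b"] * 2,
                              ["x", "y"] * 4)
        assert (r.terms["statistic"] == 0).all()
        assert (r.terms["p"] == 1).all()

    def test_balanced_grid_matches_rank_anova_oracle(self):
        rng = np.random.default_rng(12)
        fa = np.repeat(["a", "b"], 8)
        fb = np.tile(np.repeat(["x", "y"], 4), 2)
        v = rng.normal(size=16) + (fa == "b") * 0.8
        r = scheirer_ray_hare(v, fa, fb)
        oracle = _rank_anova_oracle(v, fa, fb)
        for term, h in oracle.items():
            got = r.terms[r.terms["term"] == term]["statistic"].iloc[0]
            assert got == pytest.approx(h, abs=1e-9)

    def test_empty_cell_rejected(self):
        with pytest.raises(TrialDataError, match="empty cell"):
            scheirer_ray_hare([1, 2, 3], ["a", "a", "b"], ["x", "y", "x"])


class TestMixedAnova:
    def _balanced(self, offset_b=20.0, noise=True):
        rng = np.random.default_rng(3)
        days = [0, 7, 14]
        curves_a, curves_b = [], []
        for i in range(3):
            base = 100 + 5 * i
            eps = rng.normal(0, 4, size=3) if noise else np.zeros(3)
            curves_a.append([base + 10 * d / 7 + e for d, e in zip(days, eps)])
            eps = rng.normal(0, 4, size=3) if noise else np.zeros(3)
            curves_b.append([base + offset_b + 10 * d / 7 + e for d, e in zip(days, eps)])
        return make_trial({"A": curves_a, "B": curves_b}, days, control=None)

    def test_between_f_equals_anova_on_subject_means(self):
        ds = self._balanced()
        ma = mixed_anova(ds)
        means = ds.records.groupby(["arm", "animal_id"])["volume"].mean()
        groups = {a: v.to_numpy() for a, v in means.groupby(level="arm")}
        ow = one_way_test(groups, parametric=True)
        assert ma.statistic == pytest.approx(ow.statistic, abs=1e-9)

    def test_constant_offset_no_noise_has_null_interaction(self):
        ds = self._balanced(offset_b=50.0, noise=False)
        ma = mixed_anova(ds)
        inter = ma.terms[ma.terms["term"] == "Interaction"].iloc[0]["statistic"]
        # interaction SS is exactly 0; its F is 0 (or 0/0 when the day-by-subject
        # error is also degenerate)
        assert np.isnan(inter) or inter == pytest.approx(0.0, abs=1e-9)
        assert ma.p_value < 1e-3  # huge arm effect on (1, 4) df

    def test_single_animal_arm_rejected(self):
        ds = make_trial({"A": [[100, 120, 140]], "B": [[100, 90, 80]] * 2},
                        [0, 7, 14], control=None)
        with pytest.raises(TrialDataError, match="< 2 animals"):
            mixed_anova(ds)


class TestLMM:
    def test_zero_noise_recovers_exact_slope_difference(self):
        days = [0, 3, 6, 9, 12]
        g_ctrl, g_trt = 0.10, 0.04
        curves = {
            "Vehicle": [[(100 + 10 * i) * np.exp(g_ctrl * d) for d in days]
                        for i in range(3)],
            "Drug": [[(100 + 10 * i) * np.exp(g_trt * d) for d in days]
                     for i in range(3)],
        }
        ds = make_trial(curves, days)
        # raw log response without the +1 shift keeps the model exactly linear
        res = fit_lmm(ds, response_scale="log")
        est = res.terms[res.terms["arm"] == "Drug"]["estimate"].iloc[0]
        # ln(V+1) differs from ln V by < 1% at V >= 100
        assert est == pytest.approx(g_trt - g_ctrl, abs=2e-3)

    def test_identical_arms_contrast_near_zero(self):
        days = [0, 3, 6, 9]
        rng = np.random.default_rng(8)
        mk = lambda: [[100 * np.exp(0.08 * d + rng.normal(0, 0.03)) for d in days]
                      for _ in range(6)]
        ds = make_trial({"Vehicle": mk(), "Drug": mk()}, days)
        res = fit_lmm(ds)
        est = res.terms["estimate"].iloc[0]
        se = res.terms["se"].iloc[0]
        assert abs(est) < 4 * se


class TestPermutation:
    def test_exhaustive_oracle_complete_separation(self, separated_3v3):
        # C(6,3)=20 assignments; only the observed split and its mirror
        # attain the observed |mean t|
        res = permutation_curve_test(separated_3v3, n_perm=50, seed=0)
        row = res.pairs.iloc[0]
        assert row["exhaustive"]
        assert row["n_perm"] == 20
        assert row["p_raw"] == pytest.approx(2 / 20)

    def test_monte_carlo_agrees_with_exhaustive(self, monkeypatch):
        rng = np.random.default_rng(21)
        days = [0, 3, 6]
        mk = lambda shift: [
            [100 * np.exp((0.07 + shift) * d) * np.exp(rng.normal(0, 0.05))
             for d in days] for _ in range(6)
        ]
        ds = make_trial({"Vehicle": mk(0.0), "Drug": mk(-0.04)}, days)
        exact = permutation_curve_test(ds, seed=1).pairs.iloc[0]
        assert exact["exhaustive"]  # C(12,6) = 924 enumerable
        import pdxtrial.volume_stats as vs
        monkeypatch.setattr(vs, "EXHAUSTIVE_LIMIT", 1)
        mc = permutation_curve_test(ds, n_perm=10_000, seed=1).pairs.iloc[0]
        assert not mc["exhaustive"]
        p = exact["p_raw"]
        tol = 3 * np.sqrt(max(p, 1e-4) * (1 - p) / 10_000)
        assert abs(mc["p_raw"] - p) <= tol

    def test_row_order_and_seed_determinism(self, sim_1an):
        ds = sim_1an.subset(arms=["Vehicle", "Treatment_5"])
        p1 = permutation_curve_test(ds, n_perm=200, seed=7).pairs["p_raw"]
        shuffled = TrialDataset(
            ds.records.sample(frac=1, random_state=3), control_arm="Vehicle"
        )
        p2 = permutation_curve_test(shuffled, n_perm=200, seed=7).pairs["p_raw"]
        pd.testing.assert_series_equal(p1, p2)

    def test_all_constant_days_error(self):
        ds = make_trial({"A": [[100, 100]] * 2, "B": [[100, 100]] * 2}, [0, 7],
                        control=None)
        with pytest.raises(TrialDataError, match="every shared day"):
            permutation_curve_test(ds, seed=0)

    def test_pairs_cover_all_arm_combinations(self, sim_1an):
        res = permutation_curve_test(sim_1an, n_perm=50, seed=0)
        assert len(res.pairs) == 15  # C(6,2)
        assert (res.pairs["p_adjusted"] >= res.pairs["p_raw"] - 1e-15).all()


class TestAdjustment:
    def test_holm_hand_worked(self):
        # sorted (0.01,0.03,0.04) -> x(3,2,1) -> cummax -> (0.03,0.06,0.06)
        out = adjust_pvalues([0.01, 0.04, 0.03], method="holm")
        np.testing.assert_allclose(out, [0.03, 0.06, 0.06])

    @pytest.mark.parametrize("method", ["holm", "bonferroni", "BH"])
    def test_single_p_unchanged_and_ones_stay_one(self, method):
        assert adjust_pvalues([0.2], method=method)[0] == pytest.approx(0.2)
        assert (adjust_pvalues([1.0, 1.0, 1.0], method=method) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(TrialDataError):
            adjust_pvalues([0.5, 1.2])
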