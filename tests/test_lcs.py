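import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lcsmed as L
from lcsmed.lcs import (
    ChangeScoreSpec,
    LcsError,
    SingularityError,
    compute_change_scores,
    fit_equation,
)

# 8-row, 2-predictor fixture solved beforehand by explicit normal-equation
# arithmetic: beta = (XtX)^-1 Xty with RSS 0.6
FIX8 = pd.DataFrame(
    {
        "x1": [0, 1, 2, 3, 4, 5, 6, 7],
        "x2": [1, 0, 2, 1, 3, 2, 4, 3],
        "y": [1, 3, 2, 5, 4, 7, 6, 8],
    },
    dtype=float,
)
FIX8_BETA = {"intercept": 1.8, "x1": 1.4, "x2": -1.1}
FIX8_SE_ML = {"intercept": 0.18874586, "x1": 0.07071068, "x2": 0.13228757}
FIX8_SE_OLS = {"intercept": 0.23874673, "x1": 0.08944272, "x2": 0.16733201}


class TestChangeScores:
    def test_adjacent_differences(self):
        t = pd.DataFrame({"bdi_0": [20], "bdi_1": [15], "bdi_2": [10], "bdi_3": [5]})
        for f in range(3):
            d = compute_change_scores(t, ChangeScoreSpec("bdi", f, f + 1))
            assert d.iloc[0] == -5

    def test_constant_scores_zero_change(self):
        t = pd.DataFrame({f"bdi_{w}": [17, 30] for w in range(4)})
        assert (compute_change_scores(t, ChangeScoreSpec("bdi", 0, 3)) == 0).all()

    def test_missing_endpoint_propagates(self):
        t = pd.DataFrame({"bdi_1": [10.0, 12.0], "bdi_2": [np.nan, 14.0], "bdi_3": [5.0, 10.0]})
        d12 = compute_change_scores(t, ChangeScoreSpec("bdi", 1, 2))
        d23 = compute_change_scores(t, ChangeScoreSpec("bdi", 2, 3))
        assert np.isnan(d12.iloc[0]) and np.isnan(d23.iloc[0])
        assert d12.iloc[1] == 2 and d23.iloc[1] == -4

    def test_unknown_wave_and_backward_spec(self):
        t = pd.DataFrame({"bdi_0": [1.0]})
        with pytest.raises(LcsError):
            compute_change_scores(t, ChangeScoreSpec("bdi", 0, 3))
        with pytest.raises(LcsError):
            ChangeScoreSpec("bdi", 2, 1)


class TestCentering:
    def test_trial_arm_coding(self):
        # 50 treatment vs 53 control participants
        t = pd.DataFrame({"arm": [1] * 50 + [0] * 53})
        centered, consts = L.center_predictors(t, ["arm"])
        assert round(centered["arm"].iloc[0], 2) == 0.51
        assert round(centered["arm"].iloc[-1], 2) == -0.49
        assert consts["arm"] == pytest.approx(50 / 103)

    def test_centered_mean_is_zero(self, default_trial):
        table, _ = default_trial
        centered, _ = L.center_predictors(table, ["bdi_0", "bads_0"])
        assert centered["bdi_0"].mean() == pytest.approx(0.0, abs=1e-9)

    def test_constant_variable_centers_to_zero(self):
        t = pd.DataFrame({"x": [4.0, 4.0, 4.0]})
        centered, _ = L.center_predictors(t, ["x"])
        assert (centered["x"] == 0).all()

    def test_reference_mean_override(self):
        t = pd.DataFrame({"bdi_1": [10.0, 20.0]})
        centered, consts = L.center_predictors(t, ["bdi_1"], reference_means={"bdi_1": 30.0})
        assert consts["bdi_1"] == 30.0
        assert list(centered["bdi_1"]) == [-20.0, -10.0]

    def test_all_missing_rejected(self):
        t = pd.DataFrame({"x": [np.nan, np.nan]})
        with pytest.raises(LcsError):
            L.center_predictors(t, ["x"])


class TestFitEquation:
    def test_noiseless_line_exact(self):
        t = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0], "y": [0.0, 2.0, 4.0, 6.0]})
        eq = fit_equation(t, "y", ["x"])
        assert eq["x"].estimate == pytest.approx(2.0, abs=1e-12)
        assert eq["intercept"].estimate == pytest.approx(0.0, abs=1e-12)

    def test_frozen_normal_equations_fixture(self):
        eq_ml = fit_equation(FIX8, "y", ["x1", "x2"], se_method="ml")
        eq_ols = fit_equation(FIX8, "y", ["x1", "x2"], se_method="ols")
        for term, beta in FIX8_BETA.items():
            assert eq_ml[term].estimate == pytest.approx(beta, abs=1e-10)
            assert eq_ml[term].se == pytest.approx(FIX8_SE_ML[term], abs=1e-6)
            assert eq_ols[term].se == pytest.approx(FIX8_SE_OLS[term], abs=1e-6)

    def test_against_statsmodels(self, default_trial):
        import statsmodels.api as sm

        table, _ = default_trial
        work = table.assign(d03=table["bdi_3"] - table["bdi_0"])
        eq = fit_equation(work, "d03", ["arm", "bdi_0"], se_method="ols")
        X = sm.add_constant(work[["arm", "bdi_0"]])
        ref = sm.OLS(work["d03"], X).fit()
        assert eq["arm"].estimate == pytest.approx(ref.params["arm"], abs=1e-9)
        assert eq["bdi_0"].estimate == pytest.approx(ref.params["bdi_0"], abs=1e-9)
        assert eq["arm"].se == pytest.approx(ref.bse["arm"], rel=1e-6)

    def test_wald_inference_consistency(self, default_trial):
        table, _ = default_trial
        work = table.assign(d03=table["bdi_3"] - table["bdi_0"])
        eq = fit_equation(work, "d03", ["arm", "bdi_0"])
        zcrit = stats.norm.ppf(0.975)
        for e in eq.estimates:
            assert e.z == pytest.approx(e.estimate / e.se)
            assert e.p == pytest.approx(2 * stats.norm.sf(abs(e.z)))
            assert e.ci_low == pytest.approx(e.estimate - zcrit * e.se)
            assert e.ci_high == pytest.approx(e.estimate + zcrit * e.se)
            assert (e.p < 0.05) == (e.ci_low > 0 or e.ci_high < 0)

    def test_z_of_1_96_is_borderline(self):
        assert 2 * stats.norm.sf(1.96) == pytest.approx(0.05, abs=5e-4)

    def test_ml_vs_ols_se_ratio(self):
        eq_ml = fit_equation(FIX8, "y", ["x1", "x2"], se_method="ml")
        eq_ols = fit_equation(FIX8, "y", ["x1", "x2"], se_method="ols")
        n, p = 8, 3
        ratio = np.sqrt(n / (n - p))
        assert eq_ols["x1"].se == pytest.approx(eq_ml["x1"].se * ratio)

    def test_singularity_names_collinear_terms(self):
        t = FIX8.assign(x3=FIX8["x1"] * 2.0)
        with pytest.raises(SingularityError, match="x3"):
            fit_equation(t, "y", ["x1", "x2", "x3"])

    def test_listwise_equals_complete_without_missing(self):
        eq1 = fit_equation(FIX8, "y", ["x1", "x2"], missing="listwise")
        eq2 = fit_equation(FIX8, "y", ["x1", "x2"], missing="complete")
        assert [e.estimate for e in eq1.estimates] == [e.estimate for e in eq2.estimates]

    def test_complete_policy_rejects_missing(self):
        t = FIX8.copy()
        t.loc[0, "x1"] = np.nan
        with pytest.raises(LcsError):
            fit_equation(t, "y", ["x1", "x2"], missing="complete")

    def test_too_few_rows(self):
        with pytest.raises(LcsError):
            fit_equation(FIX8.head(3), "y", ["x1", "x2"])


class TestFiml:
    def test_complete_data_matches_listwise(self):
        eq_lw = fit_equation(FIX8, "y", ["x1", "x2"], missing="listwise", se_method="ml")
        eq_fi = fit_equation(FIX8, "y", ["x1", "x2"], missing="fiml")
        for term in ("intercept", "x1", "x2"):
            assert eq_fi[term].estimate == pytest.approx(eq_lw[term].estimate, abs=1e-6)
            assert eq_fi[term].se == pytest.approx(eq_lw[term].se, rel=0.15)

    def test_recovers_truth_under_random_missingness(self):
        rng = np.random.default_rng(8)
        n = 400
        x = rng.normal(0, 2, n)
        y = 1.0 + 0.5 * x + rng.normal(0, 1, n)
        t = pd.DataFrame({"x": x, "y": y})
        t.loc[rng.random(n) < 0.3, "y"] = np.nan
        t.loc[rng.random(n) < 0.2, "x"] = np.nan
        eq = fit_equation(t, "y", ["x"], missing="fiml")
        assert eq["x"].estimate == pytest.approx(0.5, abs=3 * eq["x"].se)
        assert eq.n == int((~t.isna().all(axis=1)).sum())


class TestChangeModel:
    def _noiseless_system(self):
        # each change equals its linear prediction plus a disturbance
        # orthogonalized against that equation's design, so OLS recovers
        # every coefficient exactly while designs stay full rank
        rng = np.random.default_rng(5)
        n = 60
        arm = np.tile([0, 1], n // 2)
        y0 = rng.normal(30, 6, n)
        tc = arm - arm.mean()
        l0 = y0 - y0.mean()
        ones = np.ones(n)

        def orth(e, X):
            return e - X @ np.linalg.lstsq(X, e, rcond=None)[0]

        truth = {
            "d01": {"intercept": -8.0, "treatment": -6.0, "level_0": -0.4},
            "d12": {"intercept": -3.0, "treatment": -2.0, "level_1": -0.3, "level_0": 0.1},
            "d23": {"intercept": -4.0, "treatment": -1.5, "level_2": -0.2, "level_0": 0.05},
        }
        X1 = np.column_stack([ones, tc, l0])
        d01 = X1 @ [truth["d01"]["intercept"], truth["d01"]["treatment"],
                    truth["d01"]["level_0"]] + orth(rng.normal(0, 3, n), X1)
        y1 = y0 + d01
        l1 = y1 - y0.mean()
        X2 = np.column_stack([ones, tc, l1, l0])
        d12 = X2 @ [truth["d12"]["intercept"], truth["d12"]["treatment"],
                    truth["d12"]["level_1"], truth["d12"]["level_0"]] \
            + orth(rng.normal(0, 3, n), X2)
        y2 = y1 + d12
        l2 = y2 - y0.mean()
        X3 = np.column_stack([ones, tc, l2, l0])
        d23 = X3 @ [truth["d23"]["intercept"], truth["d23"]["treatment"],
                    truth["d23"]["level_2"], truth["d23"]["level_0"]] \
            + orth(rng.normal(0, 3, n), X3)
        y3 = y2 + d23
        table = pd.DataFrame(
            {"arm": arm, "bdi_0": y0, "bdi_1": y1, "bdi_2": y2, "bdi_3": y3}
        )
        return table, truth

    def test_noiseless_exact_recovery(self):
        table, truth = self._noiseless_system()
        fit = L.fit_change_model(table)
        labels = {"level_0": "baseline level", "level_1": "1-month level",
                  "level_2": "2-month level", "treatment": "treatment",
                  "intercept": "intercept"}
        for eq_key, eq in zip(("balance", "d01", "d12", "d23"), fit.equations):
            if eq_key == "balance":
                continue
            for term, value in truth[eq_key].items():
                assert eq[labels[term]].estimate == pytest.approx(value, abs=1e-8)

    def test_balance_equation_near_zero_under_null(self):
        st_params = L.StructuralParameters(
            a={m: 0.0 for m in ("bads", "cds", "ptq")},
            b={m: 0.0 for m in ("bads", "cds", "ptq")},
            c_prime=0.0,
        )
        table, _ = L.generate_trial(
            L.SimulationConfig(n_participants=2000, structural=st_params, seed=17)
        )
        fit = L.fit_change_model(table)
        bal = fit.equations[0]["treatment"]
        assert abs(bal.estimate) < 3 * bal.se

    def test_slopes_invariant_to_centering(self, default_trial):
        table, _ = default_trial
        work = table.assign(d01=table["bdi_1"] - table["bdi_0"])
        raw = fit_equation(work, "d01", ["arm", "bdi_0"])
        centered, _ = L.center_predictors(work, ["arm", "bdi_0"])
        cen = fit_equation(centered, "d01", ["arm", "bdi_0"])
        assert cen["arm"].estimate == pytest.approx(raw["arm"].estimate, abs=1e-9)
        assert cen["bdi_0"].estimate == pytest.approx(raw["bdi_0"].estimate, abs=1e-9)
        assert cen["intercept"].estimate != pytest.approx(raw["intercept"].estimate, abs=1e-3)

    def test_listwise_reporting_per_equation(self, default_trial):
        table, _ = default_trial
        holed = L.apply_missingness(table, (0.9, 0.85, 0.8), seed=1)
        fit = L.fit_change_model(holed)
        ns = [eq.n for eq in fit.equations]
        assert ns[0] == len(table)  # baseline complete
        assert all(n <= len(table) for n in ns)
        assert fit.equations[3].n <= fit.equations[1].n + 30  # later waves thinner

    def test_missing_baseline_rejected(self, default_trial):
        table, _ = default_trial
        bad = table.copy()
        bad.loc[0, "bdi_0"] = np.nan
        with pytest.raises(LcsError, match="baseline"):
            L.fit_change_model(bad)
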