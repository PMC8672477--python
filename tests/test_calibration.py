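import numpy as np
import pytest

from helpers import grid_logistic, random_instance
from idiomval import OutcomeMode, cohort_preset, generate_cohort, linear_predictor
from idiomval.calibration import (
    SeparationError,
    fit_logistic,
    flexible_curve,
    group_calibration,
    mean_calibration,
    weak_calibration,
)
from idiomval.model import PUBLISHED_SCHEME
from idiomval.stratification import derive_ppv_quartile_scheme


def _counts_cohort(n, events, mean_risk):
    """Cohort with constant predicted risk and a fixed event count."""
    risks = np.full(n, mean_risk)
    outcomes = np.zeros(n, int)
    outcomes[:events] = 1
    return risks, outcomes


class TestMeanCalibration:
    def test_published_oxford_overestimation(self):
        """Mean predicted 8.5% against 86/1117 events is a 10% overestimate."""
        mc = mean_calibration(*_counts_cohort(1117, 86, 0.085))
        assert round(mc.relative_diff_pct) == 10

    def test_published_sheffield_underestimation(self):
        """Mean predicted 5.5% against 36/474 events is a 28% underestimate."""
        mc = mean_calibration(*_counts_cohort(474, 36, 0.055))
        assert round(mc.relative_diff_pct) == -28

    def test_perfectly_calibrated_means(self):
        mc = mean_calibration(*_counts_cohort(200, 50, 0.25))
        assert mc.relative_diff_pct == pytest.approx(0.0)
        assert mc.oe_ratio == pytest.approx(1.0)

    def test_oe_ratio_consistency_identity(self, rng):
        risks, outcomes = random_instance(rng, n_min=20, n_max=50)
        mc = mean_calibration(risks, outcomes)
        assert mc.oe_ratio == pytest.approx(
            mc.observed_prevalence / mc.mean_predicted, abs=1e-15
        )
        assert mc.oe_ratio == pytest.approx(
            1.0 / (1.0 + mc.relative_diff_pct / 100.0), abs=1e-12
        )

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            mean_calibration([], [])


class TestFitLogistic:
    def test_matches_grid_search_oracle_on_small_instances(self, rng):
        """IRLS equals an independent likelihood grid search to 1e-4."""
        checked = 0
        while checked < 20:
            n = int(rng.integers(6, 11))
            x = rng.normal(0.0, 1.0, n)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            try:
                fit = fit_logistic(y, covariate=x)
            except SeparationError:
                continue
            oracle = grid_logistic(y, covariate=x)
            assert np.all(np.abs(fit.coef - oracle) < 1e-4)
            checked += 1

    def test_offset_fit_matches_grid_search_oracle(self, rng):
        y = np.array([1, 0, 0, 1, 0, 0, 1, 0])
        offset = rng.normal(-1.0, 0.8, y.size)
        fit = fit_logistic(y, offset=offset)
        oracle = grid_logistic(y, offset=offset)
        assert abs(fit.coef[0] - oracle[0]) < 1e-4

    def test_matches_statsmodels_glm(self, rng):
        """Cross-check coefficients and standard errors against statsmodels."""
        import statsmodels.api as sm

        n = 400
        x = rng.normal(0.0, 1.2, n)
        offset = rng.normal(-1.5, 0.5, n)
        p = 1.0 / (1.0 + np.exp(-(-0.5 + 0.8 * x + offset)))
        y = (rng.random(n) < p).astype(int)
        fit = fit_logistic(y, covariate=x, offset=offset)
        ref = sm.GLM(
            y, sm.add_constant(x), family=sm.families.Binomial(), offset=offset
        ).fit()
        assert np.allclose(fit.coef, ref.params, atol=1e-6)
        assert np.allclose(fit.se, ref.bse, atol=1e-6)

    def test_intercept_recovery_at_scale(self):
        """Responses drawn with true intercept 0 around a known offset:
        the free intercept lands within +/-0.03 of 0 at n = 50,000."""
        rng = np.random.default_rng(101)
        offset = rng.normal(0.0, 1.0, 50_000)
        y = (rng.random(offset.size) < 1.0 / (1.0 + np.exp(-offset))).astype(int)
        fit = fit_logistic(y, offset=offset)
        assert abs(fit.coef[0]) < 0.03

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic([1, 1, 1, 1])
        with pytest.raises(ValueError):
            fit_logistic([0, 1, 2, 1])
        with pytest.raises(SeparationError):
            fit_logistic([0, 0, 0, 1, 1, 1], covariate=[-2.0, -1.5, -1.0, 1.0, 1.5, 2.0])


class TestWeakCalibration:
    def test_recovers_identity_on_model_simulated_cohort(self, large_model_cohort):
        lp = np.asarray(linear_predictor(large_model_cohort))
        y = np.asarray(large_model_cohort["outcome"])
        wc = weak_calibration(lp, y)
        assert abs(wc.intercept) < 0.05
        assert abs(wc.slope - 1.0) < 0.05
        assert wc.intercept_ci[0] < wc.intercept < wc.intercept_ci[1]
        assert wc.slope_ci[0] < wc.slope < wc.slope_ci[1]

    def test_overestimating_model_yields_negative_intercept(self, large_model_cohort):
        """A model reporting risks shifted +0.5 in log-odds overestimates;
        the calibration intercept recovers about -0.5."""
        lp = np.asarray(linear_predictor(large_model_cohort))
        y = np.asarray(large_model_cohort["outcome"])
        wc = weak_calibration(lp + 0.5, y)
        assert wc.intercept == pytest.approx(-0.5, abs=0.06)
        assert wc.intercept < 0

    def test_slope_bias_shrinks_with_sample_size(self):
        """Slope estimates are consistent: mean absolute bias at n = 50,000 is
        below that at n = 2,000 over 20 seeds."""
        biases = {}
        for n in (2_000, 50_000):
            spec = cohort_preset("dorset", n=n, outcome_mode=OutcomeMode("from_model"))
            errs = []
            for seed in range(20):
                cohort = generate_cohort(spec, seed)
                wc = weak_calibration(
                    np.asarray(linear_predictor(cohort)),
                    np.asarray(cohort["outcome"]),
                )
                errs.append(wc.slope - 1.0)
            biases[n] = abs(np.mean(errs))
        assert biases[50_000] < biases[2_000]
        assert biases[50_000] < 0.03


class TestFlexibleCurve:
    def test_calibrated_simulation_tracks_identity(self, large_model_cohort):
        risks = np.asarray(large_model_cohort["true_risk"])
        y = np.asarray(large_model_cohort["outcome"])
        curve = flexible_curve(risks, y)
        window = (curve.grid >= 0.02) & (curve.grid <= 0.15)
        assert np.max(np.abs(curve.smoothed_observed[window] - curve.grid[window])) < 0.05

    def test_constant_risks_return_event_rate(self):
        risks = np.full(80, 0.3)
        y = np.zeros(80, int)
        y[:24] = 1
        curve = flexible_curve(risks, y)
        assert np.allclose(curve.smoothed_observed, 0.3)

    def test_injected_overestimation_sits_below_identity(self, large_model_cohort):
        """Doubling predicted risks relative to truth drags the smoothed
        observed curve under the diagonal on the upper risk range."""
        risks = np.asarray(large_model_cohort["true_risk"])
        y = np.asarray(large_model_cohort["outcome"])
        inflated = np.clip(2.0 * risks, 0.0, 0.999)
        curve = flexible_curve(inflated, y)
        upper = curve.grid > np.quantile(inflated, 0.5)
        assert np.mean(curve.smoothed_observed[upper] < curve.grid[upper]) > 0.95

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="span"):
            flexible_curve(np.linspace(0.01, 0.2, 60), np.zeros(60), span=1.5)
        with pytest.raises(ValueError, match="n >= 50"):
            flexible_curve([0.1] * 10, [0] * 10)

    def test_output_clipped_and_on_grid(self, large_model_cohort):
        risks = np.asarray(large_model_cohort["true_risk"])[:500]
        y = np.asarray(large_model_cohort["outcome"])[:500]
        curve = flexible_curve(risks, y)
        assert curve.grid.size == 100
        assert curve.grid[0] == risks.min() and curve.grid[-1] == risks.max()
        assert np.all((curve.smoothed_observed >= 0) & (curve.smoothed_observed <= 1))


class TestGroupCalibration:
    def test_single_group_degenerate_cohort(self):
        risks = np.full(40, 0.5)
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        table = group_calibration(risks, y, PUBLISHED_SCHEME)
        assert table.set_index("risk_group").loc["very_high", "n"] == 40
        assert table["n"].sum() == 40

    def test_calibrated_simulation_small_group_gaps(self, large_model_cohort):
        risks = np.asarray(large_model_cohort["true_risk"])
        y = np.asarray(large_model_cohort["outcome"])
        table = group_calibration(risks, y, PUBLISHED_SCHEME)
        populated = table[table["n"] > 0]
        gaps = np.abs(populated["mean_predicted"] - populated["observed_rate"])
        assert np.all(gaps < 0.02)

    def test_same_data_derived_scheme_has_event_free_lowest_group(
        self, large_model_cohort
    ):
        risks = np.asarray(large_model_cohort["true_risk"])
        y = np.asarray(large_model_cohort["outcome"])
        derived = derive_ppv_quartile_scheme(risks, y)
        table = group_calibration(risks, y, derived.scheme)
        very_low = table.set_index("risk_group").loc["very_low"]
        assert very_low["observed_rate"] == 0.0
        assert bool(very_low["zero_events"])
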