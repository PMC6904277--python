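"""Logistic fits, two-line lag estimation, plate normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lblcellfit.growth_kinetics import (
    GrowthCurve,
    LagEstimationError,
    LogisticFitError,
    compare_conditions,
    curves_from_plate,
    estimate_lag,
    fit_logistic,
    normalize_plate_signals,
    peak_fluorescence_ratio,
)
from lblcellfit.synthetic_data.plate import delayed_logistic, simulate_plate


def exact_logistic(K=1.0, N0=0.01, r=1.0, tmax=10.0, step=0.25):
    t = np.arange(0.0, tmax + 1e-9, step)
    return t, K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))


class TestFitLogistic:
    def test_noiseless_identifiability(self):
        t, y = exact_logistic()
        fit = fit_logistic(GrowthCurve(time=t, signal=y))
        assert fit.K == pytest.approx(1.0, rel=1e-6)
        assert fit.N0 == pytest.approx(0.01, rel=1e-6)
        assert fit.r == pytest.approx(1.0, rel=1e-6)

    def test_tmid_closed_form(self):
        t, y = exact_logistic()
        fit = fit_logistic(GrowthCurve(time=t, signal=y))
        assert fit.tmid == pytest.approx(np.log(99.0), rel=1e-6)

    def test_doubling_time_definition(self):
        t, y = exact_logistic(r=np.log(2.0), tmax=20.0)
        fit = fit_logistic(GrowthCurve(time=t, signal=y))
        assert fit.tgen == pytest.approx(1.0, rel=1e-6)

    def test_auc_variants_agree_on_dense_noiseless_data(self):
        t, y = exact_logistic(step=0.05)
        fit = fit_logistic(GrowthCurve(time=t, signal=y))
        assert fit.auc_l == pytest.approx(fit.auc_e, rel=0.01)

    def test_flat_signal_raises_no_growth(self):
        t = np.linspace(0, 10, 20)
        with pytest.raises(LogisticFitError, match="no growth"):
            fit_logistic(GrowthCurve(time=t, signal=np.zeros(20)))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(GrowthCurve(time=np.arange(4.0), signal=np.arange(4.0) + 1))


class TestEstimateLag:
    def test_exact_piecewise_linear_intersection(self):
        """Flat at 1 until t=5, then slope 2: the break is exactly 5."""
        t = np.arange(0.0, 10.001, 0.5)
        y = np.where(t <= 5.0, 1.0, 1.0 + 2.0 * (t - 5.0))
        est = estimate_lag(GrowthCurve(time=t, signal=y), scale="raw")
        assert est.lambda_lag == pytest.approx(5.0, abs=1e-9)
        assert est.lag_segment[1] <= est.exp_segment[0]

    def test_single_line_has_no_break(self):
        t = np.arange(0.0, 10.001, 0.5)
        with pytest.raises(LagEstimationError):
            estimate_lag(GrowthCurve(time=t, signal=1.0 + 2.0 * t), scale="raw")

    def test_recovers_lag_from_noisy_delayed_logistic(self):
        """200 noisy curves (lag 1.5 h, sd 0.01): mean within 15%."""
        t = np.arange(0.0, 16.0001, 1.0 / 3.0)
        rng = np.random.default_rng(12)
        lams = []
        with np.errstate(all="ignore"):
            for _ in range(200):
                y = delayed_logistic(t, 1.0, 0.01, 2.0, 1.5)
                y = y + rng.normal(0.0, 0.01, t.size)
                lams.append(
                    estimate_lag(GrowthCurve(time=t, signal=y)).lambda_lag
                )
        assert np.mean(lams) == pytest.approx(1.5, rel=0.15)

    def test_r2_traces_reported_for_audit(self):
        t = np.arange(0.0, 16.0001, 1.0 / 3.0)
        y = delayed_logistic(t, 1.0, 0.01, 2.0, 2.5)
        est = estimate_lag(GrowthCurve(time=t, signal=y))
        assert len(est.r2_trace_lag) >= 1
        assert len(est.r2_trace_exp) >= 1
        assert est.lag_segment[1] == est.exp_segment[0]

    def test_affine_signal_invariance_raw_scale(self):
        t = np.arange(0.0, 10.001, 0.5)
        y = np.where(t <= 4.0, 2.0, 2.0 + 3.0 * (t - 4.0))
        lam0 = estimate_lag(GrowthCurve(time=t, signal=y), scale="raw").lambda_lag
        lam1 = estimate_lag(
            GrowthCurve(time=t, signal=5.0 * y + 11.0), scale="raw"
        ).lambda_lag
        assert lam1 == pytest.approx(lam0, abs=1e-9)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale_factor=st.floats(0.1, 50.0), shift=st.floats(-3.0, 3.0))
    def test_log_scale_invariance_and_time_equivariance(self, scale_factor, shift):
        t = np.arange(0.0, 16.0001, 1.0 / 3.0)
        y = delayed_logistic(t, 1.0, 0.01, 2.0, 2.5)
        lam0 = estimate_lag(GrowthCurve(time=t, signal=y)).lambda_lag
        lam_scaled = estimate_lag(
            GrowthCurve(time=t, signal=scale_factor * y)
        ).lambda_lag
        lam_shifted = estimate_lag(
            GrowthCurve(time=t + shift, signal=y)
        ).lambda_lag
        assert lam_scaled == pytest.approx(lam0, abs=1e-6)
        assert lam_shifted == pytest.approx(lam0 + shift, abs=1e-6)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            estimate_lag(GrowthCurve(time=np.arange(5.0), signal=np.ones(5)))


class TestNormalizePlate:
    def test_control_fluorescence_normalizes_to_one(self):
        table, _ = simulate_plate(n_replicates=1, seed=0)
        norm = normalize_plate_signals(table)
        ctrl = norm[norm["condition"] == "control"]
        assert np.allclose(ctrl["fluor_norm"], 1.0)

    def test_blank_od_normalizes_to_zero(self):
        table, _ = simulate_plate(n_replicates=2, seed=0)
        norm = normalize_plate_signals(table)
        blanks = norm[norm["condition"] == "blank"]
        assert abs(blanks["od_norm"].mean()) < 0.005

    def test_noise_free_peak_ratio_is_exactly_phenotype_factor(self):
        import dataclasses

        from lblcellfit.presets import PLATE_PRESETS

        presets = [
            dataclasses.replace(PLATE_PRESETS[n], noise_sd=0.0)
            for n in ("control", "bilayers4")
        ]
        table, _ = simulate_plate(presets=presets, n_replicates=1, seed=0)
        norm = normalize_plate_signals(table)
        b4 = norm[norm["condition"] == "bilayers4"]
        assert b4["fluor_norm"].max() == pytest.approx(2.1, rel=1e-6)

    def test_missing_blank_or_control_raises(self):
        table, _ = simulate_plate(presets=("bilayers2",), n_replicates=1, seed=0)
        with pytest.raises(ValueError):
            normalize_plate_signals(table)

    def test_nonpositive_control_fluorescence_raises(self):
        table, _ = simulate_plate(n_replicates=1, seed=0)
        table.loc[table["condition"] == "control", "fluorescence"] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            normalize_plate_signals(table)


class TestCompareConditions:
    @staticmethod
    def _params(conditions, lam_by_condition, n=3, jitter=0.01):
        rows = []
        rng = np.random.default_rng(0)
        for cond in conditions:
            for rep in range(n):
                rows.append(
                    {
                        "condition": cond,
                        "replicate": rep,
                        "lambda_lag": lam_by_condition[cond]
                        + rng.normal(0.0, jitter),
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_conditions_not_significant(self):
        params = self._params(["control", "same"], {"control": 1.0, "same": 1.0})
        _, tests = compare_conditions(params)
        assert (tests["p_value"] > 0.05).all()

    def test_separated_conditions_flagged(self):
        params = self._params(
            ["control", "layers8"], {"control": 65.0, "layers8": 111.0}, jitter=2.0
        )
        _, tests = compare_conditions(params)
        lam_test = tests[tests["parameter"] == "lambda_lag"]
        assert (lam_test["p_value"] < 0.05).all()

    def test_single_condition_yields_summary_without_tests(self):
        params = self._params(["control"], {"control": 1.0})
        summary, tests = compare_conditions(params)
        assert len(summary) == 1
        assert tests.empty


class TestCurvesFromPlate:
    def test_round_trip_conditions_and_replicates(self):
        table, _ = simulate_plate(n_replicates=2, seed=1)
        norm = normalize_plate_signals(table)
        curves = curves_from_plate(norm)
        conditions = {c.condition for c in curves}
        assert "blank" not in conditions
        assert len(curves) == 5 * 2

    def test_peak_ratio_with_noise_close_to_factor(self):
        table, _ = simulate_plate(n_replicates=3, seed=2)
        assert peak_fluorescence_ratio(table, "bilayers4") == pytest.approx(
            2.1, rel=0.10
        )
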