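"""Calibration: template fitting, intensity-response curves, matching,
eligibility surrogates."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from pupilplr import calibrate as cal
from pupilplr.params import StudyDesign
from pupilplr.preprocess import preprocess_trials
from pupilplr.simulate import simulate_calibration_session, simulate_validation_session
from pupilplr.trace import PupilTrace


def make_trace(pupil, rate=100.0):
    n = len(pupil)
    return PupilTrace(
        t=np.arange(n) / rate, pupil=np.asarray(pupil, float),
        gaze_x=np.zeros(n), gaze_y=np.zeros(n), valid=np.ones(n, bool),
        sample_rate_hz=rate, unit="mm",
    )


class TestDefaultTemplate:
    def test_shape_properties(self):
        T = cal.default_template(3.0)
        s = np.linspace(-1, 5, 2401)
        vals = T(s)
        assert T(np.array(0.0)) == 0.0
        assert vals.min() == pytest.approx(-1.0, abs=1e-6)
        assert s[vals.argmin()] == pytest.approx(1.0, abs=1e-2)
        # closed form at s=4, k=3: -(64 * exp(-9))
        assert T(np.array(4.0)) == pytest.approx(-64 * math.exp(-9), abs=1e-12)
        assert T(np.array(4.0)) > -0.3
        assert np.all(vals[s < 0] == 0.0)


class TestTemplateFit:
    def test_selffit_recovers_all_four_parameters(self):
        T = cal.default_template()
        t = np.arange(0, 3.25, 0.01)
        true = dict(tau=0.35, v=4.8, sigma=0.6, a=1.2)
        trace = make_trace(true["v"] + true["a"] * T((t - true["tau"]) / true["sigma"]))
        fit = cal.fit_template(trace)
        assert fit.latency_shift == pytest.approx(true["tau"], rel=1e-6)
        assert fit.baseline == pytest.approx(true["v"], rel=1e-6)
        assert fit.time_scale == pytest.approx(true["sigma"], rel=1e-6)
        assert fit.strength == pytest.approx(true["a"], rel=1e-6)
        assert fit.rss < 1e-12

    def test_flat_trace_has_zero_strength(self):
        fit = cal.fit_template(make_trace(np.full(325, 5.0)))
        assert fit.strength == pytest.approx(0.0, abs=1e-9)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(offset=hst.floats(-2, 2), scale=hst.floats(0.5, 3))
    def test_shift_invariance_and_scale_equivariance(self, offset, scale):
        T = cal.default_template()
        t = np.arange(0, 3.25, 0.01)
        base = 5.0 + 1.5 * T((t - 0.3) / 0.5)
        f0 = cal.fit_template(make_trace(base))
        f1 = cal.fit_template(make_trace(base + offset))
        f2 = cal.fit_template(make_trace(5.0 + scale * 1.5 * T((t - 0.3) / 0.5)))
        assert f1.strength == pytest.approx(f0.strength, rel=1e-5)
        assert f1.baseline - f0.baseline == pytest.approx(offset, abs=1e-5)
        assert f2.strength == pytest.approx(scale * f0.strength, rel=1e-5)

    def test_strength_monotone_in_intensity_noiseless(self, noiseless_params):
        design = StudyDesign(phase="calibration", sample_rate_hz=1000.0, intensity_step=25.0)
        records = simulate_calibration_session(noiseless_params, design, 0)
        proc, _ = preprocess_trials(
            records, apply_exclusions=False,
            au_slope=noiseless_params.au_slope, au_intercept=noiseless_params.au_intercept,
        )
        fits = cal.fit_calibration_session(proc)
        table = cal.strengths_by_intensity(fits)
        for color in ("red", "blue"):
            sub = table[table["color"] == color].sort_values("intensity_pct")
            assert np.all(np.diff(sub["strength"]) > 0)


class TestStrengthTable:
    def test_group_means_match_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        rows = []
        for color in ("red", "blue"):
            for intensity in (0.0, 50.0, 100.0):
                for rep in range(2):
                    rows.append(
                        dict(participant_id=0, trial_id=len(rows), color=color,
                             intensity_pct=intensity, strength=rng.uniform(0, 2),
                             rss=0.0, converged=True)
                    )
        rows[0]["converged"] = False  # dropped
        fits = pd.DataFrame(rows)
        table = cal.strengths_by_intensity(fits)
        # brute-force oracle
        for _, row in table.iterrows():
            manual = [
                r["strength"] for r in rows
                if r["color"] == row["color"] and r["intensity_pct"] == row["intensity_pct"]
                and r["converged"]
            ]
            assert row["strength"] == pytest.approx(sum(manual) / len(manual), abs=1e-12)
            assert row["n"] == len(manual)
        assert len(table) <= 12


class TestIntensityCurve:
    def test_exact_quadratic_recovered(self):
        I = np.arange(0, 101, 5, dtype=float)
        beta = (0.1, 0.012, 5e-5)
        table = pd.DataFrame(
            dict(color="red", intensity_pct=I, strength=beta[0] + beta[1] * I + beta[2] * I**2)
        )
        curve = cal.fit_intensity_curve(table, "red")
        assert np.allclose(curve.coef, beta, atol=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_linear_data_gives_negligible_curvature(self):
        I = np.arange(0, 101, 10, dtype=float)
        table = pd.DataFrame(dict(color="blue", intensity_pct=I, strength=0.02 * I))
        curve = cal.fit_intensity_curve(table, "blue")
        assert abs(curve.coef[2]) < 1e-12

    def test_agrees_with_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        I = np.arange(0, 101, 5, dtype=float)
        y = 0.2 + 0.01 * I + 1e-4 * I**2 + rng.normal(0, 0.05, I.size)
        table = pd.DataFrame(dict(color="red", intensity_pct=I, strength=y))
        curve = cal.fit_intensity_curve(table, "red")
        X = np.column_stack([np.ones_like(I), I, I**2])
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(curve.coef, oracle, atol=1e-9)

    def test_too_few_points_rejected(self):
        table = pd.DataFrame(dict(color="red", intensity_pct=[0.0, 50.0], strength=[0.1, 0.5]))
        with pytest.raises(ValueError, match="3 distinct"):
            cal.fit_intensity_curve(table, "red")


def quadratic_curve(color, b0, b1, b2):
    return cal.IntensityResponseCurve(color=color, coef=np.array([b0, b1, b2]), r_squared=1.0)


class TestMatching:
    def test_identical_curves_give_symmetric_outcome(self):
        red = quadratic_curve("red", 0.05, 0.01, 1e-5)
        blue = quadratic_curve("blue", 0.05, 0.01, 1e-5)
        outcome = cal.match_intensities(red, blue)
        assert outcome.bright_red == pytest.approx(100.0, abs=1e-9)
        assert outcome.bright_blue == 100.0
        assert outcome.dim_blue == 50.0
        assert outcome.dim_red == pytest.approx(50.0, abs=1e-9)

    def test_symmetry_under_color_label_swap(self):
        red = quadratic_curve("red", 0.0, 0.02, 0.0)
        blue = quadratic_curve("blue", 0.0, 0.015, 0.0)
        a = cal.match_intensities(red, blue)
        swapped_red = quadratic_curve("red", 0.0, 0.015, 0.0)
        swapped_blue = quadratic_curve("blue", 0.0, 0.02, 0.0)
        b = cal.match_intensities(swapped_red, swapped_blue)
        assert a.bright_red == pytest.approx(b.bright_blue, abs=1e-9)
        assert a.bright_blue == pytest.approx(b.bright_red, abs=1e-9)

    def test_matched_strengths_equal_on_curves(self):
        red = quadratic_curve("red", 0.0, 0.025, 1e-5)
        blue = quadratic_curve("blue", 0.0, 0.02, 0.0)
        out = cal.match_intensities(red, blue)
        assert red.predict(out.bright_red) == pytest.approx(blue.predict(out.bright_blue), abs=1e-6)
        assert red.predict(out.dim_red) == pytest.approx(blue.predict(out.dim_blue), abs=1e-6)

    def test_non_monotone_curve_marks_ineligible(self):
        red = quadratic_curve("red", 1.0, -0.01, 0.0)
        blue = quadratic_curve("blue", 0.0, 0.02, 0.0)
        outcome = cal.match_intensities(red, blue)
        assert not outcome.eligible and "non-monotone" in outcome.reasons[0]


class TestEligibility:
    def test_exact_increasing_quadratic_eligible(self):
        red = quadratic_curve("red", 0.0, 0.02, 1e-5)
        blue = quadratic_curve("blue", 0.0, 0.015, 1e-5)
        ok, diag = cal.calibration_eligibility(red, blue)
        assert ok and diag["increasing_red"]

    def test_shuffled_strengths_ineligible(self):
        rng = np.random.default_rng(7)
        I = np.arange(0, 101, 5, dtype=float)
        y = 0.01 * I + rng.normal(0, 0.01, I.size)
        table = pd.DataFrame(dict(color="red", intensity_pct=I, strength=rng.permutation(y)))
        curve = cal.fit_intensity_curve(table, "red")
        ok, diag = cal.calibration_eligibility(curve, quadratic_curve("blue", 0.0, 0.01, 0.0))
        assert not ok and diag["r_squared_red"] < 0.7

    def test_flat_curves_ineligible(self):
        flat = quadratic_curve("red", 0.5, 0.0, 0.0)
        ok, _ = cal.calibration_eligibility(flat, quadratic_curve("blue", 0.0, 0.01, 0.0))
        assert not ok


class TestEligibilityVsNoise:
    def test_eligibility_rate_monotone_in_signal_to_noise(self):
        """More measurement noise can only hurt the automated eligibility
        surrogate (checked at three noise levels, non-strict)."""
        from pupilplr.params import PlrParams

        design = StudyDesign(phase="calibration", sample_rate_hz=100.0, intensity_step=10.0)
        rates = []
        for noise in (0.02, 0.6, 3.0):
            params = PlrParams(seed=17).noiseless().replace(
                noise_sd_mm=noise, trial_baseline_sd_mm=noise / 4
            )
            eligible = 0
            n = 3
            for pid in range(n):
                records = simulate_calibration_session(params, design, pid)
                proc, _ = preprocess_trials(
                    records, apply_exclusions=False,
                    au_slope=params.au_slope, au_intercept=params.au_intercept,
                )
                outcome, _ = cal.calibrate_participant(proc)
                eligible += outcome.eligible
            rates.append(eligible / n)
        assert rates[0] == 1.0
        assert rates[0] >= rates[1] >= rates[2]
        assert rates[2] < 1.0


class TestValidationEligibility:
    def _validation_records(self, params):
        design = StudyDesign(phase="validation", sample_rate_hz=100.0)
        records = simulate_validation_session(params, design, None, 0)
        proc, _ = preprocess_trials(
            records, apply_exclusions=False,
            au_slope=params.au_slope, au_intercept=params.au_intercept,
        )
        return proc

    def test_generator_defaults_are_eligible(self, noiseless_params):
        ok, diag = cal.validation_eligibility(self._validation_records(noiseless_params))
        assert ok
        assert diag["red_minus_blue_bright_mm"] > 0.05
        assert diag["red_minus_blue_dim_mm"] > 0.05

    def test_equal_melanopic_weights_ineligible(self, noiseless_params):
        p = noiseless_params.replace(melanopic_weight_red=0.999999, melanopic_weight_blue=1.0)
        ok, _ = cal.validation_eligibility(self._validation_records(p))
        assert not ok

    def test_bright_only_data_under_primary_rule_errors(self, noiseless_params):
        records = [r for r in self._validation_records(noiseless_params) if r.brightness == "bright"]
        with pytest.raises(ValueError, match="missing validation condition"):
            cal.validation_eligibility(records, rule="primary")
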