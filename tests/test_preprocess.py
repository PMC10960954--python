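"""Preprocessing ops: blink interpolation, downsampling, conversion,
baseline correction, and the two exclusion rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from pupilplr.preprocess import (
    TrialUnusableError,
    au_to_mm,
    baseline_correct,
    baseline_outlier_exclusion,
    downsample,
    gaze_exclusion,
    interpolate_blinks,
)
from pupilplr.trace import PupilTrace, TrialRecord


def make_trace(pupil, rate=1000.0, unit="mm", gaze=None, valid=None):
    n = len(pupil)
    t = np.arange(n) / rate
    if gaze is None:
        gaze = np.zeros(n)
    return PupilTrace(
        t=t,
        pupil=np.asarray(pupil, float),
        gaze_x=np.asarray(gaze, float),
        gaze_y=np.zeros(n),
        valid=np.ones(n, bool) if valid is None else np.asarray(valid, bool),
        sample_rate_hz=rate,
        unit=unit,
    )


class TestInterpolateBlinks:
    def test_identity_without_gaps(self):
        trace = make_trace(np.sin(np.arange(500) / 50))
        out = interpolate_blinks(trace)
        assert np.array_equal(out.pupil, trace.pupil)

    def test_gap_in_linear_ramp_filled_exactly(self):
        ramp = np.linspace(0, 5, 1000)
        valid = np.ones(1000, bool)
        valid[400:500] = False  # 100 ms gap
        corrupted = ramp.copy()
        corrupted[400:500] = 0.0
        trace = make_trace(corrupted, valid=valid)
        out = interpolate_blinks(trace)
        assert np.allclose(out.pupil, ramp, atol=1e-9)
        assert np.array_equal(out.valid, valid)  # audit flags retained

    def test_planted_blinks_recovered_below_noise_floor(self):
        """Reconstruction over a planted 200 ms blink recovers the
        blink-free underlying signal with an error below the measurement
        noise (the noise itself inside the gap is unobservable)."""
        rng = np.random.default_rng(0)
        noise_sd = 0.05
        smooth = 5.0 - np.exp(-((np.arange(3000) / 1000 - 1.0) ** 2))
        observed = smooth + rng.normal(0, noise_sd, 3000)
        valid = np.ones(3000, bool)
        valid[1200:1400] = False
        observed[1200:1400] = 0.0
        out = interpolate_blinks(make_trace(observed, valid=valid))
        rmse = np.sqrt(np.mean((out.pupil[1200:1400] - smooth[1200:1400]) ** 2))
        assert rmse < noise_sd

    def test_edge_gap_filled_by_nearest_and_all_invalid_rejected(self):
        valid = np.ones(300, bool)
        valid[:50] = False
        trace = make_trace(np.linspace(1, 2, 300), valid=valid)
        out = interpolate_blinks(trace)
        assert np.all(np.isfinite(out.pupil))
        with pytest.raises(TrialUnusableError):
            interpolate_blinks(make_trace(np.ones(100), valid=np.zeros(100, bool)))


class TestDownsample:
    def test_factor_ten_reduces_count_and_rate(self):
        trace = make_trace(np.arange(15000, dtype=float))
        out = downsample(trace, 10)
        assert out.n_samples == 1500 and out.sample_rate_hz == 100.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(factor=hst.sampled_from([2, 5, 10, 25]), blocks=hst.integers(3, 40))
    def test_block_mean_preserves_overall_mean(self, factor, blocks):
        rng = np.random.default_rng(factor * 1000 + blocks)
        x = rng.normal(size=factor * blocks)
        out = downsample(make_trace(x), factor)
        assert out.pupil.mean() == pytest.approx(x.mean(), abs=1e-12)

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            downsample(make_trace(np.ones(10)), 0)


class TestUnitConversion:
    def test_affine_and_identity(self):
        trace = make_trace(np.full(100, 2000.0), unit="au")
        out = au_to_mm(trace, 0.0025, 0.0)
        assert np.allclose(out.pupil, 5.0) and out.unit == "mm"
        ident = au_to_mm(make_trace(np.full(10, 4.0), unit="au"), 1.0, 0.0)
        assert np.array_equal(ident.pupil, np.full(10, 4.0))

    def test_generator_affine_map_inverts_exactly(self, noiseless_params):
        from pupilplr.params import StudyDesign
        from pupilplr.simulate import simulate_calibration_session

        design = StudyDesign(phase="calibration", sample_rate_hz=100.0, intensity_step=50.0)
        rec = simulate_calibration_session(noiseless_params, design, 0)[0]
        mm = au_to_mm(rec.trace, noiseless_params.au_slope, noiseless_params.au_intercept)
        from pupilplr.kernel import intensity_to_drives, plr_kernel

        rc, mel = intensity_to_drives(noiseless_params, rec.color, rec.intensity_pct)
        expected = plr_kernel(noiseless_params, rc, mel, rec.trace.t)
        assert np.allclose(mm.pupil, expected, atol=1e-9)

    def test_mm_input_rejected(self):
        with pytest.raises(ValueError, match="arbitrary"):
            au_to_mm(make_trace(np.ones(10), unit="mm"), 1.0, 0.0)


class TestBaselineCorrect:
    def _record(self, pupil, onset=0.0, rate=1000.0):
        return TrialRecord(
            participant_id=0, trial_id=0, phase="main",
            trace=make_trace(pupil, rate=rate), stream_onset_s=onset,
        )

    def test_constant_trace_becomes_zero_with_stored_baseline(self):
        rec = baseline_correct(self._record(np.full(200, 3.3)))
        assert np.allclose(rec.trace.pupil, 0.0) and rec.baseline == pytest.approx(3.3)

    def test_idempotent_on_own_output(self):
        rec = baseline_correct(self._record(np.linspace(2, 3, 500)))
        again = baseline_correct(rec)
        assert np.allclose(rec.trace.pupil, again.trace.pupil, atol=1e-12)

    def test_planted_offset_recovered(self):
        base = np.linspace(4, 5, 300)
        delta = 1.7
        b0 = baseline_correct(self._record(base)).baseline
        b1 = baseline_correct(self._record(base + delta)).baseline
        assert b1 - b0 == pytest.approx(delta, abs=1e-12)

    def test_fully_invalid_window_flagged(self):
        rec = self._record(np.ones(300))
        rec.trace.valid[:60] = False
        with pytest.raises(TrialUnusableError):
            baseline_correct(rec)


class TestGazeExclusion:
    def _record(self, gaze, rate=1000.0, trial_id=0):
        n = len(gaze)
        return TrialRecord(
            participant_id=0, trial_id=trial_id, phase="main",
            trace=make_trace(np.ones(n), rate=rate, gaze=gaze),
            stream_onset_s=0.0, stream_duration_s=n / rate,
        )

    def test_exactly_10ms_deviation_is_retained_11ms_excluded(self):
        gaze = np.zeros(1000)
        gaze[100:110] = 7.0  # 10 samples at 1000 Hz = exactly 10 ms
        kept, report = gaze_exclusion([self._record(gaze)])
        assert len(kept) == 1 and report.n_gaze_excluded == 0
        gaze11 = np.zeros(1000)
        gaze11[100:111] = 7.0  # 11 ms: strictly longer than the criterion
        kept, report = gaze_exclusion([self._record(gaze11)])
        assert len(kept) == 0 and report.n_gaze_excluded == 1

    def test_all_zero_gaze_excludes_nothing_and_is_idempotent(self):
        records = [self._record(np.zeros(500), trial_id=i) for i in range(4)]
        kept, report = gaze_exclusion(records)
        assert report.n_gaze_excluded == 0
        kept2, report2 = gaze_exclusion(kept)
        assert len(kept2) == len(kept) and report2.n_gaze_excluded == 0

    def test_subthreshold_amplitude_retained(self):
        gaze = np.full(500, 6.5)  # below 6.93 deg forever
        kept, report = gaze_exclusion([self._record(gaze)])
        assert len(kept) == 1


class TestBaselineOutlierExclusion:
    def _records(self, baselines, pid=0):
        return [
            TrialRecord(participant_id=pid, trial_id=i, phase="main", baseline=float(b))
            for i, b in enumerate(baselines)
        ]

    def test_identical_baselines_excluded_nothing(self):
        kept, report = baseline_outlier_exclusion(self._records(np.full(20, 2.0)))
        assert report.n_baseline_excluded == 0 and len(kept) == 20

    def test_single_planted_extreme_is_the_only_exclusion(self):
        rng = np.random.default_rng(1)
        baselines = rng.normal(0, 0.01, 100)
        baselines[42] = 5.0
        kept, report = baseline_outlier_exclusion(self._records(baselines))
        assert report.n_baseline_excluded == 1
        assert report.reasons == {(0, 42): "baseline_outlier"}

    def test_infinite_criterion_is_identity(self):
        rng = np.random.default_rng(2)
        records = self._records(rng.normal(size=50))
        kept, report = baseline_outlier_exclusion(records, z_crit=np.inf)
        assert len(kept) == 50 and report.n_baseline_excluded == 0

    def test_too_few_trials_warns_and_keeps(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            kept, report = baseline_outlier_exclusion(self._records([1.0, 9.0]))
        assert len(kept) == 2

    def test_report_partitions_input(self):
        rng = np.random.default_rng(3)
        records = self._records(rng.normal(size=60))
        kept, report = baseline_outlier_exclusion(records)
        assert report.n_input == report.n_retained + report.n_baseline_excluded + report.n_gaze_excluded
        assert len(kept) == report.n_retained
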