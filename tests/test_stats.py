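"""Mixed-model analyses: selectors, window LME, localize-then-test,
accuracy GLME."""

import numpy as np
import pandas as pd
import pytest

from pupilplr import stats as st
from pupilplr.params import PlrParams, StudyDesign
from pupilplr.preprocess import preprocess_trials
from pupilplr.simulate import simulate_main_session, simulate_validation_session


def crossed_trial_grid(n_reps=1, n_participants=1):
    rows = []
    levels = [("dim", "red"), ("dim", "blue"), ("bright", "red"), ("bright", "blue")]
    tid = 0
    for pid in range(n_participants):
        for _ in range(n_reps):
            for ab, ac in levels:
                for ib, ic in levels:
                    rows.append(
                        dict(participant_id=pid, trial_id=tid, attended_brightness=ab,
                             attended_color=ac, ignored_brightness=ib, ignored_color=ic)
                    )
                    tid += 1
    return pd.DataFrame(rows)


class TestSelectors:
    def test_same_color_keeps_8_of_16_combinations(self):
        grid = crossed_trial_grid()
        out = st.select_same_color(grid)
        assert len(out) == 8
        assert set(out["brightness"]) == {"dim", "bright"}

    def test_same_brightness_keeps_8_of_16(self):
        out = st.select_same_brightness(crossed_trial_grid())
        assert len(out) == 8 and set(out["color"]) == {"red", "blue"}

    def test_224_trial_participant_yields_112(self):
        grid = crossed_trial_grid(n_reps=14)  # 224 trials
        assert len(st.select_same_color(grid)) == 112
        assert len(st.select_same_brightness(grid)) == 112

    def test_empty_input_gives_empty_output(self):
        empty = crossed_trial_grid().iloc[0:0]
        assert len(st.select_same_color(empty)) == 0

    def test_union_and_intersection_combinatorics(self):
        grid = crossed_trial_grid()
        same_c = set(st.select_same_color(grid)["trial_id"])
        same_b = set(st.select_same_brightness(grid)["trial_id"])
        assert len(same_c | same_b) == 12
        assert len(same_c & same_b) == 4


def _validation_table(params, n_participants=3):
    design = StudyDesign(phase="validation", sample_rate_hz=100.0)
    records = []
    for pid in range(n_participants):
        recs = simulate_validation_session(params, design, None, pid)
        proc, _ = preprocess_trials(
            recs, apply_exclusions=False,
            au_slope=params.au_slope, au_intercept=params.au_intercept,
        )
        records.extend(proc)
    return st.window_mean_table(records)


class TestWindowLME:
    def test_noiseless_cohort_recovers_exact_condition_difference(self):
        from pupilplr.kernel import expected_window_effects

        params = PlrParams(seed=5).noiseless().replace(noise_sd_mm=1e-6)
        table = _validation_table(params, n_participants=3)
        res = st.window_lme(table, "brightness")
        expected = expected_window_effects(params)["direct_brightness_mm"]
        assert res.b == pytest.approx(expected, abs=1e-3)
        assert res.stat > 0  # constriction-positive reporting convention

    def test_invariance_to_trial_order_and_participant_offsets(self):
        rng = np.random.default_rng(0)
        params = PlrParams(seed=6)
        table = _validation_table(params, n_participants=4)
        res = st.window_lme(table, "brightness")
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        res_shuffled = st.window_lme(shuffled, "brightness")
        assert res_shuffled.b == pytest.approx(res.b, abs=1e-6)
        offset = table.copy()
        offset["pupil_mm"] = offset["pupil_mm"] + offset["participant_id"].map(
            {pid: rng.normal(0, 1) for pid in offset["participant_id"].unique()}
        )
        res_offset = st.window_lme(offset, "brightness")
        assert res_offset.b == pytest.approx(res.b, abs=1e-6)

    def test_shuffled_factor_codes_are_null(self):
        params = PlrParams(seed=8)
        table = _validation_table(params, n_participants=6)
        rng = np.random.default_rng(2)
        hits = 0
        n_reps = 20
        for _ in range(n_reps):
            null = table.copy()
            null["brightness"] = (
                null.groupby("participant_id")["brightness"]
                .transform(lambda s: rng.permutation(s.values))
            )
            res = st.window_lme(null, "brightness")
            hits += abs(res.stat) < 2
        assert hits >= int(0.75 * n_reps)

    def test_single_participant_rejected(self):
        df = pd.DataFrame(
            dict(participant_id=0, brightness=["dim", "bright"] * 5, pupil_mm=np.arange(10.0))
        )
        with pytest.raises(ValueError, match="two participants"):
            st.window_lme(df, "brightness")


def _main_matrix(params, factor, n_participants=6, n_trials=48, seed_extra=0):
    design = StudyDesign(phase="main", n_trials=n_trials, sample_rate_hz=100.0)
    records = []
    for pid in range(n_participants):
        recs = simulate_main_session(params, design, None, pid)
        proc, _ = preprocess_trials(
            recs, au_slope=params.au_slope, au_intercept=params.au_intercept
        )
        records.extend(proc)
    if factor == "brightness":
        subset = [r for r in records if r.attended_color == r.ignored_color]
    else:
        subset = [r for r in records if r.attended_brightness == r.ignored_brightness]
    meta, mat, times = st.stream_sample_matrix(subset, extra_downsample=10)
    meta[factor] = meta[f"attended_{factor}"]
    return meta, mat, times


class TestCrossValTst:
    def test_covert_brightness_effect_detected_and_localized_in_window(self):
        params = PlrParams(seed=21)
        meta, mat, times = _main_matrix(params, "brightness")
        res = st.cv_tst(meta, mat, times, "brightness", folds=4, seed=1)
        assert res.p < 0.05 and res.z > 0
        assert all(0 <= s < mat.shape[1] for s in res.localized_samples)
        assert all(times[0] <= t <= times[-1] for t in res.localized_times_s)
        assert res.fold_count == 4

    def test_identical_fold_data_localizes_identically(self):
        params = PlrParams(seed=22)
        meta, mat, times = _main_matrix(params, "brightness", n_participants=4, n_trials=32)
        # duplicate every trial so each fold sees the same data
        meta2 = pd.concat([meta] * 4, ignore_index=True)
        meta2["trial_id"] = np.arange(len(meta2))
        mat2 = np.vstack([mat] * 4)
        res = st.cv_tst(meta2, mat2, times, "brightness", folds=2, seed=9)
        assert res.localized_samples[0] == res.localized_samples[1]

    def test_two_sample_window_degenerates_to_window_lme(self):
        params = PlrParams(seed=23)
        meta, mat, times = _main_matrix(params, "brightness", n_participants=4, n_trials=32)
        j = int(np.argmax(np.abs(mat.mean(axis=0))))
        two = np.repeat(mat[:, [j]], 2, axis=1)  # both candidate samples identical
        res = st.cv_tst(meta, two, times[:2], "brightness", folds=2, seed=3)
        df = meta.copy()
        df["pupil_mm"] = mat[:, j]
        ref = st.window_lme(df, "brightness")
        assert res.z == pytest.approx(ref.stat, abs=1e-6)
        assert res.b == pytest.approx(ref.b, abs=1e-8)

    def test_window_shorter_than_two_samples_rejected(self):
        params = PlrParams(seed=24)
        meta, mat, times = _main_matrix(params, "color", n_participants=4, n_trials=32)
        with pytest.raises(ValueError, match="at least 2 samples"):
            st.cv_tst(meta, mat[:, :1], times[:1], "color")
        with pytest.raises(ValueError, match=">= 2"):
            st.cv_tst(meta, mat, times, "color", folds=1)


class TestAccuracyGlme:
    def _trials(self, params, n_participants=8, n_trials=64):
        design = StudyDesign(phase="main", n_trials=n_trials, sample_rate_hz=100.0)
        rows = []
        for pid in range(n_participants):
            for r in simulate_main_session(params, design, None, pid):
                rows.append(
                    dict(participant_id=pid, attended_color=r.attended_color,
                         attended_brightness=r.attended_brightness, correct=r.correct)
                )
        return pd.DataFrame(rows)

    def test_condition_independent_accuracy_yields_null_effects(self):
        params = PlrParams(seed=31)
        results = st.accuracy_glme(self._trials(params))
        assert set(results) == {"color", "brightness", "interaction"}
        for res in results.values():
            assert abs(res.stat) < 3
            assert res.statistic_label == "z"

    def test_perfect_accuracy_raises_separation_error(self):
        params = PlrParams(seed=32, p_correct=1.0)
        with pytest.raises(st.CompleteSeparationError):
            st.accuracy_glme(self._trials(params, n_participants=4, n_trials=32))

    def test_planted_color_effect_recovered_with_correct_sign(self):
        rng = np.random.default_rng(33)
        rows = []
        for pid in range(12):
            for tid in range(120):
                color = "blue" if tid % 2 else "red"
                brightness = "bright" if (tid // 2) % 2 else "dim"
                logit = 0.8 + (np.log(2.0) if color == "blue" else 0.0)
                prob = 1 / (1 + np.exp(-logit))
                rows.append(
                    dict(participant_id=pid, attended_color=color,
                         attended_brightness=brightness, correct=rng.random() < prob)
                )
        results = st.accuracy_glme(pd.DataFrame(rows))
        assert results["color"].b > 0
        assert results["color"].stat > 1.5
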