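"""Self-contained simulation studies validating the pipeline.

Each function generates its own data from the synthetic two-pathway PLR
generator, runs the relevant part of the pipeline, and returns the measured
quantities.  They are shared by the test suite and by the reproduction
script, so the numbers reported in both come from identical code paths.

Problem sizes: the calibration/template checks run one noiseless
participant at the native 1 kHz rate; the effect-recovery study simulates
the full 30-participant cohort (28 validation + 224 main trials each) at
1 kHz; the type-I-error and power studies use scaled-down replicates
simulated at 100 Hz, whose two x10 downsampling steps give a 1 Hz analysis
grid (15 scan points over the 15 s stream).
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from . import calibrate as cal
from . import simulate as sim
from . import stats as st
from .io import read_records
from .kernel import analytic_calibration_intensities, expected_window_effects
from .params import PlrParams, StudyDesign
from .preprocess import preprocess_trials

__all__ = [
    "calibration_match_study",
    "template_selffit_check",
    "exclusion_exactness_check",
    "effect_recovery_study",
    "cvtst_null_study",
    "cvtst_power_study",
]


def _seed(seed: int, offset: int) -> int:
    return int((int(seed) + offset) % (2**31 - 1))


def grid_search_match(curve, target: float, step_pct: float = 0.01) -> float:
    """Brute-force isoluminance match: the grid intensity whose predicted
    strength is closest to ``target`` (0.01 % steps by default).  Serves as
    an independent oracle for the quadratic root solver."""
    grid = np.arange(0.0, 100.0 + step_pct / 2, step_pct)
    return float(grid[np.argmin(np.abs(curve.predict(grid) - target))])


def calibration_match_study(seed: int) -> dict:
    """Noiseless calibration session -> template fits -> matching, compared
    with the generator's analytic isoluminance solution and with a
    0.01 %-step grid-search oracle."""
    params = PlrParams(seed=_seed(seed, 0)).noiseless()
    design = StudyDesign(phase="calibration", sample_rate_hz=1000.0)
    records = sim.simulate_calibration_session(params, design, participant_id=0)
    processed, _ = preprocess_trials(
        records, apply_exclusions=False, au_slope=params.au_slope, au_intercept=params.au_intercept
    )
    outcome, artifacts = cal.calibrate_participant(processed)
    analytic = analytic_calibration_intensities(params)
    curves = artifacts["curves"]
    grid = {
        "bright_red": grid_search_match(curves["red"], outcome.matched_strengths["bright"])
        if outcome.bright_blue == 100.0
        else outcome.bright_red,
        "dim_red": grid_search_match(curves["red"], outcome.matched_strengths["dim"]),
    }
    matched = {k: outcome.intensity(*k.split("_")) for k in analytic}
    max_err_analytic = max(abs(matched[k] - analytic[k]) for k in analytic)
    max_err_grid = max(abs(matched[k] - grid[k]) for k in grid)
    return {
        "matched": matched,
        "analytic": analytic,
        "grid": grid,
        "max_abs_err_vs_analytic_pct": float(max_err_analytic),
        "max_abs_err_vs_grid_pct": float(max_err_grid),
        "eligible": outcome.eligible,
        "n_trials": len(records),
    }


def template_selffit_check(seed: int) -> dict:
    """Self-fit identity and strength monotonicity of the template fit."""
    from .trace import PupilTrace

    rng = np.random.default_rng(_seed(seed, 1))
    template = cal.default_template()
    t = np.arange(0, 3.25, 0.01)
    true = {"tau": 0.28, "v": 5.2, "sigma": 0.55, "a": 1.7}
    pupil = true["v"] + true["a"] * template((t - true["tau"]) / true["sigma"])
    trace = PupilTrace(
        t=t, pupil=pupil, gaze_x=np.zeros_like(t), gaze_y=np.zeros_like(t),
        valid=np.ones_like(t, dtype=bool), sample_rate_hz=100.0, unit="mm",
    )
    fit = cal.fit_template(trace)
    rel = {
        "tau": abs(fit.latency_shift - true["tau"]) / true["tau"],
        "v": abs(fit.baseline - true["v"]) / true["v"],
        "sigma": abs(fit.time_scale - true["sigma"]) / true["sigma"],
        "a": abs(fit.strength - true["a"]) / true["a"],
    }

    # monotonicity on noiseless flashes
    params = PlrParams(seed=_seed(seed, 2)).noiseless()
    design = StudyDesign(phase="calibration", sample_rate_hz=1000.0, intensity_step=20.0)
    records = sim.simulate_calibration_session(params, design, participant_id=0)
    processed, _ = preprocess_trials(
        records, apply_exclusions=False, au_slope=params.au_slope, au_intercept=params.au_intercept
    )
    fits = cal.fit_calibration_session(processed)
    table = cal.strengths_by_intensity(fits)
    monotone = True
    for color in ("red", "blue"):
        sub = table[table["color"] == color].sort_values("intensity_pct")
        monotone = monotone and bool(np.all(np.diff(sub["strength"]) > 0))
    return {
        "max_rel_err": float(max(rel.values())),
        "rel_err": rel,
        "rss": fit.rss,
        "strength_monotone": monotone,
        "n_intensities": int(table["intensity_pct"].nunique()),
    }


def exclusion_exactness_check(seed: int, workdir: str | Path | None = None) -> dict:
    """Planted-exclusions fixture -> full preprocessing -> exclusion counts
    compared with the planted manifest (integer equality expected)."""
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    outdir = Path(ctx.name) if ctx else Path(workdir)
    try:
        manifest = sim.make_fixture("planted-exclusions", seed=_seed(seed, 3), outdir=outdir)
        records = read_records(outdir / "samples.csv", outdir / "trials.csv")
        retained, report = preprocess_trials(records)
        detected_gaze = sorted(
            t for (p, t), r in report.reasons.items() if r == "gaze_deviation"
        )
        detected_baseline = sorted(
            t for (p, t), r in report.reasons.items() if r == "baseline_outlier"
        )
        return {
            "planted_gaze": manifest["planted_gaze_trials"],
            "detected_gaze": detected_gaze,
            "planted_baseline": manifest["planted_baseline_trials"],
            "detected_baseline": detected_baseline,
            "gaze_exact": detected_gaze == manifest["planted_gaze_trials"],
            "baseline_exact": detected_baseline == manifest["planted_baseline_trials"],
            "n_input": report.n_input,
            "n_retained": report.n_retained,
        }
    finally:
        if ctx:
            ctx.cleanup()


def effect_recovery_study(seed: int, n_participants: int = 30) -> dict:
    """Full-scale cohort recovery of the generating effects.

    Simulates the validation phase (direct gaze, 28 trials/participant) and
    the main phase (covert attention, 224 trials/participant) for
    ``n_participants`` at 1 kHz with the generator defaults and the exact
    analytic isoluminance set, then estimates the brightness and colour
    window-LME coefficients (validation) and the covert brightness / colour
    localize-then-test contrasts (main).
    """
    params = PlrParams(seed=_seed(seed, 4))
    val_design = StudyDesign(phase="validation", n_participants=n_participants)
    main_design = StudyDesign(phase="main", n_participants=n_participants)
    pp = dict(au_slope=params.au_slope, au_intercept=params.au_intercept)

    val_records, main_records = [], []
    for pid in range(n_participants):
        vrec = sim.simulate_validation_session(params, val_design, None, pid)
        vproc, _ = preprocess_trials(vrec, apply_exclusions=False, **pp)
        val_records.extend(vproc)
        mrec = sim.simulate_main_session(params, main_design, None, pid)
        mproc, _ = preprocess_trials(mrec, **pp)
        main_records.extend(mproc)

    expected = expected_window_effects(params)
    val_table = st.window_mean_table(val_records)
    bright = st.window_lme(val_table, "brightness", window=(0.0, 15.0))
    color = st.window_lme(val_table, "color", window=(0.0, 15.0))

    same_color = [r for r in main_records if r.attended_color == r.ignored_color]
    meta, mat, times = st.stream_sample_matrix(same_color, extra_downsample=10)
    meta["brightness"] = meta["attended_brightness"]
    covert_bright = st.cv_tst(meta, mat, times, "brightness", folds=4, seed=_seed(seed, 5))

    same_bright = [r for r in main_records if r.attended_brightness == r.ignored_brightness]
    meta, mat, times = st.stream_sample_matrix(same_bright, extra_downsample=10)
    meta["color"] = meta["attended_color"]
    covert_color = st.cv_tst(meta, mat, times, "color", folds=4, seed=_seed(seed, 6))

    ci = 1.96
    return {
        "expected": expected,
        "direct_brightness": bright.to_dict(),
        "direct_color": color.to_dict(),
        "direct_brightness_ci_covers": bool(
            abs(bright.b - expected["direct_brightness_mm"]) <= ci * bright.se
        ),
        "direct_color_ci_covers": bool(
            abs(color.b - expected["direct_color_mm"]) <= ci * color.se
        ),
        "covert_brightness": covert_bright.to_dict(),
        "covert_color": covert_color.to_dict(),
        "n_main_trials": len(main_records),
    }


def _scaled_replicate(
    params: PlrParams, n_participants: int, n_trials: int
) -> tuple:
    """One scaled-down main-phase dataset at 100 Hz (analysis grid 1 Hz)."""
    design = StudyDesign(
        phase="main", n_participants=n_participants, n_trials=n_trials, sample_rate_hz=100.0
    )
    records = []
    pp = dict(au_slope=params.au_slope, au_intercept=params.au_intercept)
    for pid in range(n_participants):
        recs = sim.simulate_main_session(params, design, None, pid)
        proc, _ = preprocess_trials(recs, **pp)
        records.extend(proc)
    return records


def cvtst_null_study(
    seed: int, n_reps: int = 200, n_participants: int = 10, n_trials: int = 40, alpha: float = 0.05
) -> dict:
    """Type-I error of the localize-then-test procedure under the
    generator's null for the covert colour contrast."""
    base = PlrParams(seed=0)
    rejections, pvals = 0, []
    for rep in range(n_reps):
        params = base.replace(seed=_seed(seed, 10_000 + rep))
        records = _scaled_replicate(params, n_participants, n_trials)
        same_bright = [r for r in records if r.attended_brightness == r.ignored_brightness]
        meta, mat, times = st.stream_sample_matrix(same_bright, extra_downsample=10)
        meta["color"] = meta["attended_color"]
        res = st.cv_tst(meta, mat, times, "color", folds=4, seed=_seed(seed, 20_000 + rep))
        pvals.append(res.p)
        rejections += res.p < alpha
    return {
        "rejection_rate": rejections / n_reps,
        "n_reps": n_reps,
        "alpha": alpha,
        "mean_p": float(np.mean(pvals)),
        "n_participants": n_participants,
        "n_trials": n_trials,
    }


def cvtst_power_study(
    seed: int, n_reps: int = 50, n_participants: int = 30, n_trials: int = 40, alpha: float = 0.05
) -> dict:
    """Power of the procedure for the covert brightness effect (one quarter
    of the 0.84 mm direct effect under the generator defaults)."""
    base = PlrParams(seed=0)
    rejections = 0
    for rep in range(n_reps):
        params = base.replace(seed=_seed(seed, 30_000 + rep))
        records = _scaled_replicate(params, n_participants, n_trials)
        same_color = [r for r in records if r.attended_color == r.ignored_color]
        meta, mat, times = st.stream_sample_matrix(same_color, extra_downsample=10)
        meta["brightness"] = meta["attended_brightness"]
        res = st.cv_tst(meta, mat, times, "brightness", folds=4, seed=_seed(seed, 40_000 + rep))
        rejections += res.p < alpha
    return {
        "power": rejections / n_reps,
        "n_reps": n_reps,
        "alpha": alpha,
        "n_participants": n_participants,
        "n_trials": n_trials,
    }
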