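"""Synthetic eye-tracking sessions for the three study phases.

The generator emits, per participant, the trial structure of (a) a
calibration session of brief full-field colour flashes at 0-100 % intensity
in steps of 5, (b) a validation session of prolonged full-field exposures to
the four matched colour/brightness combinations, and (c) a cued dual-stream
session in which the attended and ignored placeholder conditions are fully
crossed.  Traces carry the two-pathway PLR kernel plus white measurement
noise, slow random-walk drift, Poisson blinks, gaze jitter with optional
planted fixation breaks, and occasional extreme baseline offsets; pupil size
is written in tracker arbitrary units through an affine map.

All stochastic output is a pure function of (params, design, participant_id,
params.seed).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np

from .kernel import intensity_to_drives, plr_kernel, analytic_calibration_intensities
from .params import COLORS, PlrParams, StudyDesign
from .trace import PupilTrace, TrialRecord

__all__ = [
    "simulate_calibration_session",
    "simulate_validation_session",
    "simulate_main_session",
    "make_fixture",
    "FIXTURE_KINDS",
]

_PHASE_CODE = {"calibration": 1, "validation": 2, "main": 3}


def _session_rng(params: PlrParams, phase: str, participant_id: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(params.seed), _PHASE_CODE[phase], int(participant_id)])
    )


def _participant_params(params: PlrParams, participant_id: int) -> PlrParams:
    """Participant-level random effects: baseline shift and multiplicative
    gain factors shared by neither pathway (lognormal, CV ``subject_gain_cv``)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 99, int(participant_id)]))
    baseline = params.baseline_mm + rng.normal(0.0, params.subject_baseline_sd_mm)
    rc_factor = float(np.exp(rng.normal(0.0, params.subject_gain_cv)))
    ip_factor = float(np.exp(rng.normal(0.0, params.subject_gain_cv)))
    return params.replace(
        baseline_mm=max(baseline, 1.0),
        rc_gain=params.rc_gain * rc_factor,
        ip_gain=params.ip_gain * ip_factor,
    )


def _time_grid(duration_s: float, rate_hz: float) -> np.ndarray:
    n = int(round(duration_s * rate_hz))
    return np.arange(n) / rate_hz


def _add_noise(rng: np.random.Generator, pupil: np.ndarray, params: PlrParams) -> np.ndarray:
    n = pupil.size
    out = pupil.copy()
    if params.noise_sd_mm > 0:
        out += rng.normal(0.0, params.noise_sd_mm, size=n)
    if params.drift_sd_mm > 0:
        # random walk with standard deviation drift_sd_mm at the trace end
        out += np.cumsum(rng.normal(0.0, params.drift_sd_mm / np.sqrt(n), size=n))
    return out


def _add_blinks(
    rng: np.random.Generator, pupil: np.ndarray, valid: np.ndarray, params: PlrParams, rate_hz: float
) -> None:
    if params.blink_rate_hz <= 0:
        return
    duration_s = pupil.size / rate_hz
    n_blinks = rng.poisson(params.blink_rate_hz * duration_s)
    lo, hi = params.blink_dur_range_s
    for _ in range(n_blinks):
        dur = rng.uniform(lo, hi)
        onset = rng.uniform(0.0, max(duration_s - dur, 0.0))
        i0 = int(onset * rate_hz)
        i1 = min(int((onset + dur) * rate_hz), pupil.size)
        valid[i0:i1] = False
        pupil[i0:i1] = 0.0  # tracker dropout


def _gaze_channels(
    rng: np.random.Generator,
    n: int,
    rate_hz: float,
    params: PlrParams,
    plant_break: bool,
    break_window: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    gx = rng.normal(0.0, params.gaze_jitter_deg, size=n) if params.gaze_jitter_deg > 0 else np.zeros(n)
    gy = rng.normal(0.0, params.gaze_jitter_deg, size=n) if params.gaze_jitter_deg > 0 else np.zeros(n)
    if plant_break:
        # look-away from fixation: amplitude safely beyond the 6.93 deg
        # criterion; duration long enough that at least one block of the
        # x10-downsampled gaze record is fully covered even at a 100 Hz
        # acquisition rate
        dur = rng.uniform(0.25, 0.5)
        w0, w1 = break_window
        onset = rng.uniform(w0, max(w1 - dur, w0))
        amp = rng.uniform(9.0, 13.0)
        angle = rng.uniform(0.0, 2 * np.pi)
        i0 = int(onset * rate_hz)
        i1 = min(int((onset + dur) * rate_hz), n)
        gx[i0:i1] += amp * np.cos(angle)
        gy[i0:i1] += amp * np.sin(angle)
    return gx, gy


def _mm_to_au(pupil_mm: np.ndarray, params: PlrParams) -> np.ndarray:
    return (pupil_mm - params.au_intercept) / params.au_slope


def _finalize_trace(
    rng: np.random.Generator,
    t: np.ndarray,
    pupil_mm: np.ndarray,
    params: PlrParams,
    rate_hz: float,
    plant_break: bool = False,
    break_window: tuple[float, float] | None = None,
) -> PupilTrace:
    pupil = _add_noise(rng, pupil_mm, params)
    valid = np.ones(t.size, dtype=bool)
    gx, gy = _gaze_channels(
        rng, t.size, rate_hz, params, plant_break, break_window or (0.0, t[-1] if t.size else 0.0)
    )
    au = _mm_to_au(pupil, params)
    _add_blinks(rng, au, valid, params, rate_hz)
    return PupilTrace(
        t=t, pupil=au, gaze_x=gx, gaze_y=gy, valid=valid, sample_rate_hz=rate_hz, unit="au"
    )


def simulate_calibration_session(
    params: PlrParams, design: StudyDesign, participant_id: int
) -> list[TrialRecord]:
    """Flash trials: every intensity x colour, ``calibration_reps`` times, in
    a seeded random order; each trace covers flash onset to flash + post."""
    if design.phase != "calibration":
        raise ValueError(f"design phase must be 'calibration', got {design.phase!r}")
    rng = _session_rng(params, "calibration", participant_id)
    p = _participant_params(params, participant_id)
    rate = design.sample_rate_hz
    t = _time_grid(design.calibration_trial_duration_s, rate)

    conditions = [
        (color, intensity)
        for _ in range(design.calibration_reps)
        for color in COLORS
        for intensity in design.calibration_intensities
    ]
    order = rng.permutation(len(conditions))
    records = []
    for trial_id, idx in enumerate(order):
        color, intensity = conditions[idx]
        rc, mel = intensity_to_drives(p, color, intensity)
        pupil = plr_kernel(p, rc, mel, t)
        if p.trial_baseline_sd_mm > 0:
            pupil = pupil + rng.normal(0.0, p.trial_baseline_sd_mm)
        trace = _finalize_trace(rng, t, pupil, p, rate)
        records.append(
            TrialRecord(
                participant_id=participant_id,
                trial_id=trial_id,
                phase="calibration",
                trace=trace,
                color=color,
                intensity_pct=float(intensity),
                stream_onset_s=0.0,
                stream_duration_s=design.calibration_trial_duration_s,
            )
        )
    return records


def _intensity_lookup(calibration, design: StudyDesign, params: PlrParams) -> dict[str, float]:
    """Accept a CalibrationOutcome, a mapping, or None (analytic matching)."""
    if calibration is None:
        table = analytic_calibration_intensities(params)
    elif isinstance(calibration, Mapping):
        table = dict(calibration)
    else:
        table = {
            key: getattr(calibration, key)
            for key in ("bright_red", "bright_blue", "dim_red", "dim_blue")
            if getattr(calibration, key, None) is not None
        }
    for brightness, color in design.placeholder_conditions:
        if f"{brightness}_{color}" not in table:
            raise ValueError(f"calibration is missing an intensity for {brightness} {color}")
    return table


def simulate_validation_session(
    params: PlrParams, design: StudyDesign, calibration, participant_id: int
) -> list[TrialRecord]:
    """Prolonged full-field exposures to the calibrated intensities,
    ``validation_reps`` repetitions per condition in seeded random order."""
    if design.phase != "validation":
        raise ValueError(f"design phase must be 'validation', got {design.phase!r}")
    rng = _session_rng(params, "validation", participant_id)
    p = _participant_params(params, participant_id)
    intensities = _intensity_lookup(calibration, design, params)
    rate = design.sample_rate_hz
    t = _time_grid(design.validation_trial_duration_s, rate)
    n_on = int(round(design.stream_duration_s * rate))

    conditions = [
        (brightness, color)
        for _ in range(design.validation_reps)
        for brightness, color in design.validation_conditions
    ]
    order = rng.permutation(len(conditions))
    records = []
    for trial_id, idx in enumerate(order):
        brightness, color = conditions[idx]
        rc, mel = intensity_to_drives(p, color, intensities[f"{brightness}_{color}"])
        pupil = plr_kernel(p, rc, mel, t)
        # stimulus offset: clamp the drive response after stream end by
        # holding the last stimulated value (recovery dynamics are not
        # analysed; the trailing black-screen samples are kept for realism)
        pupil[n_on:] = pupil[n_on - 1]
        if p.trial_baseline_sd_mm > 0:
            pupil = pupil + rng.normal(0.0, p.trial_baseline_sd_mm)
        trace = _finalize_trace(rng, t, pupil, p, rate)
        records.append(
            TrialRecord(
                participant_id=participant_id,
                trial_id=trial_id,
                phase="validation",
                trace=trace,
                color=color,
                brightness=brightness,
                intensity_pct=float(intensities[f"{brightness}_{color}"]),
                stream_onset_s=0.0,
                stream_duration_s=design.stream_duration_s,
            )
        )
    return records


def _main_conditions(rng: np.random.Generator, design: StudyDesign) -> list[tuple[str, str, str, str]]:
    grid = design.condition_grid
    reps, extra = divmod(design.n_trials, len(grid))
    conditions = grid * reps
    if extra:
        conditions += [grid[i] for i in rng.choice(len(grid), size=extra, replace=False)]
    order = rng.permutation(len(conditions))
    return [conditions[i] for i in order]


def simulate_main_session(
    params: PlrParams, design: StudyDesign, calibration, participant_id: int
) -> list[TrialRecord]:
    """Cued dual-stream trials with fully crossed placeholder conditions.

    Scene drives combine the attended and ignored placeholders through the
    attention weights and the placeholder scale of each pathway:

        drive = scale * (w * drive_attended + (1 - w) * drive_ignored).

    Behavioural correctness is condition-independent with probability
    ``p_correct``; a seeded fraction of trials receives a planted fixation
    break (``fixation_break_prob``) or an extreme baseline offset
    (``baseline_outlier_frac``), recorded as ground truth on the record.
    """
    if design.phase != "main":
        raise ValueError(f"design phase must be 'main', got {design.phase!r}")
    rng = _session_rng(params, "main", participant_id)
    p = _participant_params(params, participant_id)
    intensities = _intensity_lookup(calibration, design, params)
    rate = design.sample_rate_hz
    t = _time_grid(design.main_trial_duration_s, rate)
    onset = design.stream_onset_s

    records = []
    for trial_id, (ab, ac, ib, ic) in enumerate(_main_conditions(rng, design)):
        rc_att, mel_att = intensity_to_drives(p, ac, intensities[f"{ab}_{ac}"])
        rc_ign, mel_ign = intensity_to_drives(p, ic, intensities[f"{ib}_{ic}"])
        w_rc, w_ip = p.attention_weight_rc, p.attention_weight_ip
        rc = p.placeholder_scale_rc * (w_rc * rc_att + (1.0 - w_rc) * rc_ign)
        mel = p.placeholder_scale_ip * (w_ip * mel_att + (1.0 - w_ip) * mel_ign)
        pupil = plr_kernel(p, rc, mel, t - onset)
        if p.trial_baseline_sd_mm > 0:
            pupil = pupil + rng.normal(0.0, p.trial_baseline_sd_mm)
        planted_outlier = rng.random() < p.baseline_outlier_frac
        if planted_outlier:
            pupil = pupil + rng.choice([-1.0, 1.0]) * p.baseline_outlier_offset_mm
        plant_break = rng.random() < p.fixation_break_prob
        trace = _finalize_trace(
            rng, t, pupil, p, rate,
            plant_break=plant_break,
            break_window=(onset, onset + design.stream_duration_s),
        )
        n_targets = int(rng.binomial(design.n_letters, design.target_prob))
        correct = bool(rng.random() < p.p_correct)
        if correct:
            reported = n_targets
        else:
            reported = n_targets + (1 if (n_targets == 0 or rng.random() < 0.5) else -1)
        records.append(
            TrialRecord(
                participant_id=participant_id,
                trial_id=trial_id,
                phase="main",
                trace=trace,
                attended_color=ac,
                attended_brightness=ab,
                ignored_color=ic,
                ignored_brightness=ib,
                cue_side="left" if rng.random() < 0.5 else "right",
                n_targets=n_targets,
                reported_targets=reported,
                correct=correct,
                stream_onset_s=onset,
                stream_duration_s=design.stream_duration_s,
                planted_fixation_break=plant_break,
                planted_baseline_outlier=planted_outlier,
            )
        )
    return records


FIXTURE_KINDS = ("tiny-calibration", "tiny-main", "planted-exclusions")


def make_fixture(kind: str, seed: int, outdir: str | Path) -> dict:
    """Write a small on-disk dataset (samples.csv + trials.csv) for tests
    and documentation; returns a manifest describing it.

    ``planted-exclusions`` zeroes the natural baseline/drift variability so
    that the gaze- and baseline-exclusion rules flag exactly the planted
    trials, and writes the planted trial ids to ``manifest.json``.
    """
    from .io import write_samples, write_trials  # local import: io is format-only

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "tiny-calibration":
        params = PlrParams(seed=seed, blink_rate_hz=0.05)
        design = StudyDesign(phase="calibration", sample_rate_hz=100.0, intensity_step=20.0)
        records = simulate_calibration_session(params, design, participant_id=0)
    elif kind == "tiny-main":
        params = PlrParams(seed=seed, blink_rate_hz=0.05)
        design = StudyDesign(phase="main", sample_rate_hz=100.0, n_trials=16)
        records = simulate_main_session(params, design, None, participant_id=0)
    elif kind == "planted-exclusions":
        params = PlrParams(
            seed=seed,
            noise_sd_mm=0.01,
            drift_sd_mm=0.0,
            trial_baseline_sd_mm=0.0,
            subject_baseline_sd_mm=0.0,
            subject_gain_cv=0.0,
            blink_rate_hz=0.05,
            gaze_jitter_deg=0.3,
            fixation_break_prob=0.1,
            baseline_outlier_frac=0.05,
        )
        design = StudyDesign(phase="main", sample_rate_hz=100.0, n_trials=100)
        records = simulate_main_session(params, design, None, participant_id=0)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")

    write_samples(outdir / "samples.csv", records)
    write_trials(outdir / "trials.csv", records)
    manifest = {
        "kind": kind,
        "seed": int(seed),
        "n_trials": len(records),
        "sample_rate_hz": records[0].trace.sample_rate_hz,
        "planted_gaze_trials": sorted(
            r.trial_id for r in records if r.planted_fixation_break
        ),
        "planted_baseline_trials": sorted(
            r.trial_id
            for r in records
            if r.planted_baseline_outlier and not r.planted_fixation_break
        ),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
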