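"""Pupil-trace preprocessing and trial exclusion.

The pipeline order is fixed: blink interpolation -> x10 downsampling ->
arbitrary-units-to-mm conversion -> baseline correction (first 50 ms after
stream onset) -> gaze-deviation exclusion (> 6.93 deg for strictly more than
10 ms within the analysed interval) -> within-participant baseline z-score
exclusion (|z| > 2).  Each trial carries its first triggered exclusion
reason; the report partitions the input exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .trace import PupilTrace, TrialRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ExclusionReport",
    "interpolate_blinks",
    "downsample",
    "au_to_mm",
    "baseline_correct",
    "gaze_exclusion",
    "baseline_outlier_exclusion",
    "preprocess_trials",
    "TrialUnusableError",
]


class TrialUnusableError(ValueError):
    """The trace cannot be preprocessed (e.g. no valid samples at all)."""


@dataclass
class ExclusionReport:
    n_input: int = 0
    n_gaze_excluded: int = 0
    n_baseline_excluded: int = 0
    reasons: dict = field(default_factory=dict)  # (participant, trial) -> reason code

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_gaze_excluded - self.n_baseline_excluded

    def merged_with(self, other: "ExclusionReport") -> "ExclusionReport":
        merged = ExclusionReport(
            n_input=self.n_input or other.n_input,
            n_gaze_excluded=self.n_gaze_excluded + other.n_gaze_excluded,
            n_baseline_excluded=self.n_baseline_excluded + other.n_baseline_excluded,
        )
        merged.reasons = {**self.reasons, **other.reasons}
        return merged

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_gaze_excluded": self.n_gaze_excluded,
            "n_baseline_excluded": self.n_baseline_excluded,
            "n_retained": self.n_retained,
            "excluded_pct": round(100.0 * (self.n_input - self.n_retained) / self.n_input, 2)
            if self.n_input
            else 0.0,
            "reasons": {f"{p}:{t}": r for (p, t), r in sorted(self.reasons.items())},
        }


def _invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of invalid samples."""
    padded = np.concatenate(([True], valid, [True]))
    flips = np.flatnonzero(padded[1:] != padded[:-1])
    return [(flips[i], flips[i + 1]) for i in range(0, flips.size, 2)]


def _anchor_point(
    t: np.ndarray, pupil: np.ndarray, ok: np.ndarray, center: int, half: int
) -> tuple[float, float] | None:
    """(time, value) anchor: means over the valid samples in a short window
    around ``center`` (noise-robust support for the interpolating cubic)."""
    lo, hi = max(center - half, 0), min(center + half + 1, pupil.size)
    sel = ok[lo:hi]
    if not sel.any():
        return None
    return float(t[lo:hi][sel].mean()), float(pupil[lo:hi][sel].mean())


def interpolate_blinks(trace: PupilTrace, margin_s: float = 0.05) -> PupilTrace:
    """Replace invalid (blink/dropout) runs by local cubic interpolation.

    Each invalid run is widened by ``margin_s`` on both sides (skipping the
    partial-occlusion samples flanking a blink); four anchor points are
    placed one and two margins before and after the widened run, their
    values taken as short local means of valid samples, and the gap is
    filled by the cubic through those anchors (linear if fewer than four
    anchors are available).  Runs touching the trace edge are filled by
    nearest-valid extension.  Validity flags are kept for audit.
    """
    if not trace.valid.any():
        raise TrialUnusableError("trace has no valid samples to interpolate from")
    if trace.valid.all():
        return trace.copy()
    out = trace.copy()
    n = trace.n_samples
    margin = max(int(round(margin_s * trace.sample_rate_hz)), 1)
    half = margin
    ok = trace.valid.copy()
    runs = []
    for start, stop in _invalid_runs(trace.valid):
        lo, hi = max(start - margin, 0), min(stop + margin, n)
        ok[lo:hi] = False
        runs.append((lo, hi))
    if not ok.any():
        raise TrialUnusableError("no anchor samples left after margin widening")
    for lo, hi in runs:
        anchor_idx = [lo - 1 - 2 * margin, lo - 1, hi, hi + 2 * margin]
        anchors = [
            _anchor_point(trace.t, trace.pupil, ok, i, half)
            for i in anchor_idx
            if 0 <= i < n
        ]
        anchors = [a for a in anchors if a is not None]
        anchors = [a for i, a in enumerate(anchors) if i == 0 or a[0] > anchors[i - 1][0]]
        if not anchors:
            # fall back to the nearest valid sample anywhere in the trace
            valid_idx = np.flatnonzero(ok)
            nearest = valid_idx[np.argmin(np.abs(valid_idx - (lo + hi) / 2))]
            out.pupil[lo:hi] = trace.pupil[nearest]
            continue
        gap_t = trace.t[lo:hi]
        if lo == 0 or hi == n:
            # run touches the trace edge: nearest-valid extension
            nearest = anchors[-1][1] if lo == 0 else anchors[0][1]
            out.pupil[lo:hi] = nearest
        elif len(anchors) >= 2:
            at = np.array([a[0] for a in anchors])
            av = np.array([a[1] for a in anchors])
            deg = min(3, len(anchors) - 1)
            poly = np.polynomial.Polynomial.fit(at, av, deg)
            out.pupil[lo:hi] = poly(gap_t)
        elif len(anchors) == 1:
            out.pupil[lo:hi] = anchors[0][1]  # edge run: nearest-valid extension
        else:  # pragma: no cover - guarded by the ok.any() check above
            raise TrialUnusableError("invalid run with no usable anchors")
    return out


def downsample(trace: PupilTrace, factor: int) -> PupilTrace:
    """Block-mean downsampling; a trailing partial block is dropped."""
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor!r}")
    factor = int(factor)
    if factor == 1:
        return trace.copy()
    n_blocks, remainder = divmod(trace.n_samples, factor)
    if n_blocks == 0:
        raise ValueError("trace shorter than one downsampling block")
    if remainder:
        logger.debug("downsample: dropping %d trailing samples", remainder)

    def block_mean(x: np.ndarray) -> np.ndarray:
        return x[: n_blocks * factor].reshape(n_blocks, factor).mean(axis=1)

    return PupilTrace(
        t=block_mean(trace.t),
        pupil=block_mean(trace.pupil),
        gaze_x=block_mean(trace.gaze_x),
        gaze_y=block_mean(trace.gaze_y),
        valid=trace.valid[: n_blocks * factor].reshape(n_blocks, factor).all(axis=1),
        sample_rate_hz=trace.sample_rate_hz / factor,
        unit=trace.unit,
    )


def au_to_mm(trace: PupilTrace, slope: float, intercept: float) -> PupilTrace:
    """Affine conversion from tracker arbitrary units to millimetres."""
    if trace.unit != "au":
        raise ValueError(f"trace unit is {trace.unit!r}; expected arbitrary units")
    out = trace.copy()
    out.pupil = slope * trace.pupil + intercept
    out.unit = "mm"
    if np.any(out.pupil[out.valid] <= 0):
        raise TrialUnusableError("non-positive pupil diameter after mm conversion")
    return out


def baseline_correct(
    record: TrialRecord, window_s: tuple[float, float] = (0.0, 0.05)
) -> TrialRecord:
    """Subtract the mean pupil size over ``window_s`` (relative to the
    record's stream onset); the baseline value is stored for outlier
    screening."""
    trace = record.trace
    if trace is None:
        raise TrialUnusableError("record has no trace")
    sl = trace.window_slice(record.stream_onset_s + window_s[0], record.stream_onset_s + window_s[1])
    window_valid = trace.valid[sl]
    if sl.stop <= sl.start or not window_valid.any():
        raise TrialUnusableError("baseline window empty or fully invalid")
    baseline = float(trace.pupil[sl].mean())
    out = trace.copy()
    out.pupil = trace.pupil - baseline
    return record.replace(trace=out, baseline=baseline)


def _analysis_window(record: TrialRecord) -> tuple[float, float]:
    start = record.stream_onset_s
    if record.stream_duration_s is not None:
        return start, start + record.stream_duration_s
    return start, float(record.trace.t[-1]) + 1.0 / record.trace.sample_rate_hz


def gaze_exclusion(
    records: Sequence[TrialRecord],
    max_dev_deg: float = 6.93,
    min_dur_ms: float = 10.0,
) -> tuple[list[TrialRecord], ExclusionReport]:
    """Exclude trials whose Euclidean gaze deviation from screen centre
    exceeds ``max_dev_deg`` continuously for strictly more than
    ``min_dur_ms`` within the analysed (stream) interval."""
    report = ExclusionReport(n_input=len(records))
    retained = []
    for rec in records:
        trace = rec.trace
        if trace is None or trace.gaze_x is None:
            raise ValueError(f"trial {rec.key} is missing gaze channels")
        sl = trace.window_slice(*_analysis_window(rec))
        dev = np.hypot(trace.gaze_x[sl], trace.gaze_y[sl])
        over = dev > max_dev_deg
        dt_ms = 1000.0 / trace.sample_rate_hz
        longest = max(
            ((stop - start) * dt_ms for start, stop in _true_runs(over)), default=0.0
        )
        if longest > min_dur_ms:
            report.n_gaze_excluded += 1
            report.reasons[rec.key] = "gaze_deviation"
        else:
            retained.append(rec)
    return retained, report


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], mask, [False]))
    flips = np.flatnonzero(padded[1:] != padded[:-1])
    return [(flips[i], flips[i + 1]) for i in range(0, flips.size, 2)]


def baseline_outlier_exclusion(
    records: Sequence[TrialRecord], z_crit: float = 2.0
) -> tuple[list[TrialRecord], ExclusionReport]:
    """Exclude trials whose baseline pupil size deviates more than
    ``z_crit`` z-scores from the participant's own baseline distribution.

    Z-scores are computed within participant (between-participant pupil-size
    differences would otherwise dominate).  Participants with fewer than
    three trials, or zero baseline variance, contribute no exclusions.
    """
    report = ExclusionReport(n_input=len(records))
    by_participant: dict[int, list[TrialRecord]] = {}
    for rec in records:
        if rec.baseline is None:
            raise ValueError(f"trial {rec.key} has no baseline; run baseline_correct first")
        by_participant.setdefault(rec.participant_id, []).append(rec)
    retained = []
    for pid, recs in by_participant.items():
        baselines = np.array([r.baseline for r in recs], dtype=float)
        if len(recs) < 3:
            warnings.warn(
                f"participant {pid}: fewer than 3 trials, skipping baseline screening",
                stacklevel=2,
            )
            retained.extend(recs)
            continue
        sd = baselines.std(ddof=1)
        if sd == 0.0:
            retained.extend(recs)
            continue
        z = (baselines - baselines.mean()) / sd
        for rec, zi in zip(recs, z):
            if np.abs(zi) > z_crit:
                report.n_baseline_excluded += 1
                report.reasons[rec.key] = "baseline_outlier"
            else:
                retained.append(rec)
    retained.sort(key=lambda r: r.key)
    return retained, report


def preprocess_trials(
    records: Sequence[TrialRecord],
    downsample_factor: int = 10,
    au_slope: float = 0.0025,
    au_intercept: float = 0.0,
    baseline_window_s: tuple[float, float] = (0.0, 0.05),
    blink_margin_s: float = 0.05,
    max_gaze_dev_deg: float = 6.93,
    min_gaze_dur_ms: float = 10.0,
    baseline_z_crit: float = 2.0,
    apply_exclusions: bool = True,
) -> tuple[list[TrialRecord], ExclusionReport]:
    """Run the full fixed-order preprocessing chain on a set of trials.

    Trials that become unusable (no valid samples, empty baseline window)
    are dropped and counted as gaze exclusions with their own reason code.
    """
    processed: list[TrialRecord] = []
    report = ExclusionReport(n_input=len(records))
    for rec in records:
        try:
            trace = interpolate_blinks(rec.trace, margin_s=blink_margin_s)
            trace = downsample(trace, downsample_factor)
            if trace.unit == "au":
                trace = au_to_mm(trace, au_slope, au_intercept)
            new_rec = baseline_correct(rec.replace(trace=trace), window_s=baseline_window_s)
        except TrialUnusableError as exc:
            logger.info("trial %s unusable: %s", rec.key, exc)
            report.reasons[rec.key] = f"unusable:{exc}"
            report.n_gaze_excluded += 1
            continue
        processed.append(new_rec)
    if not apply_exclusions:
        return processed, report
    retained, gaze_report = gaze_exclusion(
        processed, max_dev_deg=max_gaze_dev_deg, min_dur_ms=min_gaze_dur_ms
    )
    retained, base_report = baseline_outlier_exclusion(retained, z_crit=baseline_z_crit)
    return retained, report.merged_with(gaze_report).merged_with(base_report)
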