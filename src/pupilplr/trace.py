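"""Sample-level and trial-level containers.

A :class:`PupilTrace` is one trial's uniformly sampled record of pupil size,
gaze position (degrees from screen centre) and per-sample validity; a
:class:`TrialRecord` binds a trace to its trial metadata (phase, conditions,
behaviour) and accumulates derived quantities (baseline, exclusion flags) as
the trace moves through the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

UNITS = ("au", "mm")


@dataclass
class PupilTrace:
    t: np.ndarray  # seconds from trial onset, uniform grid
    pupil: np.ndarray  # diameter, in `unit`
    gaze_x: np.ndarray  # degrees from screen centre
    gaze_y: np.ndarray
    valid: np.ndarray  # False during blinks / dropouts
    sample_rate_hz: float
    unit: str = "au"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.gaze_x = np.asarray(self.gaze_x, dtype=float)
        self.gaze_y = np.asarray(self.gaze_y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t.size
        for name in ("pupil", "gaze_x", "gaze_y", "valid"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name!r} length differs from time grid")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if n >= 2:
            dt = np.diff(self.t)
            if dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time grid must be strictly increasing and uniform")

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.n_samples > 1 else 0.0

    def copy(self) -> "PupilTrace":
        return PupilTrace(
            t=self.t.copy(),
            pupil=self.pupil.copy(),
            gaze_x=self.gaze_x.copy(),
            gaze_y=self.gaze_y.copy(),
            valid=self.valid.copy(),
            sample_rate_hz=self.sample_rate_hz,
            unit=self.unit,
        )

    def window_slice(self, start_s: float, stop_s: float) -> slice:
        """Index slice of samples with start_s <= t < stop_s."""
        i0 = int(np.searchsorted(self.t, start_s - 1e-12, side="left"))
        i1 = int(np.searchsorted(self.t, stop_s - 1e-12, side="left"))
        return slice(i0, i1)


@dataclass
class TrialRecord:
    participant_id: int
    trial_id: int
    phase: str  # calibration | validation | main
    trace: Optional[PupilTrace] = None
    # calibration / validation conditions (full-field display)
    color: Optional[str] = None
    brightness: Optional[str] = None
    intensity_pct: Optional[float] = None
    # main-experiment conditions (dual placeholder streams)
    attended_color: Optional[str] = None
    attended_brightness: Optional[str] = None
    ignored_color: Optional[str] = None
    ignored_brightness: Optional[str] = None
    cue_side: Optional[str] = None
    # behaviour
    n_targets: Optional[int] = None
    reported_targets: Optional[int] = None
    correct: Optional[bool] = None
    # timing anchor of the analysed interval (stream / stimulus onset)
    stream_onset_s: float = 0.0
    stream_duration_s: Optional[float] = None
    # generator ground truth, for planted-manifest tests
    planted_fixation_break: bool = False
    planted_baseline_outlier: bool = False
    # pipeline-derived
    baseline: Optional[float] = None
    unusable: bool = False
    unusable_reason: Optional[str] = None

    def replace(self, **kwargs) -> "TrialRecord":
        return replace(self, **kwargs)

    def with_trace(self, trace: PupilTrace) -> "TrialRecord":
        return self.replace(trace=trace)

    @property
    def key(self) -> tuple[int, int]:
        return (self.participant_id, self.trial_id)
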