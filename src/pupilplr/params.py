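"""Parameter and design containers for the two-pathway PLR simulator.

The pupillary light response (PLR) to a sustained stimulus decomposes into a
transient component driven by rods and cones (onset latency ~200 ms, adapting
with a time constant of ~1.75 s toward a non-zero residual) and a sustained
component driven by melanopsin-expressing ipRGCs (emerging seconds after
onset, saturating slowly).  :class:`PlrParams` collects the kernel constants,
the intensity-to-drive map, the attentional weighting used in the cued
dual-stream task, and the nuisance processes (noise, drift, blinks, gaze
jitter) of the synthetic eye-tracking record.

Defaults are set so that, with the default study designs, the generating
window-mean effects are: direct-gaze brightness 0.84 mm, direct-gaze colour
(blue vs. red at matched rod/cone drive) 0.19 mm, covert-attention brightness
one quarter of the direct effect, and covert-attention colour exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

COLORS = ("red", "blue")
BRIGHTNESS_LEVELS = ("dim", "bright")

#: fraction of dual-stream attention allocated to the cued stream, calibrated
#: together with ``placeholder_scale_rc`` so the covert brightness effect is
#: one quarter of the direct one (0.366 * 0.75 * direct rod/cone effect).
_DEFAULT_ATTENTION_RC = 0.75
_DEFAULT_PLACEHOLDER_RC = 0.366


@dataclass
class PlrParams:
    """Kernel, drive-map and nuisance parameters of the synthetic PLR.

    All gains are in mm of constriction per unit drive; time constants in
    seconds.  ``attention_weight_*`` live in [0.5, 1]: 0.5 means the attended
    and ignored streams contribute equally (no attentional weighting).
    ``placeholder_scale_*`` scale the drive of the small peripheral
    placeholder circles of the dual-stream task relative to a full-field
    display of the same colour/intensity; the melanopic placeholder scale
    defaults to 0 because small parafoveal patches contribute negligibly to
    the sustained melanopic response (and the covert colour contrast is then
    an exact null).
    """

    baseline_mm: float = 5.5
    # transient rod/cone pathway
    rc_gain: float = 4.16
    rc_latency: float = 0.2
    rc_rise_tau: float = 0.15
    rc_adapt_tau: float = 1.75
    rc_residual_frac: float = 0.3
    # sustained melanopic (ipRGC) pathway
    ip_gain: float = 0.5
    ip_latency: float = 3.0
    ip_rise_tau: float = 4.0
    melanopic_weight_blue: float = 1.0
    melanopic_weight_red: float = 0.1
    # intensity -> drive map
    gamma_intensity: float = 1.0
    color_gain_red: float = 1.25
    color_gain_blue: float = 1.0
    # attentional weighting of the two streams (main experiment)
    attention_weight_rc: float = _DEFAULT_ATTENTION_RC
    attention_weight_ip: float = 0.5
    placeholder_scale_rc: float = _DEFAULT_PLACEHOLDER_RC
    placeholder_scale_ip: float = 0.0
    # nuisance processes
    noise_sd_mm: float = 0.05
    drift_sd_mm: float = 0.3
    blink_rate_hz: float = 0.1
    blink_dur_range_s: Tuple[float, float] = (0.1, 0.3)
    gaze_jitter_deg: float = 0.5
    fixation_break_prob: float = 0.105
    # between-participant / between-trial variation
    subject_baseline_sd_mm: float = 0.5
    subject_gain_cv: float = 0.15
    trial_baseline_sd_mm: float = 0.15
    baseline_outlier_frac: float = 0.02
    baseline_outlier_offset_mm: float = 2.5
    # behaviour
    p_correct: float = 0.8
    # affine mm <-> arbitrary-units map of the simulated tracker record
    au_slope: float = 0.0025
    au_intercept: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "baseline_mm": self.baseline_mm,
            "rc_gain": self.rc_gain,
            "rc_rise_tau": self.rc_rise_tau,
            "rc_adapt_tau": self.rc_adapt_tau,
            "ip_gain": self.ip_gain,
            "ip_rise_tau": self.ip_rise_tau,
            "color_gain_red": self.color_gain_red,
            "color_gain_blue": self.color_gain_blue,
            "gamma_intensity": self.gamma_intensity,
            "au_slope": self.au_slope,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.rc_latency < 0 or self.ip_latency < 0:
            raise ValueError("latencies must be non-negative")
        if not 0 <= self.rc_residual_frac <= 1:
            raise ValueError("rc_residual_frac must lie in [0, 1]")
        if not self.melanopic_weight_blue > self.melanopic_weight_red >= 0:
            raise ValueError(
                "melanopic weights must satisfy blue > red >= 0 "
                f"(got blue={self.melanopic_weight_blue}, red={self.melanopic_weight_red})"
            )
        for name in ("attention_weight_rc", "attention_weight_ip"):
            w = getattr(self, name)
            if not 0.5 <= w <= 1.0:
                raise ValueError(f"{name} must lie in [0.5, 1], got {w!r}")
        for name in ("placeholder_scale_rc", "placeholder_scale_ip"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.p_correct <= 1:
            raise ValueError("p_correct must lie in [0, 1]")
        lo, hi = self.blink_dur_range_s
        if not 0 < lo <= hi:
            raise ValueError("blink_dur_range_s must be an increasing positive pair")

    def replace(self, **kwargs) -> "PlrParams":
        return replace(self, **kwargs)

    def color_gain(self, color: str) -> float:
        _check_color(color)
        return self.color_gain_red if color == "red" else self.color_gain_blue

    def melanopic_weight(self, color: str) -> float:
        _check_color(color)
        return self.melanopic_weight_red if color == "red" else self.melanopic_weight_blue

    def noiseless(self) -> "PlrParams":
        """Copy with every stochastic nuisance process switched off."""
        return self.replace(
            noise_sd_mm=0.0,
            drift_sd_mm=0.0,
            blink_rate_hz=0.0,
            gaze_jitter_deg=0.0,
            fixation_break_prob=0.0,
            subject_baseline_sd_mm=0.0,
            subject_gain_cv=0.0,
            trial_baseline_sd_mm=0.0,
            baseline_outlier_frac=0.0,
        )


def _check_color(color: str) -> None:
    if color not in COLORS:
        raise ValueError(f"unknown color {color!r}; expected one of {COLORS}")


PHASES = ("calibration", "validation", "main")


@dataclass
class StudyDesign:
    """Trial-count and timing structure of one experimental phase.

    ``variant`` selects the primary study (fully crossed 4x4 placeholder
    grid, 224 main trials, 28 validation trials) or the bright-only follow-up
    (2x2 grid restricted to bright placeholders, 200 main trials, 20
    validation trials).
    """

    phase: str = "main"
    variant: str = "primary"
    n_participants: int = 30
    n_trials: int | None = None  # main phase; default from variant
    calibration_reps: int = 2
    validation_reps: int | None = None  # default from variant
    intensity_step: float = 5.0
    stream_duration_s: float = 15.0
    cue_duration_s: float = 1.0
    fixation_duration_s: float = 0.5
    flash_duration_s: float = 0.25
    post_flash_s: float = 3.0
    post_stream_s: float = 2.5
    sample_rate_hz: float = 1000.0
    target_prob: float = 0.2
    n_letters: int = 15

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        if self.variant not in ("primary", "followup"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.n_trials is None:
            self.n_trials = 224 if self.variant == "primary" else 200
        if self.validation_reps is None:
            self.validation_reps = 7 if self.variant == "primary" else 10
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.n_participants < 1:
            raise ValueError("n_participants must be at least 1")

    def replace(self, **kwargs) -> "StudyDesign":
        return replace(self, **kwargs)

    @property
    def calibration_intensities(self) -> list[float]:
        n = int(round(100.0 / self.intensity_step)) + 1
        return [i * self.intensity_step for i in range(n)]

    @property
    def placeholder_conditions(self) -> list[tuple[str, str]]:
        """(brightness, color) levels available for placeholders."""
        if self.variant == "primary":
            return [(b, c) for b in BRIGHTNESS_LEVELS for c in COLORS]
        return [("bright", c) for c in COLORS]

    @property
    def condition_grid(self) -> list[tuple[str, str, str, str]]:
        """Fully crossed (att_brightness, att_color, ign_brightness, ign_color)."""
        conds = self.placeholder_conditions
        return [(ab, ac, ib, ic) for (ab, ac) in conds for (ib, ic) in conds]

    @property
    def validation_conditions(self) -> list[tuple[str, str]]:
        return self.placeholder_conditions

    @property
    def n_calibration_trials(self) -> int:
        return self.calibration_reps * len(self.calibration_intensities) * len(COLORS)

    @property
    def n_validation_trials(self) -> int:
        return self.validation_reps * len(self.validation_conditions)

    @property
    def stream_onset_s(self) -> float:
        return self.fixation_duration_s + self.cue_duration_s

    @property
    def main_trial_duration_s(self) -> float:
        return self.stream_onset_s + self.stream_duration_s

    @property
    def validation_trial_duration_s(self) -> float:
        return self.stream_duration_s + self.post_stream_s

    @property
    def calibration_trial_duration_s(self) -> float:
        return self.flash_duration_s + self.post_flash_s


def primary_design(phase: str = "main", **overrides) -> StudyDesign:
    return StudyDesign(phase=phase, variant="primary", **overrides)


def followup_design(phase: str = "main", **overrides) -> StudyDesign:
    return StudyDesign(phase=phase, variant="followup", **overrides)
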