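"""Isoluminance calibration from flash-evoked pupil responses.

A parametric constriction template is fitted to each flash response with
four parameters — latency shift, baseline, time scale, and constriction
strength — by bounded least squares with a coarse multi-start over the
nonlinear parameters.  Mean constriction strength per (colour, intensity)
is then summarised by a second-order polynomial per colour, and red/blue
intensities with equal predicted strength are matched: the bright pair
fixes the stronger colour's 100 % response as unreachable and reduces it to
the weaker colour's 100 % response; the dim pair fixes blue at 50 % and
solves for the matching red.

The template here is a parametric stand-in (any smooth unimodal
constriction profile works under the four-parameter transform); empirical
templates can be passed as a callable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .trace import PupilTrace, TrialRecord

logger = logging.getLogger(__name__)

__all__ = [
    "default_template",
    "TemplateFit",
    "TemplateFitResult",
    "fit_template",
    "fit_calibration_session",
    "strengths_by_intensity",
    "IntensityResponseCurve",
    "fit_intensity_curve",
    "CalibrationOutcome",
    "match_intensities",
    "calibration_eligibility",
    "validation_eligibility",
    "calibrate_participant",
]


def default_template(shape_k: float = 3.0) -> Callable[[np.ndarray], np.ndarray]:
    """Unit constriction template T(s) = -(s^k * exp(k*(1-s))) for s > 0.

    T(0) = 0, the minimum is exactly -1 at s = 1, and the profile partially
    recovers afterwards (T(4) ~ -0.008 for k = 3).
    """
    if shape_k <= 0:
        raise ValueError("shape_k must be strictly positive")

    def template(s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        su = np.clip(s, 0.0, None)
        with np.errstate(over="ignore"):
            out = -(su**shape_k) * np.exp(shape_k * (1.0 - su))
        return np.where(s > 0, out, 0.0)

    return template


@dataclass
class TemplateFitResult:
    """Four-parameter template fit: p(t) = baseline + strength * T((t - latency_shift)/time_scale)."""

    latency_shift: float  # tau, s
    baseline: float  # v, same unit as the trace
    time_scale: float  # sigma, s
    strength: float  # a >= 0; constriction amplitude
    rss: float
    converged: bool
    n_samples: int = 0

    def predict(self, t: np.ndarray, template: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
        return self.baseline + self.strength * template(
            (np.asarray(t, float) - self.latency_shift) / self.time_scale
        )

    def summary(self) -> str:
        flag = "" if self.converged else "  [not converged]"
        return (
            f"TemplateFit: strength={self.strength:.4f}, latency={self.latency_shift:.3f} s, "
            f"time_scale={self.time_scale:.3f} s, baseline={self.baseline:.4f}, "
            f"rss={self.rss:.3e}, n={self.n_samples}{flag}"
        )


class TemplateFit:
    """Model object for fitting the constriction template to one trace.

    Parameters
    ----------
    trace:
        Preprocessed trace covering the flash and post-flash window.
    template:
        Unit template callable; defaults to :func:`default_template`.
    tau_bounds, sigma_bounds:
        Bounds for the latency shift (around the ~200 ms physiological
        latency) and the time scale.
    """

    def __init__(
        self,
        trace: PupilTrace,
        template: Callable[[np.ndarray], np.ndarray] | None = None,
        tau_bounds: tuple[float, float] = (0.1, 0.6),
        sigma_bounds: tuple[float, float] = (0.1, 3.0),
    ) -> None:
        if not trace.valid.any():
            raise ValueError("cannot fit template to an all-invalid trace")
        self.trace = trace
        self.template = template or default_template()
        self.tau_bounds = tau_bounds
        self.sigma_bounds = sigma_bounds

    def _linear_fit(self, tau: float, sigma: float) -> tuple[float, float, float]:
        """Given (tau, sigma), solve the (baseline, strength>=0) least squares."""
        t, y = self.trace.t, self.trace.pupil
        basis = self.template((t - tau) / sigma)
        bb = float(basis @ basis)
        n = t.size
        bs = float(basis.sum())
        det = n * bb - bs * bs
        if det <= 1e-12:
            v, a = float(y.mean()), 0.0
        else:
            sy, by = float(y.sum()), float(basis @ y)
            v = (bb * sy - bs * by) / det
            a = (n * by - bs * sy) / det
            if a < 0:
                a, v = 0.0, float(y.mean())
        rss = float(((v + a * basis - y) ** 2).sum())
        return v, a, rss

    def fit(self, n_tau: int = 6, n_sigma: int = 8, polish: bool = True) -> TemplateFitResult:
        taus = np.linspace(*self.tau_bounds, n_tau)
        sigmas = np.geomspace(*self.sigma_bounds, n_sigma)
        best = None
        for tau in taus:
            for sigma in sigmas:
                v, a, rss = self._linear_fit(tau, sigma)
                if best is None or rss < best[0]:
                    best = (rss, tau, v, sigma, a)
        rss0, tau0, v0, sigma0, a0 = best
        if not polish:
            return TemplateFitResult(tau0, v0, sigma0, a0, rss0, True, self.trace.n_samples)

        t, y = self.trace.t, self.trace.pupil

        def resid(theta):
            tau, v, sigma, a = theta
            return v + a * self.template((t - tau) / sigma) - y

        scale = max(float(np.ptp(y)), 1e-6)
        sol = least_squares(
            resid,
            x0=[tau0, v0, sigma0, max(a0, 1e-9)],
            bounds=(
                [self.tau_bounds[0], -np.inf, self.sigma_bounds[0], 0.0],
                [self.tau_bounds[1], np.inf, self.sigma_bounds[1], np.inf],
            ),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=2000,
        )
        tau, v, sigma, a = sol.x
        rss = float(2 * sol.cost)
        converged = bool(sol.success)
        if not converged:
            warnings.warn("template fit did not converge; strength reported anyway", stacklevel=2)
        return TemplateFitResult(float(tau), float(v), float(sigma), float(a), rss, converged, t.size)


def fit_template(
    trace: PupilTrace,
    template: Callable[[np.ndarray], np.ndarray] | None = None,
    tau_bounds: tuple[float, float] = (0.1, 0.6),
    sigma_bounds: tuple[float, float] = (0.1, 3.0),
) -> TemplateFitResult:
    """Functional wrapper around :class:`TemplateFit`."""
    return TemplateFit(trace, template, tau_bounds, sigma_bounds).fit()


def fit_calibration_session(
    records: Sequence[TrialRecord],
    template: Callable[[np.ndarray], np.ndarray] | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit the template to every (preprocessed) calibration trial.

    Returns one row per trial: colour, intensity, strength, rss, converged.
    """
    rows = []
    for rec in records:
        res = TemplateFit(rec.trace, template, **fit_kwargs).fit()
        rows.append(
            {
                "participant_id": rec.participant_id,
                "trial_id": rec.trial_id,
                "color": rec.color,
                "intensity_pct": rec.intensity_pct,
                "strength": res.strength,
                "rss": res.rss,
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)


def strengths_by_intensity(fits: pd.DataFrame) -> pd.DataFrame:
    """Mean constriction strength per (colour, intensity); non-converged
    fits are dropped and logged, cells with no usable fits are dropped."""
    usable = fits[fits["converged"]]
    dropped = len(fits) - len(usable)
    if dropped:
        logger.info("strengths_by_intensity: dropping %d non-converged fit(s)", dropped)
    if usable.empty:
        return pd.DataFrame(columns=["color", "intensity_pct", "strength", "n"])
    out = (
        usable.groupby(["color", "intensity_pct"], as_index=False)
        .agg(strength=("strength", "mean"), n=("strength", "size"))
        .sort_values(["color", "intensity_pct"], ignore_index=True)
    )
    return out


@dataclass
class IntensityResponseCurve:
    """Second-order polynomial c(I) = b0 + b1*I + b2*I^2 predicting
    constriction strength (trace units) from stimulus intensity (percent)."""

    color: str
    coef: np.ndarray  # (b0, b1, b2)
    r_squared: float
    support: pd.DataFrame = field(repr=False, default=None)

    def predict(self, intensity_pct) -> np.ndarray | float:
        i = np.asarray(intensity_pct, dtype=float)
        out = self.coef[0] + self.coef[1] * i + self.coef[2] * i**2
        return float(out) if out.ndim == 0 else out

    def derivative(self, intensity_pct) -> np.ndarray | float:
        i = np.asarray(intensity_pct, dtype=float)
        out = self.coef[1] + 2.0 * self.coef[2] * i
        return float(out) if out.ndim == 0 else out

    def is_increasing(self, lo: float = 0.0, hi: float = 100.0) -> bool:
        # derivative of a quadratic is linear: its sign on [lo, hi] is
        # determined by the endpoints
        return self.derivative(lo) > 0 and self.derivative(hi) > 0


def fit_intensity_curve(table: pd.DataFrame, color: str) -> IntensityResponseCurve:
    """Ordinary least-squares quadratic through the (intensity, mean
    strength) support points of one colour."""
    sub = table[table["color"] == color]
    intensities = sub["intensity_pct"].to_numpy(float)
    strengths = sub["strength"].to_numpy(float)
    if np.unique(intensities).size < 3:
        raise ValueError(
            f"need >= 3 distinct intensities to fit a quadratic for {color!r}, "
            f"got {np.unique(intensities).size}"
        )
    X = np.column_stack([np.ones_like(intensities), intensities, intensities**2])
    coef, _, rank, _ = np.linalg.lstsq(X, strengths, rcond=None)
    if rank < 3:
        raise ValueError(f"rank-deficient design for {color!r} intensity curve")
    pred = X @ coef
    ss_res = float(((strengths - pred) ** 2).sum())
    ss_tot = float(((strengths - strengths.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return IntensityResponseCurve(color=color, coef=coef, r_squared=r2, support=sub.copy())


@dataclass
class CalibrationOutcome:
    """Participant-specific matched intensities for dim/bright red/blue."""

    bright_red: float | None = None
    bright_blue: float | None = None
    dim_red: float | None = None
    dim_blue: float | None = None
    matched_strengths: dict = field(default_factory=dict)
    eligible: bool = True
    reasons: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def intensity(self, brightness: str, color: str) -> float:
        value = getattr(self, f"{brightness}_{color}")
        if value is None:
            raise KeyError(f"no matched intensity for {brightness} {color}")
        return value

    def as_dict(self) -> dict:
        return {
            "bright_red": self.bright_red,
            "bright_blue": self.bright_blue,
            "dim_red": self.dim_red,
            "dim_blue": self.dim_blue,
            "matched_strengths": dict(self.matched_strengths),
            "eligible": self.eligible,
            "reasons": list(self.reasons),
            "diagnostics": dict(self.diagnostics),
        }


def _solve_on_increasing_branch(curve: IntensityResponseCurve, target: float) -> float | None:
    """Intensity in [0, 100] where c(I) = target and dc/dI > 0; ties go to
    the larger intensity.  Returns None if no such root exists."""
    b0, b1, b2 = curve.coef
    if abs(b2) < 1e-14:
        if abs(b1) < 1e-14:
            return None
        roots = [(target - b0) / b1]
    else:
        disc = b1 * b1 - 4.0 * b2 * (b0 - target)
        if disc < 0:
            return None
        sq = np.sqrt(disc)
        roots = [(-b1 - sq) / (2 * b2), (-b1 + sq) / (2 * b2)]
    candidates = [
        r for r in roots if -1e-9 <= r <= 100 + 1e-9 and curve.derivative(np.clip(r, 0, 100)) > 0
    ]
    if not candidates:
        return None
    return float(np.clip(max(candidates), 0.0, 100.0))


def match_intensities(
    curve_red: IntensityResponseCurve,
    curve_blue: IntensityResponseCurve,
    dim_blue: float = 50.0,
) -> CalibrationOutcome:
    """Isoluminance matching on the fitted intensity-response curves.

    Bright pair: the target is the smaller of the two 100 % responses; the
    colour with the larger response is reduced to match, the other stays at
    100 %.  Dim pair: blue is fixed (50 % by default) and red is solved to
    match.  Participants whose curves are non-monotone, or for whom no root
    lies in [0, 100], are marked ineligible with the reason recorded.
    """
    outcome = CalibrationOutcome(dim_blue=dim_blue)
    for curve in (curve_red, curve_blue):
        if not curve.is_increasing():
            outcome.eligible = False
            outcome.reasons.append(f"non-monotone intensity-response curve for {curve.color}")
    if not outcome.eligible:
        return outcome

    c_red_100 = curve_red.predict(100.0)
    c_blue_100 = curve_blue.predict(100.0)
    bright_target = min(c_red_100, c_blue_100)
    if c_red_100 >= c_blue_100:
        outcome.bright_blue = 100.0
        outcome.bright_red = _solve_on_increasing_branch(curve_red, bright_target)
        missing = "red" if outcome.bright_red is None else None
    else:
        outcome.bright_red = 100.0
        outcome.bright_blue = _solve_on_increasing_branch(curve_blue, bright_target)
        missing = "blue" if outcome.bright_blue is None else None
    if missing:
        outcome.eligible = False
        outcome.reasons.append(f"no bright-matching {missing} intensity in [0, 100]")
        return outcome

    dim_target = curve_blue.predict(dim_blue)
    outcome.dim_red = _solve_on_increasing_branch(curve_red, dim_target)
    if outcome.dim_red is None:
        outcome.eligible = False
        outcome.reasons.append("no dim-matching red intensity in [0, 100]")
        return outcome

    outcome.matched_strengths = {
        "bright": float(bright_target),
        "dim": float(dim_target),
    }
    outcome.diagnostics = {
        "r_squared_red": curve_red.r_squared,
        "r_squared_blue": curve_blue.r_squared,
    }
    return outcome


def calibration_eligibility(
    curve_red: IntensityResponseCurve,
    curve_blue: IntensityResponseCurve,
    r2_min: float = 0.7,
) -> tuple[bool, dict]:
    """Automated surrogate for a 'systematic and biologically plausible'
    constriction pattern: both curves must fit well (r^2 >= ``r2_min``) and
    be strictly increasing over the intensity range."""
    diagnostics = {
        "r_squared_red": curve_red.r_squared,
        "r_squared_blue": curve_blue.r_squared,
        "increasing_red": curve_red.is_increasing(),
        "increasing_blue": curve_blue.is_increasing(),
        "r2_min": r2_min,
    }
    eligible = (
        curve_red.r_squared >= r2_min
        and curve_blue.r_squared >= r2_min
        and diagnostics["increasing_red"]
        and diagnostics["increasing_blue"]
    )
    return bool(eligible), diagnostics


def validation_eligibility(
    records: Sequence[TrialRecord],
    window_s: float = 5.0,
    margin_mm: float = 0.05,
    rule: str = "primary",
) -> tuple[bool, dict]:
    """Automated surrogate for the sustained-constriction entry criterion.

    Over the final ``window_s`` seconds of the stimulus interval, mean
    pupil size must be larger for red than for blue (i.e. blue constricts
    more) by at least ``margin_mm`` — in both brightness conditions under
    the ``primary`` rule, or in the bright condition only under the
    ``followup`` rule.  Records must be preprocessed validation trials.
    """
    if rule not in ("primary", "followup"):
        raise ValueError(f"unknown rule {rule!r}")
    needed = ("dim", "bright") if rule == "primary" else ("bright",)
    means: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        if rec.phase != "validation" or rec.brightness is None or rec.color is None:
            raise ValueError(f"trial {rec.key} is not a validation trial with conditions")
        stop = rec.stream_onset_s + (rec.stream_duration_s or rec.trace.t[-1])
        sl = rec.trace.window_slice(stop - window_s, stop)
        means.setdefault((rec.brightness, rec.color), []).append(float(rec.trace.pupil[sl].mean()))
    diagnostics = {"window_s": window_s, "margin_mm": margin_mm, "rule": rule}
    eligible = True
    for brightness in needed:
        for color in ("red", "blue"):
            if (brightness, color) not in means:
                raise ValueError(f"missing validation condition: {brightness} {color}")
        diff = float(np.mean(means[(brightness, "red")]) - np.mean(means[(brightness, "blue")]))
        diagnostics[f"red_minus_blue_{brightness}_mm"] = diff
        eligible = eligible and diff > margin_mm
    return bool(eligible), diagnostics


def calibrate_participant(
    records: Sequence[TrialRecord],
    template: Callable[[np.ndarray], np.ndarray] | None = None,
    dim_blue: float = 50.0,
    r2_min: float = 0.7,
    **fit_kwargs,
) -> tuple[CalibrationOutcome, dict]:
    """Full calibration chain on one participant's preprocessed flash
    trials: template fits -> strength table -> quadratic curves ->
    matching -> eligibility."""
    fits = fit_calibration_session(records, template, **fit_kwargs)
    table = strengths_by_intensity(fits)
    curves = {color: fit_intensity_curve(table, color) for color in ("red", "blue")}
    outcome = match_intensities(curves["red"], curves["blue"], dim_blue=dim_blue)
    eligible, diagnostics = calibration_eligibility(curves["red"], curves["blue"], r2_min=r2_min)
    outcome.eligible = outcome.eligible and eligible
    if not eligible:
        outcome.reasons.append("calibration eligibility criterion failed")
    outcome.diagnostics.update(diagnostics)
    return outcome, {"fits": fits, "table": table, "curves": curves}
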