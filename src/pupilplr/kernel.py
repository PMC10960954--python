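"""Closed-form two-pathway PLR kernel and its analytic summaries.

The noiseless pupil trace to a stimulus switched on at t = 0 is

    p(t) = baseline - rc_gain * rc_drive * h(t) - ip_gain * mel_drive * s(t)

with the transient rod/cone impulse

    h(t) = (1 - exp(-(t - L_rc)/tau_rise)) *
           (r + (1 - r) * exp(-(t - L_rc)/tau_adapt)),   t >= L_rc,  else 0

(rise to a peak a few hundred ms after onset, then adaptation toward the
residual fraction ``r`` that models letter-refresh / microsaccadic
re-activation), and the sustained melanopic saturation

    s(t) = 1 - exp(-(t - L_ip)/tau_ip),   t >= L_ip,  else 0.

Both components are linear in their drives, which is what makes template
strengths proportional to stimulus drive and isoluminance matching
well-posed.
"""

from __future__ import annotations

import numpy as np

from .params import PlrParams, _check_color

__all__ = [
    "rc_impulse",
    "ip_saturation",
    "plr_kernel",
    "intensity_to_drives",
    "analytic_match_intensity",
    "analytic_calibration_intensities",
    "expected_window_effects",
]


def _check_uniform_grid(t_grid: np.ndarray) -> None:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("t_grid must be a 1-D array with at least two samples")
    dt = np.diff(t)
    if dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("t_grid must be strictly increasing and uniform")


def rc_impulse(t: np.ndarray, params: PlrParams) -> np.ndarray:
    """Transient rod/cone response h(t), dimensionless in [0, 1)."""
    t = np.asarray(t, dtype=float)
    u = t - params.rc_latency
    rise = -np.expm1(-np.clip(u, 0.0, None) / params.rc_rise_tau)
    r = params.rc_residual_frac
    adapt = r + (1.0 - r) * np.exp(-np.clip(u, 0.0, None) / params.rc_adapt_tau)
    return np.where(u > 0, rise * adapt, 0.0)


def ip_saturation(t: np.ndarray, params: PlrParams) -> np.ndarray:
    """Sustained melanopic response s(t), rising monotonically to 1."""
    t = np.asarray(t, dtype=float)
    v = t - params.ip_latency
    return np.where(v > 0, -np.expm1(-np.clip(v, 0.0, None) / params.ip_rise_tau), 0.0)


def plr_kernel(
    params: PlrParams,
    rc_drive: float,
    melanopic_drive: float,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Noiseless, blink-free pupil diameter (mm) on a uniform time grid.

    ``t_grid`` starts at stimulus onset (t = 0); negative times are allowed
    and return the baseline.
    """
    _check_uniform_grid(t_grid)
    if rc_drive < 0 or melanopic_drive < 0:
        raise ValueError("drives must be non-negative")
    t = np.asarray(t_grid, dtype=float)
    return (
        params.baseline_mm
        - params.rc_gain * rc_drive * rc_impulse(t, params)
        - params.ip_gain * melanopic_drive * ip_saturation(t, params)
    )


def intensity_to_drives(params: PlrParams, color: str, intensity_pct: float) -> tuple[float, float]:
    """Map a colour at ``intensity_pct`` (0-100 % of monitor maximum) to
    (rod/cone drive, melanopic drive) for a full-field display."""
    _check_color(color)
    if not 0 <= intensity_pct <= 100:
        raise ValueError(f"intensity must lie in [0, 100], got {intensity_pct!r}")
    frac = (intensity_pct / 100.0) ** params.gamma_intensity
    return params.color_gain(color) * frac, params.melanopic_weight(color) * frac


def analytic_match_intensity(
    params: PlrParams, fixed_color: str, fixed_intensity_pct: float, solve_color: str
) -> float:
    """Intensity of ``solve_color`` whose rod/cone drive equals that of
    ``fixed_color`` at ``fixed_intensity_pct`` (exact isoluminance solution
    of the generator's power-law drive map)."""
    g_fixed = params.color_gain(fixed_color)
    g_solve = params.color_gain(solve_color)
    gamma = params.gamma_intensity
    frac = (g_fixed / g_solve) * (fixed_intensity_pct / 100.0) ** gamma
    intensity = 100.0 * frac ** (1.0 / gamma)
    if not 0 <= intensity <= 100 + 1e-9:
        raise ValueError(
            f"no {solve_color} intensity in [0, 100] matches "
            f"{fixed_color} at {fixed_intensity_pct}%"
        )
    return float(min(intensity, 100.0))


def analytic_calibration_intensities(params: PlrParams) -> dict[str, float]:
    """The generator's exact isoluminant intensity set.

    The bright pair fixes the weaker-driving colour at 100 % and solves for
    the other; the dim pair fixes blue at 50 % and solves for red, mirroring
    the calibration procedure's conventions.
    """
    if params.color_gain_red >= params.color_gain_blue:
        bright_blue, bright_red = 100.0, analytic_match_intensity(params, "blue", 100.0, "red")
    else:
        bright_red, bright_blue = 100.0, analytic_match_intensity(params, "red", 100.0, "blue")
    dim_blue = 50.0
    dim_red = analytic_match_intensity(params, "blue", dim_blue, "red")
    return {
        "bright_red": bright_red,
        "bright_blue": bright_blue,
        "dim_red": dim_red,
        "dim_blue": dim_blue,
    }


def _window_mean(fn, params: PlrParams, window_s: tuple[float, float], n: int = 20001) -> float:
    t = np.linspace(window_s[0], window_s[1], n)
    return float(np.trapezoid(fn(t, params), t) / (window_s[1] - window_s[0]))


def expected_window_effects(
    params: PlrParams,
    window_s: tuple[float, float] = (0.0, 15.0),
    intensities: dict[str, float] | None = None,
) -> dict[str, float]:
    """Generating window-mean condition effects (mm) implied by the kernel.

    Returns the direct-gaze brightness and colour effects for full-field
    displays at the matched intensity set, and the covert-attention
    counterparts under the placeholder/attention weighting of the main
    experiment.  These are the ground-truth values that parameter-recovery
    tests compare estimated mixed-model coefficients against.
    """
    if intensities is None:
        intensities = analytic_calibration_intensities(params)
    hbar = _window_mean(rc_impulse, params, window_s)
    sbar = _window_mean(ip_saturation, params, window_s)

    def drives(color: str, level: str) -> tuple[float, float]:
        return intensity_to_drives(params, color, intensities[f"{level}_{color}"])

    rc = {(c, b): drives(c, b)[0] for c in ("red", "blue") for b in ("dim", "bright")}
    mel = {(c, b): drives(c, b)[1] for c in ("red", "blue") for b in ("dim", "bright")}

    # direct brightness: bright minus dim, averaged over colours
    d_bright = np.mean(
        [
            params.rc_gain * (rc[(c, "bright")] - rc[(c, "dim")]) * hbar
            + params.ip_gain * (mel[(c, "bright")] - mel[(c, "dim")]) * sbar
            for c in ("red", "blue")
        ]
    )
    # direct colour: blue minus red, averaged over brightness (rod/cone drives matched)
    d_color = np.mean(
        [
            params.rc_gain * (rc[("blue", b)] - rc[("red", b)]) * hbar
            + params.ip_gain * (mel[("blue", b)] - mel[("red", b)]) * sbar
            for b in ("dim", "bright")
        ]
    )
    # covert effects: attended minus ignored weighting of placeholder drives,
    # ignored stream balanced out by the crossed design
    cov_bright = np.mean(
        [
            params.placeholder_scale_rc
            * params.attention_weight_rc
            * params.rc_gain
            * (rc[(c, "bright")] - rc[(c, "dim")])
            * hbar
            + params.placeholder_scale_ip
            * params.attention_weight_ip
            * params.ip_gain
            * (mel[(c, "bright")] - mel[(c, "dim")])
            * sbar
            for c in ("red", "blue")
        ]
    )
    cov_color = np.mean(
        [
            params.placeholder_scale_rc
            * params.attention_weight_rc
            * params.rc_gain
            * (rc[("blue", b)] - rc[("red", b)])
            * hbar
            + params.placeholder_scale_ip
            * params.attention_weight_ip
            * params.ip_gain
            * (mel[("blue", b)] - mel[("red", b)])
            * sbar
            for b in ("dim", "bright")
        ]
    )
    return {
        "direct_brightness_mm": float(d_bright),
        "direct_color_mm": float(d_color),
        "covert_brightness_mm": float(cov_bright),
        "covert_color_mm": float(cov_color),
        "rc_window_mean": hbar,
        "ip_window_mean": sbar,
    }
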