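"""Basic trace and calibration figures (matplotlib)."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .calibrate import IntensityResponseCurve
from .trace import TrialRecord


def plot_traces(records: Sequence[TrialRecord], by: str = "color", ax=None):
    """Condition-mean pupil traces (requires equal-length traces)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    groups: dict[str, list[np.ndarray]] = {}
    t = None
    for rec in records:
        key = str(getattr(rec, by))
        groups.setdefault(key, []).append(rec.trace.pupil)
        t = rec.trace.t - rec.stream_onset_s
    for key in sorted(groups):
        mean = np.mean(groups[key], axis=0)
        color = key if key in ("red", "blue") else None
        ax.plot(t, mean, label=f"{by}={key}", color=color)
    ax.set_xlabel("time from stream onset (s)")
    ax.set_ylabel(f"pupil ({records[0].trace.unit})")
    ax.legend(frameon=False)
    return ax


def plot_intensity_curves(
    curve_red: IntensityResponseCurve, curve_blue: IntensityResponseCurve, ax=None
):
    """Fitted intensity-response curves with their support points."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    grid = np.linspace(0, 100, 201)
    for curve in (curve_red, curve_blue):
        ax.plot(grid, curve.predict(grid), color=curve.color, label=f"{curve.color} (r2={curve.r_squared:.2f})")
        if curve.support is not None:
            ax.scatter(curve.support["intensity_pct"], curve.support["strength"], color=curve.color, s=12)
    ax.set_xlabel("intensity (% of maximum)")
    ax.set_ylabel("constriction strength (mm)")
    ax.legend(frameon=False)
    return ax
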