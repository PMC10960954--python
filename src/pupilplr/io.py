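"""Tidy on-disk formats: long sample tables and trial tables, as CSV.

One sample row per (participant, trial, sample); one trial row per trial.
Round trips are lossless for finite values.  The sample table is the format
the preprocessing pipeline consumes; trial tables carry design metadata and
behaviour.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .params import BRIGHTNESS_LEVELS, COLORS, PHASES
from .trace import PupilTrace, TrialRecord

SAMPLE_COLUMNS = [
    "participant_id",
    "trial_id",
    "phase",
    "t_s",
    "pupil",
    "unit",
    "gaze_x_deg",
    "gaze_y_deg",
    "valid",
]

TRIAL_COLUMNS = [
    "participant_id",
    "trial_id",
    "phase",
    "attended_color",
    "attended_brightness",
    "ignored_color",
    "ignored_brightness",
    "cue_side",
    "n_targets",
    "reported_targets",
    "correct",
]

# optional extras preserved on round trip when present
TRIAL_EXTRA_COLUMNS = [
    "color",
    "brightness",
    "intensity_pct",
    "stream_onset_s",
    "stream_duration_s",
    "planted_fixation_break",
    "planted_baseline_outlier",
]

_ENUMS = {
    "phase": set(PHASES),
    "attended_color": set(COLORS),
    "ignored_color": set(COLORS),
    "color": set(COLORS),
    "attended_brightness": set(BRIGHTNESS_LEVELS),
    "ignored_brightness": set(BRIGHTNESS_LEVELS),
    "brightness": set(BRIGHTNESS_LEVELS),
    "cue_side": {"left", "right"},
}


class FormatError(ValueError):
    """A table does not conform to the tidy format contract."""


def samples_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    chunks = []
    for rec in records:
        tr = rec.trace
        if tr is None:
            raise FormatError(f"trial {rec.key} has no trace")
        chunks.append(
            pd.DataFrame(
                {
                    "participant_id": rec.participant_id,
                    "trial_id": rec.trial_id,
                    "phase": rec.phase,
                    "t_s": tr.t,
                    "pupil": tr.pupil,
                    "unit": tr.unit,
                    "gaze_x_deg": tr.gaze_x,
                    "gaze_y_deg": tr.gaze_y,
                    "valid": tr.valid.astype(int),
                }
            )
        )
    if not chunks:
        return pd.DataFrame(columns=SAMPLE_COLUMNS)
    return pd.concat(chunks, ignore_index=True)


def trials_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {col: getattr(rec, col) for col in TRIAL_COLUMNS if col != "correct"}
        row["correct"] = None if rec.correct is None else int(rec.correct)
        for col in TRIAL_EXTRA_COLUMNS:
            value = getattr(rec, col)
            row[col] = int(value) if isinstance(value, bool) else value
        rows.append(row)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS + TRIAL_EXTRA_COLUMNS)


def write_samples(path: str | Path, records: Sequence[TrialRecord]) -> None:
    samples_frame(records).to_csv(path, index=False, float_format="%.10g")


def write_trials(path: str | Path, records: Sequence[TrialRecord]) -> None:
    trials_frame(records).to_csv(path, index=False, float_format="%.10g")


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def _check_enums(df: pd.DataFrame, path) -> None:
    for col, allowed in _ENUMS.items():
        if col not in df.columns:
            continue
        values = df[col].dropna()
        bad = set(values.unique()) - allowed
        if bad:
            raise FormatError(
                f"{path}: column {col!r} contains unknown value(s) {sorted(map(str, bad))!r}; "
                f"expected one of {sorted(allowed)}"
            )


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy sample table; returns the DataFrame."""
    df = pd.read_csv(path)
    if df.empty and not df.columns.size:
        return pd.DataFrame(columns=SAMPLE_COLUMNS)
    _require_columns(df, SAMPLE_COLUMNS, path)
    _check_enums(df, path)
    for (pid, tid), grp in df.groupby(["participant_id", "trial_id"], sort=False):
        t = grp["t_s"].to_numpy(float)
        if t.size >= 2:
            dt = np.diff(t)
            if dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise FormatError(
                    f"{path}: non-uniform time grid in trial ({pid}, {tid})"
                )
    return df


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty and not df.columns.size:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    _require_columns(df, TRIAL_COLUMNS, path)
    _check_enums(df, path)
    return df


def records_from_frames(samples: pd.DataFrame, trials: pd.DataFrame) -> list[TrialRecord]:
    """Reassemble TrialRecords from a (samples, trials) table pair."""
    by_key = {}
    for (pid, tid), grp in samples.groupby(["participant_id", "trial_id"], sort=False):
        t = grp["t_s"].to_numpy(float)
        rate = 1.0 / float(np.diff(t)[0]) if t.size >= 2 else 1.0
        unit = str(grp["unit"].iloc[0])
        by_key[(int(pid), int(tid))] = PupilTrace(
            t=t,
            pupil=grp["pupil"].to_numpy(float),
            gaze_x=grp["gaze_x_deg"].to_numpy(float),
            gaze_y=grp["gaze_y_deg"].to_numpy(float),
            valid=grp["valid"].to_numpy().astype(bool),
            sample_rate_hz=round(rate, 6),
            unit=unit,
        )
    records = []
    for _, row in trials.iterrows():
        key = (int(row["participant_id"]), int(row["trial_id"]))
        kwargs = {}
        for col in TRIAL_COLUMNS + TRIAL_EXTRA_COLUMNS:
            if col not in trials.columns:
                continue
            value = row[col]
            if pd.isna(value):
                value = None
            kwargs[col] = value
        for col in ("n_targets", "reported_targets"):
            if kwargs.get(col) is not None:
                kwargs[col] = int(kwargs[col])
        for col in ("correct", "planted_fixation_break", "planted_baseline_outlier"):
            if kwargs.get(col) is not None:
                kwargs[col] = bool(int(kwargs[col]))
        for col in ("participant_id", "trial_id"):
            kwargs[col] = int(kwargs[col])
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        records.append(TrialRecord(trace=by_key.get(key), **kwargs))
    return records


def read_records(samples_path: str | Path, trials_path: str | Path) -> list[TrialRecord]:
    return records_from_frames(read_samples(samples_path), read_trials(trials_path))
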