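"""Mixed-effects analyses of pupil time series.

Three model objects, statsmodels-style (construct from data, ``fit()``
returns a results object with ``summary()``):

* :class:`WindowLME` — linear mixed model on per-trial window-mean pupil
  size with one two-level fixed factor and by-participant random intercepts
  and slopes.
* :class:`CrossValTimeSeriesTest` — the cross-validated localize-then-test
  procedure: folds stratified by participant; for each fold the sample with
  the strongest effect (largest |z| of the factor's coefficient) is located
  on the training folds; held-out trials contribute their pupil value at
  their fold's localized sample to a single pooled mixed model.
* :class:`AccuracyGLME` — binomial mixed model (logit link, variational
  approximation) for behavioural accuracy with colour, brightness and their
  interaction.

Sign convention: pupil coefficients are reported as positive constriction
effects (the raw coefficient of bright-vs-dim or blue-vs-red on
baseline-corrected pupil size is negative when the pupil constricts more;
the report layer negates it, keeping |statistic| and p unchanged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .preprocess import downsample
from .trace import TrialRecord

logger = logging.getLogger(__name__)

__all__ = [
    "LmeResult",
    "TstResult",
    "select_same_color",
    "select_same_brightness",
    "window_mean_table",
    "stream_sample_matrix",
    "WindowLME",
    "window_lme",
    "CrossValTimeSeriesTest",
    "cv_tst",
    "AccuracyGLME",
    "accuracy_glme",
    "CompleteSeparationError",
]

_DEFAULT_REFERENCE = {"brightness": "dim", "color": "red"}
_FACTOR_LEVELS = {"brightness": ("dim", "bright"), "color": ("red", "blue")}


class CompleteSeparationError(ValueError):
    """The accuracy outcome is degenerate (e.g. all trials correct)."""


@dataclass
class LmeResult:
    """One fixed-effect contrast from a mixed model."""

    b: float  # reported effect (constriction-positive for pupil dvs)
    se: float
    stat: float  # t or z, = b / se
    p: float
    n_obs: int
    formula: str
    window: tuple | None = None
    contrast: str = ""
    statistic_label: str = "t"
    coef_raw: float = 0.0
    re_structure: str = "full"
    converged: bool = True

    def summary(self) -> str:
        win = f", window={self.window}" if self.window is not None else ""
        return (
            f"{self.contrast}: b = {self.b:.3f}, SE = {self.se:.3f}, "
            f"{self.statistic_label} = {self.stat:.2f}, P = {self.p:.3g} "
            f"(n = {self.n_obs}, re = {self.re_structure}{win})"
        )

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "b": self.b,
            "se": self.se,
            "statistic": self.stat,
            "statistic_label": self.statistic_label,
            "p": self.p,
            "n_obs": self.n_obs,
            "re_structure": self.re_structure,
            "window": list(self.window) if self.window is not None else None,
        }


@dataclass
class TstResult:
    """Pooled localize-then-test outcome."""

    fold_count: int
    localized_samples: list  # one sample index per fold
    localized_times_s: list  # same, in seconds from stream onset
    z: float
    p: float
    b: float
    se: float
    n_obs: int
    window: tuple
    contrast: str = ""
    scan_stats: list = field(default_factory=list, repr=False)

    def summary(self) -> str:
        samples = ", ".join(str(s) for s in self.localized_samples)
        return (
            f"{self.contrast}: z = {self.z:.2f}, P = {self.p:.3g} "
            f"(tested at samples {samples}; "
            f"{', '.join(f'{t:.1f} s' for t in self.localized_times_s)}; n = {self.n_obs})"
        )

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "z": self.z,
            "p": self.p,
            "b": self.b,
            "se": self.se,
            "fold_count": self.fold_count,
            "localized_samples": [int(s) for s in self.localized_samples],
            "localized_times_s": [float(t) for t in self.localized_times_s],
            "n_obs": self.n_obs,
            "window": list(self.window),
        }


# ---------------------------------------------------------------------------
# trial selection and recoding


def select_same_color(trials: pd.DataFrame) -> pd.DataFrame:
    """Keep trials whose attended and ignored placeholders share a colour;
    recode brightness across colours (dim red and dim blue are both 'dim')."""
    out = trials[trials["attended_color"] == trials["ignored_color"]].copy()
    out["brightness"] = out["attended_brightness"]
    return out


def select_same_brightness(trials: pd.DataFrame) -> pd.DataFrame:
    """Keep trials whose attended and ignored placeholders share a
    brightness level; recode colour across brightness."""
    out = trials[trials["attended_brightness"] == trials["ignored_brightness"]].copy()
    out["color"] = out["attended_color"]
    return out


# ---------------------------------------------------------------------------
# record -> table bridges


def _meta_row(rec: TrialRecord) -> dict:
    return {
        "participant_id": rec.participant_id,
        "trial_id": rec.trial_id,
        "phase": rec.phase,
        "color": rec.color,
        "brightness": rec.brightness,
        "attended_color": rec.attended_color,
        "attended_brightness": rec.attended_brightness,
        "ignored_color": rec.ignored_color,
        "ignored_brightness": rec.ignored_brightness,
        "correct": rec.correct,
        "baseline": rec.baseline,
    }


def window_mean_table(
    records: Sequence[TrialRecord], window_s: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Per-trial mean pupil size over a window relative to stream onset
    (default: the full stimulus interval), plus trial metadata."""
    rows = []
    for rec in records:
        if window_s is None:
            w = (0.0, rec.stream_duration_s or float(rec.trace.t[-1]))
        else:
            w = window_s
        sl = rec.trace.window_slice(rec.stream_onset_s + w[0], rec.stream_onset_s + w[1])
        row = _meta_row(rec)
        row["pupil_mm"] = float(rec.trace.pupil[sl].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def stream_sample_matrix(
    records: Sequence[TrialRecord],
    extra_downsample: int = 10,
    window_s: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Sample-level matrix for the time-series test.

    Each trace is further block-mean downsampled by ``extra_downsample``
    and restricted to ``window_s`` (seconds relative to stream onset;
    default the full stimulus interval).  Returns (meta, matrix, times)
    with ``matrix[i, j]`` the pupil of trial i at sample j and ``times``
    in seconds from stream onset.
    """
    metas, series = [], []
    times = None
    for rec in records:
        tr = downsample(rec.trace, extra_downsample) if extra_downsample > 1 else rec.trace
        if window_s is None:
            w = (0.0, rec.stream_duration_s or float(tr.t[-1]))
        else:
            w = window_s
        sl = tr.window_slice(rec.stream_onset_s + w[0], rec.stream_onset_s + w[1])
        t_rel = tr.t[sl] - rec.stream_onset_s
        if times is None:
            times = t_rel
        elif t_rel.size != times.size:
            raise ValueError("trials have unequal sample grids; cannot build a matrix")
        metas.append(_meta_row(rec))
        series.append(tr.pupil[sl])
    if times is None:
        raise ValueError("no records supplied")
    return pd.DataFrame(metas), np.vstack(series), times


# ---------------------------------------------------------------------------
# window LME


def _encode_factor(data: pd.DataFrame, factor: str, reference: str | None) -> tuple[pd.Series, str]:
    levels = [str(x) for x in pd.unique(data[factor].dropna())]
    if len(levels) != 2:
        raise ValueError(f"factor {factor!r} must have exactly 2 levels, got {levels}")
    if reference is None:
        reference = _DEFAULT_REFERENCE.get(factor, sorted(levels)[0])
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not among {levels}")
    other = next(l for l in levels if l != reference)
    return (data[factor].astype(str) == other).astype(float), other


class WindowLME:
    """Linear mixed model for a two-level factor on a per-trial dv.

    by-participant random intercepts and random slopes for the factor;
    restricted-maximum-likelihood fitting.  On a singular or non-converged
    fit the random-effects structure is relaxed (uncorrelated intercept +
    slope, then intercept only), logged.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        factor: str,
        dv: str = "pupil_mm",
        group: str = "participant_id",
        reference: str | None = None,
        negate: bool = True,
    ) -> None:
        if data[group].nunique() < 2:
            raise ValueError("window LME requires at least two participants")
        self.data = data.reset_index(drop=True).copy()
        self.factor, self.dv, self.group = factor, dv, group
        self.negate = negate
        self.data["_x"], self.tested_level = _encode_factor(self.data, factor, reference)
        self.reference = reference or _DEFAULT_REFERENCE.get(factor, "")

    def _fit_structure(self, structure: str, reml: bool):
        kwargs = {"groups": self.data[self.group]}
        if structure == "full":
            kwargs["re_formula"] = "~_x"
        elif structure == "uncorrelated":
            kwargs["re_formula"] = "~1"
            kwargs["vc_formula"] = {"slope": "0 + _x"}
        elif structure == "intercept":
            kwargs["re_formula"] = "~1"
        else:
            raise ValueError(structure)
        model = smf.mixedlm(f"{self.dv} ~ _x", self.data, **kwargs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(reml=reml, method=["lbfgs", "bfgs"])
        return result

    def fit(self, reml: bool = True, re_structure: str = "full") -> LmeResult:
        order = {"full": ["full", "uncorrelated", "intercept"],
                 "uncorrelated": ["uncorrelated", "intercept"],
                 "intercept": ["intercept"]}[re_structure]
        result, used = None, order[-1]
        for structure in order:
            try:
                candidate = self._fit_structure(structure, reml)
            except (np.linalg.LinAlgError, ValueError) as exc:
                logger.info("window LME %s structure failed (%s); relaxing", structure, exc)
                continue
            if candidate.converged and np.isfinite(candidate.bse["_x"]):
                result, used = candidate, structure
                break
            logger.info("window LME %s structure singular/non-converged; relaxing", structure)
        if result is None:
            # last resort: the intercept-only fit regardless of convergence,
            # or (if even that is numerically singular) the degenerate
            # zero-variance mixed model, i.e. OLS
            try:
                result = self._fit_structure("intercept", reml)
                used = "intercept"
            except (np.linalg.LinAlgError, ValueError):
                logger.info("mixed-model fits singular; falling back to OLS")
                result = smf.ols(f"{self.dv} ~ _x", self.data).fit()
                used = "ols"
        coef = float(result.params["_x"])
        se = float(result.bse["_x"])
        stat = coef / se
        p = float(2.0 * sps.norm.sf(abs(stat)))
        sign = -1.0 if self.negate else 1.0
        return LmeResult(
            b=sign * coef,
            se=se,
            stat=sign * stat,
            p=p,
            n_obs=len(self.data),
            formula=f"{self.dv} ~ {self.factor} + (1 + {self.factor} | {self.group})",
            contrast=f"{self.factor} ({self.tested_level} vs {self.reference})",
            coef_raw=coef,
            re_structure=used,
            converged=bool(getattr(result, "converged", True)),
        )


def window_lme(
    trials: pd.DataFrame,
    factor: str,
    dv: str = "pupil_mm",
    window: tuple | None = None,
    **kwargs,
) -> LmeResult:
    """Functional wrapper around :class:`WindowLME`."""
    res = WindowLME(trials, factor, dv=dv, **kwargs).fit()
    res.window = window
    return res


# ---------------------------------------------------------------------------
# cross-validated localize-then-test


def _fold_assignment(
    meta: pd.DataFrame, group: str, folds: int, seed: int
) -> np.ndarray:
    """Per-participant round-robin fold ids after a seeded shuffle."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    fold_of = np.empty(len(meta), dtype=int)
    for pid, idx in meta.groupby(group, sort=True).indices.items():
        idx = np.asarray(idx)
        if idx.size < folds:
            logger.warning(
                "participant %s has %d trials < %d folds; some folds miss this participant",
                pid, idx.size, folds,
            )
        perm = rng.permutation(idx.size)
        fold_of[idx[perm]] = np.arange(idx.size) % folds
    return fold_of


class CrossValTimeSeriesTest:
    """Cross-validated localize-then-test for a two-level factor.

    ``meta`` carries one row per trial (with the factor and participant
    columns), ``samples`` the trial x sample pupil matrix, ``times`` the
    sample times in seconds from stream onset.
    """

    def __init__(
        self,
        meta: pd.DataFrame,
        samples: np.ndarray,
        times: np.ndarray,
        factor: str,
        group: str = "participant_id",
        reference: str | None = None,
        negate: bool = True,
    ) -> None:
        samples = np.asarray(samples, dtype=float)
        if samples.ndim != 2 or samples.shape[0] != len(meta):
            raise ValueError("samples must be a (n_trials, n_samples) matrix aligned with meta")
        if samples.shape[1] < 2:
            raise ValueError("the tested window must contain at least 2 samples")
        self.meta = meta.reset_index(drop=True).copy()
        self.samples = samples
        self.times = np.asarray(times, dtype=float)
        self.factor, self.group, self.negate = factor, group, negate
        self.meta["_x"], self.tested_level = _encode_factor(self.meta, factor, reference)
        self.reference = reference or _DEFAULT_REFERENCE.get(factor, "")

    def _scan_stat(self, df: pd.DataFrame, structure: str) -> float:
        model = WindowLME(df, self.factor, dv="_dv", group=self.group, negate=False)
        res = model.fit(reml=True, re_structure=structure)
        return res.stat

    def fit(
        self,
        folds: int = 4,
        seed: int = 0,
        scan_re: str = "intercept",
        pooled_re: str = "full",
    ) -> TstResult:
        if folds < 2:
            raise ValueError("fold_count must be >= 2")
        meta = self.meta
        fold_of = _fold_assignment(meta, self.group, folds, seed)
        localized: list[int] = []
        scan_stats = []
        for k in range(folds):
            train = fold_of != k
            df = meta.loc[train, [self.group, self.factor, "_x"]].copy()
            stats_k = np.empty(self.samples.shape[1])
            for j in range(self.samples.shape[1]):
                df["_dv"] = self.samples[train, j]
                stats_k[j] = self._scan_stat(df, scan_re)
            best = int(np.argmax(np.abs(stats_k)))  # ties -> earliest sample
            localized.append(best)
            scan_stats.append(stats_k)
        pooled_dv = np.array(
            [self.samples[i, localized[fold_of[i]]] for i in range(len(meta))]
        )
        pooled = meta[[self.group, self.factor, "_x"]].copy()
        pooled["_dv"] = pooled_dv
        res = WindowLME(
            pooled, self.factor, dv="_dv", group=self.group, negate=self.negate
        ).fit(reml=True, re_structure=pooled_re)
        return TstResult(
            fold_count=folds,
            localized_samples=localized,
            localized_times_s=[float(self.times[s]) for s in localized],
            z=res.stat,
            p=res.p,
            b=res.b,
            se=res.se,
            n_obs=len(meta),
            window=(float(self.times[0]), float(self.times[-1])),
            contrast=f"{self.factor} ({self.tested_level} vs {self.reference})",
            scan_stats=scan_stats,
        )


def cv_tst(
    meta: pd.DataFrame,
    samples: np.ndarray,
    times: np.ndarray,
    factor: str,
    folds: int = 4,
    seed: int = 0,
    **kwargs,
) -> TstResult:
    """Functional wrapper around :class:`CrossValTimeSeriesTest`."""
    return CrossValTimeSeriesTest(meta, samples, times, factor, **kwargs).fit(
        folds=folds, seed=seed
    )


# ---------------------------------------------------------------------------
# behavioural accuracy


class AccuracyGLME:
    """Binomial mixed model for per-trial correctness.

    Fixed effects: colour, brightness (of the covertly attended stream) and
    their interaction; by-participant random intercepts and slopes per
    fixed effect.  Fitted by statsmodels' variational Bayes approximation
    to the binomial GLMM; coefficients are posterior means on the log-odds
    scale with z = mean / sd.
    """

    def __init__(self, trials: pd.DataFrame, factors: Sequence[str] = ("color", "brightness")):
        df = trials.copy()
        for f in ("color", "brightness"):
            absent = f not in df.columns or df[f].isna().all()
            if absent and f"attended_{f}" in df.columns:
                df[f] = df[f"attended_{f}"]
        df["correct"] = df["correct"].astype(float)
        if df["correct"].nunique() < 2:
            raise CompleteSeparationError(
                "accuracy is constant across all trials; the binomial model is not identified"
            )
        self.factors = [f for f in factors if df[f].nunique() > 1]
        for f in factors:
            if f not in self.factors:
                logger.info("accuracy GLME: dropping single-level factor %r", f)
        self.codes = {}
        for f in self.factors:
            df[f"_{f}"], self.codes[f] = _encode_factor(df, f, _DEFAULT_REFERENCE.get(f))
        self.data = df.reset_index(drop=True)

    def fit(self) -> dict[str, LmeResult]:
        terms = [f"_{f}" for f in self.factors]
        if len(terms) == 2:
            fixed = f"{terms[0]} * {terms[1]}"
            labels = {
                terms[0]: "color",
                terms[1]: "brightness",
                f"{terms[0]}:{terms[1]}": "interaction",
            }
        else:
            fixed = terms[0]
            labels = {terms[0]: self.factors[0]}
        vc = {"participant": "0 + C(participant_id)"}
        for i, term in enumerate(terms):
            vc[f"slope{i}"] = f"0 + C(participant_id):{term}"
        formula = f"correct ~ {fixed}"
        model = sm.BinomialBayesMixedGLM.from_formula(formula, vc, self.data)
        with warnings.catch_warnings():
            # Laplace (MAP) fit: its posterior sds track the likelihood-based
            # standard errors, unlike the mean-field variational fit which
            # underestimates them substantially.  The optimizer draws its
            # starting point from the global RNG; pin it for determinism.
            warnings.simplefilter("ignore")
            state = np.random.get_state()
            np.random.seed(0)
            try:
                fit = model.fit_map()
            finally:
                np.random.set_state(state)
        results = {}
        names = list(fit.model.exog_names)
        for term, label in labels.items():
            # patsy names interactions "a:b"
            idx = names.index(term) if term in names else names.index(":".join(sorted(term.split(":"))))
            b = float(fit.fe_mean[idx])
            se = float(fit.fe_sd[idx])
            z = b / se
            results[label] = LmeResult(
                b=b,
                se=se,
                stat=z,
                p=float(2.0 * sps.norm.sf(abs(z))),
                n_obs=len(self.data),
                formula=formula,
                contrast=f"accuracy ~ {label}",
                statistic_label="z",
                coef_raw=b,
                re_structure="map",
            )
        return results


def accuracy_glme(trials: pd.DataFrame, **kwargs) -> dict[str, LmeResult]:
    """Functional wrapper around :class:`AccuracyGLME`."""
    return AccuracyGLME(trials, **kwargs).fit()
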