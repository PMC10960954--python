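"""End-to-end study orchestration: simulate -> preprocess -> calibrate ->
validate -> analyse, with on-disk JSON/markdown reports.

Two presets mirror the two study designs: ``primary`` (fully crossed 4x4
placeholder grid, 224 main trials, four headline contrasts + accuracy
model) and ``followup`` (bright-only 2x2 grid, 200 trials, colour contrast
restricted to the preregistered last-3-s window).  Every artifact embeds
the configuration hash and seed; identical (config, seed) pairs produce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import calibrate as cal
from . import simulate as sim
from . import stats as st
from .params import PlrParams, StudyDesign
from .preprocess import preprocess_trials

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyResult", "run_study", "PRESETS"]


@dataclass
class StudyConfig:
    """All knobs of one end-to-end study run.

    The preprocessing and exclusion constants default to the pipeline's
    canonical values (x10 downsampling twice, 50 ms baseline window,
    6.93 deg / 10 ms gaze criterion, +-2 z baseline criterion, 4 folds,
    last-3-s exploratory window).
    """

    preset: str = "primary"
    seed: int = 1
    n_participants: int = 30
    sample_rate_hz: float = 1000.0
    params: PlrParams = None
    # preprocessing
    downsample_factor: int = 10
    extra_downsample: int = 10
    baseline_window_s: tuple = (0.0, 0.05)
    blink_margin_s: float = 0.05
    max_gaze_dev_deg: float = 6.93
    min_gaze_dur_ms: float = 10.0
    baseline_z_crit: float = 2.0
    # calibration / eligibility
    dim_blue_pct: float = 50.0
    calibration_r2_min: float = 0.7
    validation_window_s: float = 5.0
    validation_margin_mm: float = 0.05
    min_eligible: int = 2
    # analysis
    folds: int = 4
    exploratory_window_s: tuple = (12.0, 15.0)
    use_fitted_calibration: bool = True
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; expected one of {sorted(PRESETS)}")
        if self.params is None:
            self.params = PlrParams(seed=self.seed)
        elif isinstance(self.params, dict):
            self.params = PlrParams(**self.params)
        self.baseline_window_s = tuple(self.baseline_window_s)
        self.exploratory_window_s = tuple(self.exploratory_window_s)

    @property
    def variant(self) -> str:
        return self.preset

    def design(self, phase: str) -> StudyDesign:
        return StudyDesign(
            phase=phase,
            variant=self.variant,
            n_participants=self.n_participants,
            sample_rate_hz=self.sample_rate_hz,
        )

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["params"] = dataclasses.asdict(self.params)
        out["params"]["blink_dur_range_s"] = list(self.params.blink_dur_range_s)
        out["baseline_window_s"] = list(self.baseline_window_s)
        out["exploratory_window_s"] = list(self.exploratory_window_s)
        return out

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        raw = dict(raw)
        if "params" in raw and isinstance(raw["params"], dict):
            p = dict(raw["params"])
            if "blink_dur_range_s" in p:
                p["blink_dur_range_s"] = tuple(p["blink_dur_range_s"])
            raw["params"] = PlrParams(**p)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


PRESETS = {"primary", "followup"}


@dataclass
class StudyResult:
    config_hash: str
    seed: int
    preset: str
    n_participants: int
    n_eligible: int
    calibration: dict  # participant -> CalibrationOutcome dict
    exclusion: dict
    contrasts: dict  # name -> result dict
    accuracy: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def report_markdown(self) -> str:
        lines = [
            f"# Study report ({self.preset} preset)",
            "",
            f"- config hash: `{self.config_hash}`, seed: {self.seed}",
            f"- participants simulated: {self.n_participants}, eligible: {self.n_eligible}",
            "",
            "## Trial exclusion",
            "",
        ]
        exc = self.exclusion
        if exc.get("n_input"):
            pct = 100.0 * (exc["n_input"] - exc["n_retained"]) / exc["n_input"]
            lines += [
                f"- {exc['n_gaze_excluded']} trials excluded for gaze deviation, "
                f"{exc['n_baseline_excluded']} for baseline outliers; "
                f"in total {exc['n_input'] - exc['n_retained']} of {exc['n_input']} trials "
                f"({pct:.2f}%) were excluded.",
                "",
            ]
        lines += ["## Contrasts", ""]
        for name, res in self.contrasts.items():
            if "z" in res:
                samples = ", ".join(str(s) for s in res["localized_samples"])
                lines.append(
                    f"- **{name}**: z = {res['z']:.2f}, P = {res['p']:.3g} "
                    f"(tested at samples {samples})"
                )
            else:
                lines.append(
                    f"- **{name}**: b = {res['b']:.2f}, SE = {res['se']:.2f}, "
                    f"{res['statistic_label']} = {res['statistic']:.2f}, P = {res['p']:.3g}"
                )
        if self.accuracy:
            lines += ["", "## Accuracy model", ""]
            for label, res in self.accuracy.items():
                lines.append(
                    f"- {label}: b = {res['b']:.2f}, SE = {res['se']:.2f}, "
                    f"z = {res['statistic']:.2f}, P = {res['p']:.3g}"
                )
        return "\n".join(lines) + "\n"


def _preprocess_kwargs(config: StudyConfig) -> dict:
    return dict(
        downsample_factor=config.downsample_factor,
        au_slope=config.params.au_slope,
        au_intercept=config.params.au_intercept,
        baseline_window_s=config.baseline_window_s,
        blink_margin_s=config.blink_margin_s,
        max_gaze_dev_deg=config.max_gaze_dev_deg,
        min_gaze_dur_ms=config.min_gaze_dur_ms,
        baseline_z_crit=config.baseline_z_crit,
    )


def run_study(config: StudyConfig) -> StudyResult:
    """Execute one full study from a configuration; deterministic in
    (config, seed)."""
    params = config.params.replace(seed=config.seed)
    pp = _preprocess_kwargs(config)
    followup = config.preset == "followup"

    calibration_outcomes: dict[int, cal.CalibrationOutcome] = {}
    eligible_ids: list[int] = []
    val_records_all, main_records_all = [], []

    cal_design = config.design("calibration")
    val_design = config.design("validation")
    main_design = config.design("main")

    for pid in range(config.n_participants):
        cal_records = sim.simulate_calibration_session(params, cal_design, pid)
        cal_proc, _ = preprocess_trials(cal_records, apply_exclusions=False, **pp)
        outcome, _ = cal.calibrate_participant(
            cal_proc, dim_blue=config.dim_blue_pct, r2_min=config.calibration_r2_min
        )
        calibration_outcomes[pid] = outcome
        if not outcome.eligible:
            logger.info("participant %d ineligible after calibration: %s", pid, outcome.reasons)
            continue
        lookup = outcome if config.use_fitted_calibration else None
        val_records = sim.simulate_validation_session(params, val_design, lookup, pid)
        val_proc, _ = preprocess_trials(val_records, apply_exclusions=False, **pp)
        ok, diag = cal.validation_eligibility(
            val_proc,
            window_s=config.validation_window_s,
            margin_mm=config.validation_margin_mm,
            rule="followup" if followup else "primary",
        )
        outcome.diagnostics.update(diag)
        if not ok:
            outcome.eligible = False
            outcome.reasons.append("validation eligibility criterion failed")
            logger.info("participant %d ineligible after validation", pid)
            continue
        eligible_ids.append(pid)
        val_records_all.extend(val_proc)
        main_records_all.extend(sim.simulate_main_session(params, main_design, lookup, pid))

    if len(eligible_ids) < config.min_eligible:
        raise RuntimeError(
            f"only {len(eligible_ids)} eligible synthetic participant(s); "
            f"minimum cohort is {config.min_eligible}. Calibration diagnostics: "
            + "; ".join(
                f"p{pid}: {out.reasons}" for pid, out in calibration_outcomes.items() if not out.eligible
            )
        )

    main_proc, report = preprocess_trials(main_records_all, **pp)

    contrasts: dict[str, dict] = {}
    # validation (direct gaze) window LMEs over the full stimulus interval
    val_table = st.window_mean_table(val_records_all)
    if not followup:
        res = st.window_lme(val_table, "brightness", window=(0.0, 15.0))
        contrasts["direct_brightness"] = res.to_dict()
    res = st.window_lme(val_table, "color", window=(0.0, 15.0))
    contrasts["direct_color"] = res.to_dict()

    # covert-attention contrasts via the cross-validated time-series test
    main_table = st.window_mean_table(main_proc)  # carries meta incl. behaviour
    if not followup:
        meta, mat, times = st.stream_sample_matrix(
            [r for r in main_proc if r.attended_color == r.ignored_color],
            extra_downsample=config.extra_downsample,
        )
        meta["brightness"] = meta["attended_brightness"]
        tst = st.cv_tst(meta, mat, times, "brightness", folds=config.folds, seed=config.seed)
        contrasts["covert_brightness"] = tst.to_dict()

        same_bright_records = [
            r for r in main_proc if r.attended_brightness == r.ignored_brightness
        ]
        meta, mat, times = st.stream_sample_matrix(
            same_bright_records, extra_downsample=config.extra_downsample
        )
        meta["color"] = meta["attended_color"]
        tst = st.cv_tst(meta, mat, times, "color", folds=config.folds, seed=config.seed)
        contrasts["covert_color"] = tst.to_dict()

        # exploratory: colour within the bright condition, last-3-s window
        bright_records = [
            r for r in same_bright_records if r.attended_brightness == "bright"
        ]
        meta, mat, times = st.stream_sample_matrix(
            bright_records,
            extra_downsample=config.extra_downsample,
            window_s=config.exploratory_window_s,
        )
        meta["color"] = meta["attended_color"]
        tst = st.cv_tst(meta, mat, times, "color", folds=config.folds, seed=config.seed)
        contrasts["covert_color_bright_last3s"] = tst.to_dict()
    else:
        same_bright_records = [
            r for r in main_proc if r.attended_brightness == r.ignored_brightness
        ]
        meta, mat, times = st.stream_sample_matrix(
            same_bright_records,
            extra_downsample=config.extra_downsample,
            window_s=config.exploratory_window_s,
        )
        meta["color"] = meta["attended_color"]
        tst = st.cv_tst(meta, mat, times, "color", folds=config.folds, seed=config.seed)
        contrasts["covert_color_last3s"] = tst.to_dict()

    factors = ("color",) if followup else ("color", "brightness")
    try:
        acc = {k: v.to_dict() for k, v in st.accuracy_glme(main_table, factors=factors).items()}
    except st.CompleteSeparationError as exc:
        logger.warning("accuracy model degenerate: %s", exc)
        acc = {"error": {"message": str(exc)}}

    result = StudyResult(
        config_hash=config.config_hash(),
        seed=config.seed,
        preset=config.preset,
        n_participants=config.n_participants,
        n_eligible=len(eligible_ids),
        calibration={pid: out.as_dict() for pid, out in calibration_outcomes.items()},
        exclusion=report.to_dict(),
        contrasts=contrasts,
        accuracy=acc,
    )
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "results.json", "w") as fh:
            json.dump(result.to_dict(), fh, indent=2, sort_keys=True, default=float)
        with open(outdir / "report.md", "w") as fh:
            fh.write(result.report_markdown())
        config.to_yaml(outdir / "config.yaml")
    return result
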