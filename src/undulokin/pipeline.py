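"""End-to-end orchestration: trials in, analysis tables out.

A run takes either a synthetic cohort (generated from a seed-controlled
design) or a directory of digitized trial bundles, computes one kinematic
summary per trial, then the cross-speed statistics, the PCA, the per-speed
summary table, and a Strouhal-Reynolds table flagging trials inside the
propulsive-efficiency optimum St in [0.2, 0.4]. Artifacts are plain CSV
plus a JSON run-metadata sidecar and a structured text log. Runs are fully
deterministic under a fixed seed (timestamps appear only in the log).
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import group_stats, kinematics, synthetic, tracking_io
from .errors import UndulokinError
from .types import KinematicSummary

__all__ = ["RunConfig", "run_pipeline", "validate_inputs",
           "summaries_to_frame", "ST_OPTIMAL_RANGE"]

#: propulsive-efficiency optimum for the Strouhal number
ST_OPTIMAL_RANGE = (0.2, 0.4)

STATS_VARIABLES = ["tbf", "amplitude", "wave_speed", "wavelength", "k_max",
                   "k_max_loc", "fin_effort", "body_angle", "angle_of_attack"]


@dataclass
class RunConfig:
    """Everything a run needs; round-trips through YAML."""

    mode: str = "synthetic"            # "synthetic" | "files"
    out_dir: str = "results"
    seed: int = 0
    input_dir: str | None = None       # files mode
    calibration: float = 1.0           # metres per pixel (files mode)
    # synthetic-design overrides (None -> CohortDesign default)
    n_individuals: int | None = None
    speeds: list | None = None
    noise_sd: float | None = None
    fps: float | None = None
    n_cycles: float | None = None
    between_sd_scale: float = 1.0      # scales all between-individual SDs
    # kinematics tunables
    fit_region: tuple = (0.50, 0.95)
    smooth_window: int = 15
    smooth_order: int = 3
    # stats
    alpha: float = 0.05
    stats_variables: list = field(default_factory=lambda: list(STATS_VARIABLES))
    pca_variables: list = field(
        default_factory=lambda: list(group_stats.PCA_DEFAULT_VARIABLES))
    log_level: str = "info"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"mode: unknown input mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["fit_region"] = list(self.fit_region)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _design_from_config(config: RunConfig) -> synthetic.CohortDesign:
    kw: dict = {"seed": config.seed}
    if config.n_individuals is not None:
        kw["n_individuals"] = config.n_individuals
        kw["missing"] = ()                      # custom cohorts start complete
    if config.speeds is not None:
        kw["speeds"] = tuple(config.speeds)
        kw.setdefault("missing", ())
    for name in ("noise_sd", "fps", "n_cycles"):
        if getattr(config, name) is not None:
            kw[name] = getattr(config, name)
    design = synthetic.CohortDesign(**kw)
    if config.between_sd_scale != 1.0:
        design.between_sd = {k: v * config.between_sd_scale
                             for k, v in design.between_sd.items()}
    return design


def _load_trials(config: RunConfig, log: list[str]):
    if config.mode == "synthetic":
        design = _design_from_config(config)
        trials, truth = synthetic.generate_cohort(design)
        log.append(f"generated {len(trials)} synthetic trials "
                   f"(seed={design.seed})")
        return trials, truth
    if not config.input_dir:
        raise UndulokinError("files mode requires input_dir")
    trials = []
    for stem in tracking_io.list_bundles(config.input_dir):
        trials.append(tracking_io.read_trial_bundle(config.input_dir, stem))
    log.append(f"read {len(trials)} trial bundles from {config.input_dir}")
    if not trials:
        raise UndulokinError(f"no trial bundles found in {config.input_dir}")
    return trials, None


def summaries_to_frame(summaries: list[KinematicSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in summaries])


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run; returns the artifact dict and writes CSVs.

    Individual trial failures are logged and skipped; the run fails only if
    every trial fails.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"run started (mode={config.mode}, seed={config.seed})"]

    trials, truth = _load_trials(config, log)
    options = kinematics.KinematicsOptions(
        fit_region=tuple(config.fit_region),
        smooth_window=config.smooth_window, smooth_order=config.smooth_order)

    summaries, failures = [], []
    for seq, tracks, meta in trials:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tracking_io.merge_views(tracks, meta.body_length)
            summaries.append(kinematics.summarize_trial(seq, tracks, meta,
                                                        options=options))
        except Exception as err:   # noqa: BLE001 - record and continue
            failures.append((meta.trial_id, str(err)))
            log.append(f"trial {meta.trial_id} failed: {err}")
    if not summaries:
        raise UndulokinError("all trials failed; see log")
    log.append(f"summarized {len(summaries)} trials "
               f"({len(failures)} failures)")

    table = summaries_to_frame(summaries)
    table.to_csv(out / "trial_summaries.csv", index=False)
    if truth is not None:
        truth.to_csv(out / "ground_truth.csv", index=False)

    # cross-speed statistics
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        stats_vars = [v for v in config.stats_variables
                      if table[v].notna().sum() >= 3]
        report = group_stats.analyze_table(table, stats_vars,
                                           alpha=config.alpha)
        speed_summary = group_stats.summary_table(table, alpha=config.alpha)
        pca = group_stats.pca_contributions(
            table, variables=tuple(config.pca_variables))
    log.extend(f"warning: {w.message}" for w in caught)
    report.tests.to_csv(out / "stats_tests.csv", index=False)
    report.letters.to_csv(out / "stats_letters.csv", index=False)
    pd.concat([c.assign(variable=v) for v, c in report.contrasts.items()],
              ignore_index=True).to_csv(out / "stats_contrasts.csv", index=False)
    speed_summary.to_csv(out / "speed_summary.csv", index=False)

    pd.DataFrame(pca.scores,
                 columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])]
                 ).assign(trial=list(pca.row_index)) \
        .to_csv(out / "pca_scores.csv", index=False)
    pd.DataFrame(pca.loadings, index=pca.variables,
                 columns=[f"PC{i+1}" for i in range(pca.loadings.shape[1])]
                 ).to_csv(out / "pca_loadings.csv")
    pd.DataFrame(pca.contributions, index=pca.variables,
                 columns=[f"PC{i+1}" for i in range(pca.contributions.shape[1])]
                 ).to_csv(out / "pca_contributions.csv")
    pd.DataFrame({"axis": [f"PC{i+1}" for i in range(len(pca.percent_variance))],
                  "percent_variance": pca.percent_variance}) \
        .to_csv(out / "pca_variance.csv", index=False)

    lo, hi = ST_OPTIMAL_RANGE
    st_re = table[["trial_id", "speed_bl", "reynolds", "strouhal"]].copy()
    st_re["st_in_range"] = (st_re["strouhal"] >= lo) & (st_re["strouhal"] <= hi)
    st_re.to_csv(out / "st_re.csv", index=False)

    meta_out = {"config": dataclasses.asdict(config),
                "n_trials": len(summaries), "n_failures": len(failures),
                "failures": failures,
                "artifacts": sorted(p.name for p in out.glob("*.csv"))}
    (out / "run_meta.json").write_text(json.dumps(meta_out, indent=2,
                                                  default=str))
    log.append(f"run finished in {time.time() - t_start:.1f} s")
    (out / "pipeline.log").write_text("\n".join(log) + "\n")

    return {"summaries": table, "truth": truth, "report": report,
            "speed_summary": speed_summary, "pca": pca, "st_re": st_re,
            "failures": failures, "log": log}


def validate_inputs(config: RunConfig) -> list[dict]:
    """Report-only schema/units/frame-rate checks; never raises for
    individual bad files."""
    issues: list[dict] = []
    if config.mode == "synthetic":
        try:
            _design_from_config(config)
        except Exception as err:
            issues.append({"item": "design", "problem": str(err)})
        return issues
    d = Path(config.input_dir or ".")
    if not d.is_dir():
        return [{"item": str(d), "problem": "input_dir does not exist"}]
    stems = tracking_io.list_bundles(d)
    if not stems:
        issues.append({"item": str(d), "problem": "no trial bundles found"})
    for stem in stems:
        for suffix in ("midline", "lateral", "dorsal"):
            if not (d / f"{stem}_{suffix}.csv").exists():
                issues.append({"item": stem,
                               "problem": f"missing {suffix} file"})
        try:
            seq, tracks, meta = tracking_io.read_trial_bundle(d, stem)
        except Exception as err:
            issues.append({"item": stem, "problem": f"unreadable: {err}"})
            continue
        if seq.n_frames != tracks.n_frames:
            issues.append({"item": stem,
                           "problem": "midline/landmark frame counts differ"})
        arcs = tracking_io._smoothed_arc_lengths(seq.points)
        if np.any(np.abs(arcs - meta.body_length) > 0.10 * meta.body_length):
            issues.append({"item": stem,
                           "problem": "midline arc length departs >10% from BL"})
    return issues
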