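"""End-to-end orchestration of the two study designs.

``run_pipeline`` composes the stages: simulate cohort -> preprocess
(band-pass, edge trim, downsample) -> per-epoch curve lengths ->
group-level scaling-region onsets -> harmonized k_max -> tidy FD table
-> design-appropriate statistics -> (chronic design) subject-level
classification.  Every stage is a pure function of the config and its
seeds, so the run manifest (config hash + seeds + artifact paths) is
sufficient to reproduce any stage.

The acute design (subjects as their own controls across three drug
states) runs the one-way repeated-measures analysis only; the chronic
design (lesioned vs sham groups, baseline vs stimulation sessions) adds
the two-way mixed ANOVA and the SVM classification, which is where the
emulated study applied it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ParameterError, PipelineStageError
from .signal_io import preprocess, split_epochs
from .hfd_core import hfd_curve, fit_loglog
from .scaling_region import detect_onset, harmonize_kmax, group_mean_curve
from .synthetic_data import CohortConfig, simulate_cohort, simulate_acute_cohort
from .group_stats import (
    rm_anova_oneway,
    mixed_anova_twoway,
    fisher_lsd,
    assumption_checks,
)
from .classification import (
    build_features,
    loocv_classify,
    confusion,
    metrics,
    roc_auc,
    permutation_test,
)

__all__ = ["RunConfig", "run_pipeline", "fd_table_from_recordings"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    design: str = "chronic"  # "acute" or "chronic"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    low_hz: float = 0.5
    high_hz: float = 100.0
    skip_downsample: bool = False  # analyze at the acquisition rate
    edge_trim_s: float = 1.0
    k_eval_max: int = 100
    r2_threshold: float = 0.99
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    n_perm: int = 1000
    run_permutation: bool = True
    classifier_seed: int = 7
    n_acute_subjects: int = 6
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.design not in ("acute", "chronic"):
            raise ParameterError("design must be 'acute' or 'chronic'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outdir"] = str(self.outdir) if self.outdir else None
        return d


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def fd_table_from_recordings(
    recordings,
    config: RunConfig,
) -> tuple[pd.DataFrame, dict[str, int], int, dict]:
    """Preprocess, compute curve lengths, select k_max, and tabulate FD.

    Returns (tidy FD table, group onsets, harmonized k_max, curves by
    group).  The scaling-region onset is detected per experimental
    group on the geometric-mean curve of that group's epochs, then
    harmonized to the per-study upper bound.
    """
    target_fs = None if config.skip_downsample else config.cohort.fs_analysis
    epochs = []
    for rec in recordings:
        pre = preprocess(
            rec,
            low_hz=config.low_hz,
            high_hz=config.high_hz,
            target_fs=target_fs,
            edge_trim_s=config.edge_trim_s,
        )
        epochs.extend(split_epochs(pre))
    curves = [hfd_curve(ep.x, k_eval_max=config.k_eval_max) for ep in epochs]

    group_of = lambda ep: f"{'pd' if ep.condition.startswith('pd') else 'control'}" \
        f"/{'treated' if ep.condition.endswith('treated') else 'baseline'}"
    group_curves: dict[str, list] = {}
    for ep, cv in zip(epochs, curves):
        group_curves.setdefault(group_of(ep), []).append(cv)
    onsets = {
        g: detect_onset(
            group_mean_curve(cs),
            r2_threshold=config.r2_threshold,
            k_eval=config.k_eval_max,
        )
        for g, cs in group_curves.items()
    }
    k_max = harmonize_kmax(onsets)

    rows = []
    for ep, cv in zip(epochs, curves):
        est = fit_loglog(cv, k_max)
        rows.append(
            {
                "subject_id": ep.subject_id,
                "group": "pd" if ep.condition.startswith("pd") else "control",
                "condition": ep.condition,
                "treatment": "treated" if ep.condition.endswith("treated") else "baseline",
                "channel": ep.channel_id,
                "k_max": k_max,
                "fd": est.fd,
                "r2": est.r2,
            }
        )
    table = pd.DataFrame(rows)
    onset_ints = {g: r.k_onset for g, r in onsets.items()}
    return table, onset_ints, k_max, group_curves


def _subject_means(fd_table: pd.DataFrame) -> pd.DataFrame:
    """Channel-averaged FD per subject x condition (ANOVA unit).

    Channels are repeated measurements of the same cortical state;
    averaging them yields one value per animal per session, consistent
    with subject-level degrees of freedom.
    """
    return (
        fd_table.groupby(["subject_id", "group", "condition", "treatment"])["fd"]
        .mean()
        .reset_index()
        .rename(columns={"fd": "value"})
    )


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run one design end-to-end; returns (and optionally writes) the
    manifest with a deterministic ``summary`` block."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    if config.design == "chronic":
        cohort = _stage("simulate")(simulate_cohort, config.cohort)
    else:
        cohort = _stage("simulate")(
            simulate_acute_cohort, config.cohort, config.n_acute_subjects
        )

    fd_table, onsets, k_max, _ = _stage("fd_extraction")(
        fd_table_from_recordings, cohort.recordings, config
    )
    means = _subject_means(fd_table)

    summary: dict = {
        "design": config.design,
        "n_recordings": len(cohort.recordings),
        "n_epochs": int(len(fd_table)),
        "group_k_onsets": onsets,
        "k_max": int(k_max),
        "fd_group_means": {
            f"{g}/{t}": float(v)
            for (g, t), v in means.groupby(["group", "treatment"])["value"].mean().items()
        },
    }

    checks = _stage("assumption_checks")(
        assumption_checks, means, "condition", "value"
    )
    summary["assumptions"] = {
        "levene_p": checks.levene_p,
        "shapiro_residuals_p": checks.shapiro_residuals_p,
        "warnings": checks.warnings,
    }

    if config.design == "acute":
        anova = _stage("stats")(rm_anova_oneway, means, "subject_id", "condition", "value")
        lsd_pairs = [("pd", "control"), ("pd", "pd_treated"), ("control", "pd_treated")]
        lsd = {
            f"{a}_vs_{b}": _stage("stats")(
                fisher_lsd, means, anova, (a, b),
                subject="subject_id", condition="condition", value="value",
            )
            for a, b in lsd_pairs
        }
        summary["anova"] = [_anova_dict(anova)]
        summary["lsd"] = {k: _lsd_dict(v) for k, v in lsd.items()}
    else:
        results = _stage("stats")(
            mixed_anova_twoway, means, "subject_id", "group", "treatment", "value"
        )
        by_name = {r.effect_name: r for r in results}
        lsd = {
            "pd_vs_control": _stage("stats")(
                fisher_lsd, means, by_name["group"], ("pd", "control"),
                subject="subject_id", condition="treatment", value="value",
            ),
            "pd_baseline_vs_treated": _stage("stats")(
                fisher_lsd, means, by_name["treatment"], ("baseline", "treated"),
                subject="subject_id", condition="treatment", value="value",
                within_group="pd",
            ),
            "control_baseline_vs_treated": _stage("stats")(
                fisher_lsd, means, by_name["treatment"], ("baseline", "treated"),
                subject="subject_id", condition="treatment", value="value",
                within_group="control",
            ),
        }
        summary["anova"] = [_anova_dict(r) for r in results]
        summary["lsd"] = {k: _lsd_dict(v) for k, v in lsd.items()}

        features = _stage("classification")(
            build_features, fd_table, ["pd", "control"]
        )
        cv = _stage("classification")(loocv_classify, features, config.c_grid)
        counts = confusion(cv)
        rep = metrics(counts)
        roc = roc_auc(cv.scores, cv.y_true)
        clf_summary = {
            "n_subjects": len(features.subject_ids),
            "n_features": len(features.channel_ids),
            "confusion": asdict(counts),
            "accuracy": rep.accuracy,
            "sensitivity": rep.sensitivity,
            "specificity": rep.specificity,
            "precision": rep.precision,
            "f1": rep.f1,
            "auc": roc.auc,
            "selected_c": cv.selected_c,
        }
        if config.run_permutation:
            perm = _stage("classification")(
                permutation_test, features,
                n_perm=config.n_perm, seed=config.classifier_seed,
                c_grid=config.c_grid,
            )
            clf_summary["permutation_p"] = perm.p
        summary["classification"] = clf_summary

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "artifacts": artifacts,
        "summary": summary,
    }
    if outdir:
        fd_path = outdir / "fd_table.csv"
        fd_table.to_csv(fd_path, index=False)
        artifacts["fd_table"] = str(fd_path)
        truth_path = outdir / "truth.csv"
        cohort.truth.to_csv(truth_path, index=False)
        artifacts["truth"] = str(truth_path)
        manifest_path = outdir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=_jsonable)
        artifacts["manifest"] = str(manifest_path)
    return manifest


def _anova_dict(a) -> dict:
    return {
        "effect": a.effect_name,
        "F": a.F,
        "df": [a.df_num, a.df_den],
        "p": a.p,
        "ms_error": a.ms_error,
    }


def _lsd_dict(r) -> dict:
    return {
        "pair": list(r.pair), "mean_diff": r.mean_diff, "t": r.t,
        "df": r.df, "p": r.p,
    }


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
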