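"""End-to-end orchestration: simulate -> extract -> metrics -> infer -> report.

Every stage persists its output (CSV/JSON) into the run directory so each
can be re-run independently, and the final report is recomputable from the
persisted intermediates. The report contains no timestamps or host
information, so a rerun with the same config and seed is byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import BLOCK_TYPE_SITES, GeneratorConfig, SITE_SPINAL, SITE_VL
from .extraction import steady_table, windowed_table
from .inference import early_late_comparison, fit_error_model, welch_t
from .io import write_study
from .metrics import (
    angular_deviation_to_mean,
    combined_r2,
    compute_error_table,
    compute_windowed_error_table,
)
from .recruitment import RecruitmentCurve, recruitment_summary
from .synthetic import generate_recruitment_trials, generate_study
from .extraction import demean_trace, steady_state_vector

log = logging.getLogger("costim")

_FLOAT_FMT = "%.17g"


def _stage(name: str, n_in: int, n_out: int, seed: int) -> None:
    log.info("stage=%s n_in=%d n_out=%d seed=%d", name, n_in, n_out, seed)


def config_hash(config: GeneratorConfig) -> str:
    payload = json.dumps(json.loads(config.model_dump_json()), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _within_subject_deviations(steady: pd.DataFrame) -> pd.DataFrame:
    """Angle of each single-site trial to its subject's mean vector.

    Spinal vectors come from the spinal-only trials of spinal/muscle blocks;
    muscle vectors from the VL-only trials of the same blocks.
    """
    sm = steady[steady["block_type"] == "spinal_muscle"]
    rows = []
    for (subject, cond), g in sm.groupby(["subject_id", "condition"]):
        if cond == "co_stim":
            continue
        site = "spinal" if cond == "site_A_only" else "muscle"
        if len(g) < 2:
            continue
        devs = angular_deviation_to_mean(g[["fx", "fy", "fz"]].to_numpy())
        for d in devs:
            rows.append({"subject_id": subject, "site": site, "deviation_deg": d})
    return pd.DataFrame(rows)


def _recruitment_stage(config: GeneratorConfig, out: Path) -> pd.DataFrame:
    rows = []
    for site in (SITE_SPINAL, SITE_VL):
        for subject in range(1, config.n_subjects + 1):
            traces = generate_recruitment_trials(config, subject, site)
            vecs = np.array([steady_state_vector(demean_trace(t)).vector
                             for t in traces])
            amps = np.array([t.meta["amplitude_a"] for t in traces], dtype=float)
            s = recruitment_summary(RecruitmentCurve(site, amps, vecs))
            rows.append({"site_id": site, "subject_id": subject,
                         "direction_spread": s["direction_spread"],
                         "monotone_magnitude": s["monotone_magnitude"]})
    df = pd.DataFrame(rows)
    df.to_csv(out / "recruitment.csv", index=False, float_format=_FLOAT_FMT)
    return df


def run_pipeline(config: GeneratorConfig, out_dir: str | Path,
                 seed: int | None = None) -> dict:
    """Run the full analysis on a freshly simulated study; return the report."""
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    study = generate_study(config)
    write_study(study, out)
    _stage("simulate", len(study.design), len(study.traces), config.seed)

    steady = steady_table(study.traces)
    steady.to_csv(out / "vectors.csv", index=False, float_format=_FLOAT_FMT)
    windowed = windowed_table(study.traces)
    windowed.to_csv(out / "windowed_vectors.csv", index=False, float_format=_FLOAT_FMT)
    _stage("extract", len(study.traces), len(steady) + len(windowed), config.seed)

    errors = compute_error_table(steady)
    errors.to_csv(out / "errors.csv", index=False, float_format=_FLOAT_FMT)
    werrors = compute_windowed_error_table(windowed)
    werrors.to_csv(out / "windowed_errors.csv", index=False, float_format=_FLOAT_FMT)
    _stage("metrics", len(steady), len(errors) + len(werrors), config.seed)

    devs = _within_subject_deviations(steady)
    devs.to_csv(out / "within_subject_deviations.csv", index=False,
                float_format=_FLOAT_FMT)
    recruit = _recruitment_stage(config, out)
    _stage("recruitment", config.n_subjects, len(recruit), config.seed)

    models = {}
    for response in ("force", "normalized", "magnitude", "direction"):
        models[response] = fit_error_model(errors, response=response).to_dict()
    models["force_with_magnitude"] = fit_error_model(
        errors, response="force", include_predicted_magnitude=True).to_dict()
    models["early_late"] = early_late_comparison(werrors).to_dict()
    _stage("infer", len(errors), len(models), config.seed)

    report = _build_report(config, errors, devs, recruit, models)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "summary.txt").write_text(_summary_text(report))
    _stage("report", len(errors), 1, config.seed)
    return report


def _build_report(config: GeneratorConfig, errors: pd.DataFrame,
                  devs: pd.DataFrame, recruit: pd.DataFrame,
                  models: dict) -> dict:
    per_type: dict = {}
    for typ, g in errors.groupby("costim_type"):
        pred = g[["pred_fx", "pred_fy", "pred_fz"]].to_numpy()
        obs = g[["obs_fx", "obs_fy", "obs_fz"]].to_numpy()
        per_type[str(typ)] = {
            "n_trials": int(len(g)),
            "median_force_error_N": float(g["force_prediction_error"].median()),
            "median_normalized_error_pct": float(100 * g["normalized_error"].median()),
            "mean_predicted_magnitude_N": float(g["predicted_magnitude"].mean()),
            "combined_r2": combined_r2(pred, obs),
        }

    dev_summary: dict = {}
    welch_dev = None
    if not devs.empty:
        for site, g in devs.groupby("site"):
            dev_summary[str(site)] = {
                "n": int(len(g)),
                "mean_deg": float(g["deviation_deg"].mean()),
                "max_deg": float(g["deviation_deg"].max()),
            }
        if {"spinal", "muscle"} <= set(devs["site"]):
            welch_dev = welch_t(
                devs.loc[devs["site"] == "spinal", "deviation_deg"],
                devs.loc[devs["site"] == "muscle", "deviation_deg"])

    spread = {}
    welch_spread = None
    if not recruit.empty:
        for site, g in recruit.groupby("site_id"):
            spread[str(site)] = {
                "mean_direction_spread_deg": float(g["direction_spread"].mean()),
                "all_monotone": bool(g["monotone_magnitude"].all()),
            }
        spinal = recruit.loc[recruit["site_id"] == SITE_SPINAL, "direction_spread"]
        muscle = recruit.loc[recruit["site_id"] == SITE_VL, "direction_spread"]
        if len(spinal) >= 2 and len(muscle) >= 2:
            welch_spread = welch_t(spinal, muscle)

    return {
        "provenance": {
            "package_version": __version__,
            "config_hash": config_hash(config),
            "seed": config.seed,
            "config": json.loads(config.model_dump_json()),
        },
        "per_type": per_type,
        "within_subject_deviation": dev_summary,
        "within_subject_deviation_welch": welch_dev,
        "recruitment_direction_spread": spread,
        "recruitment_spread_welch": welch_spread,
        "mixed_models": models,
    }


def _summary_text(report: dict) -> str:
    lines = [f"costim study report (seed={report['provenance']['seed']}, "
             f"config={report['provenance']['config_hash']})", ""]
    for typ, v in report["per_type"].items():
        lines.append(
            f"{typ}: n={v['n_trials']}  median error {v['median_force_error_N']:.3f} N "
            f"({v['median_normalized_error_pct']:.1f}% of predicted)  "
            f"combined R^2 {v['combined_r2']:.3f}")
    lines.append("")
    for site, v in report["recruitment_direction_spread"].items():
        lines.append(f"recruitment spread {site}: "
                     f"{v['mean_direction_spread_deg']:.2f} deg "
                     f"(monotone magnitudes: {v['all_monotone']})")
    for site, v in report["within_subject_deviation"].items():
        lines.append(f"within-subject deviation {site}: mean "
                     f"{v['mean_deg']:.2f} deg, max {v['max_deg']:.2f} deg")
    lines.append("")
    for name, m in report["mixed_models"].items():
        term = ("period[late]" if name == "early_late"
                else "costim_type[spinal_muscle]")
        fe = m["fixed_effects"].get(term)
        if fe:
            lines.append(f"model {name}: {term} est {fe['estimate']:+.3f}, "
                         f"p = {fe['p']:.3g} ({m['ladder_name']})")
    return "\n".join(lines) + "\n"
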