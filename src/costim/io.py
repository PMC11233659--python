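"""CSV/JSON interchange for simulated or recorded studies.

A study directory contains:

``trials.csv``
    one row per trial: subject_id, block_type, block_id, slot_order,
    condition, site_a, site_b, amplitude_a, amplitude_b, trial_id.
``traces.csv``
    long format: trial_id, t, fx, fy, fz (seconds and newtons).
``study.json``
    sidecar with the generator config, seed, axis convention and units.

Floats are written with 17 significant digits so a write->read round trip
reproduces the binary values exactly.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AXIS_CONVENTION, GeneratorConfig
from .synthetic import ForceTrace, TrialSet

_FLOAT_FMT = "%.17g"

TRIAL_COLUMNS = ["trial_id", "subject_id", "block_type", "block_id", "slot_order",
                 "condition", "site_a", "site_b", "amplitude_a", "amplitude_b",
                 "stim_onset", "train_duration", "n_pulses_a", "n_pulses_b"]


def trial_table(traces: list[ForceTrace]) -> pd.DataFrame:
    rows = []
    for i, tr in enumerate(traces):
        row = {"trial_id": i, "stim_onset": tr.stim_onset,
               "train_duration": tr.train_duration}
        row.update(tr.meta)
        rows.append(row)
    return pd.DataFrame(rows)[TRIAL_COLUMNS]


def write_study(study: TrialSet, out_dir: str | Path) -> Path:
    """Persist a study; returns the directory written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trial_table(study.traces).to_csv(out / "trials.csv", index=False,
                                     float_format=_FLOAT_FMT)
    parts = []
    for i, tr in enumerate(study.traces):
        parts.append(pd.DataFrame({
            "trial_id": i, "t": tr.t,
            "fx": tr.force[:, 0], "fy": tr.force[:, 1], "fz": tr.force[:, 2],
        }))
    pd.concat(parts, ignore_index=True).to_csv(out / "traces.csv", index=False,
                                               float_format=_FLOAT_FMT)
    sidecar = {
        "config": json.loads(study.config.model_dump_json()),
        "seed": study.config.seed,
        "axis_convention": AXIS_CONVENTION,
        "units": {"force": "N", "time": "s"},
    }
    (out / "study.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return out


def read_study(study_dir: str | Path) -> tuple[pd.DataFrame, list[ForceTrace], GeneratorConfig]:
    """Load (trial table, traces, config) from a study directory."""
    d = Path(study_dir)
    for name in ("trials.csv", "traces.csv", "study.json"):
        if not (d / name).exists():
            raise FileNotFoundError(f"study file missing: {d / name}")
    trials = pd.read_csv(d / "trials.csv", float_precision="round_trip")
    long = pd.read_csv(d / "traces.csv", float_precision="round_trip")
    sidecar = json.loads((d / "study.json").read_text())
    config = GeneratorConfig.model_validate(sidecar["config"])
    traces: list[ForceTrace] = []
    grouped = dict(tuple(long.groupby("trial_id", sort=True)))
    for row in trials.itertuples(index=False):
        g = grouped[row.trial_id]
        meta = {k: getattr(row, k) for k in
                ("subject_id", "block_type", "block_id", "slot_order", "condition",
                 "site_a", "site_b", "amplitude_a", "amplitude_b",
                 "n_pulses_a", "n_pulses_b")}
        traces.append(ForceTrace(
            t=g["t"].to_numpy(),
            force=g[["fx", "fy", "fz"]].to_numpy(),
            stim_onset=float(row.stim_onset),
            train_duration=float(row.train_duration),
            baseline_offset=None,
            meta=meta,
        ))
    return trials, traces, config


def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Read and validate a GeneratorConfig JSON file."""
    return GeneratorConfig.model_validate_json(Path(path).read_text())
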