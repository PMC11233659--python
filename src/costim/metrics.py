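"""Prediction and error statistics on steady-state force vectors.

The linear-summation hypothesis predicts each co-stimulation force as the
componentwise sum of the two single-site forces measured in the same block.
Deviations are quantified four ways: the Euclidean force prediction error,
its magnitude-only and direction-only components, and the error normalized
by the predicted magnitude. Direction dispersion uses the circular angular
deviation sqrt(2(1 - R)) with R the mean resultant length.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, UndefinedDirectionError

_EPS_NORM = 1e-12


def _vec(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("vector contains non-finite components")
    return a


def predicted_vector(v_a, v_b) -> np.ndarray:
    """Linear-summation prediction: componentwise sum of the two site vectors."""
    return _vec(v_a) + _vec(v_b)


def force_prediction_error(predicted, observed) -> float:
    """Euclidean distance between predicted and observed vectors, N."""
    return float(np.linalg.norm(_vec(observed) - _vec(predicted)))


def magnitude_error(predicted, observed) -> float:
    """Absolute difference of the two vector magnitudes, N."""
    return float(abs(np.linalg.norm(_vec(observed)) - np.linalg.norm(_vec(predicted))))


def direction_error(predicted, observed) -> float:
    """3-D angle between predicted and observed vectors, degrees in [0, 180]."""
    p, o = _vec(predicted), _vec(observed)
    np_, no = np.linalg.norm(p), np.linalg.norm(o)
    if np_ < _EPS_NORM or no < _EPS_NORM:
        raise UndefinedDirectionError(
            "direction error undefined for zero-magnitude vector")
    c = np.clip((p @ o) / (np_ * no), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def normalized_error(error: float, predicted) -> float:
    """Force prediction error as a fraction of the predicted magnitude."""
    m = np.linalg.norm(_vec(predicted))
    if m < _EPS_NORM:
        raise UndefinedDirectionError(
            "normalized error undefined for zero predicted magnitude")
    return float(error / m)


def sagittal_angle(v) -> float:
    """Angle of the sagittal-plane (y, z) projection, degrees in (-180, 180].

    0 deg is pure rostral (+y), +90 deg pure dorsal (+z), -90 deg pure
    ventral (-z). The mediolateral (x) component is ignored.
    """
    a = _vec(v)
    if np.hypot(a[1], a[2]) < _EPS_NORM:
        raise UndefinedDirectionError("zero sagittal projection")
    return float(np.degrees(np.arctan2(a[2], a[1])))


def angular_deviation_to_mean(vectors) -> np.ndarray:
    """3-D angle (degrees) between each vector and the arithmetic mean vector."""
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
        raise DegenerateDataError("need at least two 3-vectors")
    mean = arr.mean(axis=0)
    if np.linalg.norm(mean) < _EPS_NORM:
        raise UndefinedDirectionError("mean vector has zero magnitude")
    return np.array([direction_error(mean, v) for v in arr])


def circular_angular_deviation(angles_deg) -> float:
    """Angular deviation s = sqrt(2 (1 - R)) of a set of angles, in degrees.

    R is the mean resultant length of the unit vectors at the given angles;
    s ranges from 0 (all angles equal) to sqrt(2) rad ~ 81.03 deg (R = 0).
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise DegenerateDataError("no angles given")
    r = float(np.hypot(np.sin(a).mean(), np.cos(a).mean()))
    return float(np.degrees(np.sqrt(max(2.0 * (1.0 - r), 0.0))))


def angular_sd(angles_deg) -> float:
    """Alternative dispersion: circular standard deviation sqrt(-2 ln R), degrees."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise DegenerateDataError("no angles given")
    r = float(np.hypot(np.sin(a).mean(), np.cos(a).mean()))
    if r <= 0:
        raise DegenerateDataError("mean resultant length is zero")
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


def combined_r2(predicted, observed) -> float:
    """Coefficient of determination about the unity line, pooled over axes.

    1 - [sum over axes and trials of (obs - pred)^2] / [sum over axes of the
    per-axis total sum of squares about that axis's observed mean]. Residuals
    are taken about perfect prediction (obs = pred), not a fitted line.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 2 or p.shape[0] < 2:
        raise DegenerateDataError("need matching (n >= 2, 3) arrays")
    ss_res = float(((o - p) ** 2).sum())
    ss_tot = float(((o - o.mean(axis=0)) ** 2).sum())
    if ss_tot <= 0:
        raise DegenerateDataError("observed values are constant on every axis")
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# tabular assembly

_KEY = ["subject_id", "block_type", "block_id"]


def _pivot_conditions(steady: pd.DataFrame) -> pd.DataFrame:
    """Wide table with one row per block: _a, _b and _co force columns."""
    need = set(_KEY + ["condition", "fx", "fy", "fz"])
    if not need.issubset(steady.columns):
        raise ValueError(f"steady table missing columns {sorted(need - set(steady.columns))}")
    parts = {}
    for cond, tag in (("site_A_only", "a"), ("site_B_only", "b"), ("co_stim", "co")):
        sub = steady[steady["condition"] == cond]
        parts[tag] = sub.set_index(_KEY)[["fx", "fy", "fz"]].add_suffix(f"_{tag}")
    wide = parts["a"].join(parts["b"], how="inner").join(parts["co"], how="inner")
    return wide.reset_index()


def compute_error_table(steady: pd.DataFrame) -> pd.DataFrame:
    """Per-co-stimulation-trial error records from a steady-vector table.

    Predictions pair each co-stimulation trial with the two single-site
    trials of the same (subject, block type, block).
    """
    wide = _pivot_conditions(steady)
    rows = []
    for r in wide.itertuples(index=False):
        pred = predicted_vector((r.fx_a, r.fy_a, r.fz_a), (r.fx_b, r.fy_b, r.fz_b))
        obs = np.array([r.fx_co, r.fy_co, r.fz_co])
        err = force_prediction_error(pred, obs)
        rows.append({
            "subject_id": r.subject_id,
            "block_type": r.block_type,
            "block_id": r.block_id,
            "pred_fx": pred[0], "pred_fy": pred[1], "pred_fz": pred[2],
            "obs_fx": obs[0], "obs_fy": obs[1], "obs_fz": obs[2],
            "predicted_magnitude": float(np.linalg.norm(pred)),
            "force_prediction_error": err,
            "magnitude_error": magnitude_error(pred, obs),
            "direction_error": direction_error(pred, obs),
            "normalized_error": normalized_error(err, pred),
        })
    out = pd.DataFrame(rows)
    return out.rename(columns={"block_type": "costim_type"})


def compute_windowed_error_table(windowed: pd.DataFrame) -> pd.DataFrame:
    """Per-window force prediction errors for every co-stimulation trial.

    Windows are matched on ``window_start`` across the three conditions of a
    block; windows present in only some conditions (trains of different
    lengths) are dropped.
    """
    key = _KEY + ["window_start"]
    parts = {}
    for cond, tag in (("site_A_only", "a"), ("site_B_only", "b"), ("co_stim", "co")):
        sub = windowed[windowed["condition"] == cond]
        parts[tag] = sub.set_index(key)[["fx", "fy", "fz"]].add_suffix(f"_{tag}")
    wide = parts["a"].join(parts["b"], how="inner").join(parts["co"], how="inner")
    wide = wide.reset_index()
    pred = wide[["fx_a", "fy_a", "fz_a"]].to_numpy() + wide[["fx_b", "fy_b", "fz_b"]].to_numpy()
    obs = wide[["fx_co", "fy_co", "fz_co"]].to_numpy()
    err = np.linalg.norm(obs - pred, axis=1)
    out = wide[key].copy()
    out["force_prediction_error"] = err
    return out.rename(columns={"block_type": "costim_type"})
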