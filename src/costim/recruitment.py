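"""Recruitment-curve characterization: magnitude and direction vs amplitude.

A recruitment curve is the series of steady-state force vectors evoked by
one site over increasing stimulation amplitudes. Muscle-site curves grow in
magnitude with nearly fixed direction; spinal-site curves additionally
rotate in the sagittal plane as amplitude recruits more of the surrounding
tissue, so their direction spread is the discriminating summary.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, WindowError
from .metrics import circular_angular_deviation, sagittal_angle


@dataclass(frozen=True)
class RecruitmentCurve:
    site_id: str
    amplitudes: np.ndarray  # (k,) stimulator units, strictly increasing
    vectors: np.ndarray     # (k, 3) steady-state forces, N

    def __post_init__(self):
        amps = np.asarray(self.amplitudes, dtype=float)
        vecs = np.asarray(self.vectors, dtype=float)
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "vectors", vecs)
        if amps.ndim != 1 or vecs.shape != (amps.size, 3):
            raise DegenerateDataError("amplitudes and vectors must align (k,) / (k, 3)")
        if np.any(np.diff(amps) <= 0):
            raise DegenerateDataError("amplitudes must be strictly increasing")


def recruitment_summary(curve: RecruitmentCurve,
                        monotone_tol_frac: float = 0.01) -> dict:
    """Magnitudes, sagittal angles, direction spread and monotonicity check.

    ``direction_spread`` is the circular angular deviation of the per-
    amplitude sagittal angles. Monotonicity of magnitude is assessed with a
    tolerance of ``monotone_tol_frac`` of the maximum magnitude to absorb
    measurement noise.
    """
    if curve.amplitudes.size < 3:
        raise DegenerateDataError("need at least 3 amplitudes for a recruitment summary")
    mags = np.linalg.norm(curve.vectors, axis=1)
    angles = np.array([sagittal_angle(v) for v in curve.vectors])
    tol = monotone_tol_frac * float(mags.max())
    monotone = bool(np.all(np.diff(mags) >= -tol))
    return {
        "site_id": curve.site_id,
        "magnitudes": mags,
        "sagittal_angles": angles,
        "direction_spread": circular_angular_deviation(angles),
        "monotone_magnitude": monotone,
    }


def select_amplitude(curve: RecruitmentCurve,
                     target_range: tuple[float, float] = (0.5, 1.8),
                     rule: str = "smallest") -> float:
    """Choose the stimulation amplitude for the main study.

    Returns the smallest amplitude whose evoked magnitude falls in
    ``target_range`` (the rodent stance-phase ground-reaction-force band,
    0.5-1.8 N, by default); ``rule="mid"`` instead picks the in-band
    amplitude whose magnitude is closest to the band midpoint.
    """
    lo, hi = target_range
    mags = np.linalg.norm(curve.vectors, axis=1)
    in_band = np.flatnonzero((mags >= lo) & (mags <= hi))
    if in_band.size == 0:
        raise WindowError(
            f"no amplitude evokes a force in [{lo}, {hi}] N; "
            f"achieved magnitudes: {np.round(mags, 3).tolist()}")
    if rule == "smallest":
        idx = int(in_band[0])
    elif rule == "mid":
        mid = 0.5 * (lo + hi)
        idx = int(in_band[np.argmin(np.abs(mags[in_band] - mid))])
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    return float(curve.amplitudes[idx])


def curve_from_table(df: pd.DataFrame, site_id: str) -> RecruitmentCurve:
    """Build a curve from a table with columns amplitude, fx, fy, fz."""
    sub = df.sort_values("amplitude")
    return RecruitmentCurve(site_id, sub["amplitude"].to_numpy(),
                            sub[["fx", "fy", "fz"]].to_numpy())


def summary_table(curves: list[RecruitmentCurve]) -> pd.DataFrame:
    """Long-form summary (site, amplitude, force, magnitude, angle) for CSV."""
    rows = []
    for c in curves:
        s = recruitment_summary(c)
        for amp, v, m, a in zip(c.amplitudes, c.vectors, s["magnitudes"],
                                s["sagittal_angles"]):
            rows.append({"site_id": c.site_id, "amplitude": amp,
                         "fx": v[0], "fy": v[1], "fz": v[2],
                         "magnitude": m, "sagittal_angle": a,
                         "direction_spread": s["direction_spread"],
                         "monotone_magnitude": s["monotone_magnitude"]})
    return pd.DataFrame(rows)
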