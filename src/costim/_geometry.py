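"""Small 3-D rotation helpers shared by the generator and tests."""
from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

_X_AXIS = np.array([1.0, 0.0, 0.0])


def rotate_sagittal(v: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate ``v`` within the sagittal (y, z) plane, i.e. about the x axis."""
    if angle_deg == 0.0:
        return np.asarray(v, dtype=float)
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * _X_AXIS).apply(v)


def rotate_random_cone(v: np.ndarray, angle_sd_deg: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Tilt ``v`` by an angle ~ N(0, angle_sd_deg) about a random axis ⟂ v.

    Magnitude is preserved exactly; only the direction is jittered. With
    ``angle_sd_deg == 0`` the input is returned unchanged (and the rng is not
    consumed, keeping zero-jitter runs stream-compatible with the docs).
    """
    v = np.asarray(v, dtype=float)
    if angle_sd_deg == 0.0:
        return v
    n = np.linalg.norm(v)
    if n < 1e-300:
        return v
    u = rng.normal(size=3)
    u = u - (u @ v) * v / n**2  # orthogonalize against v
    un = np.linalg.norm(u)
    if un < 1e-12:  # pathological draw; fall back to any perpendicular
        u = np.cross(v, _X_AXIS if abs(v[0]) < 0.9 * n else [0.0, 1.0, 0.0])
        un = np.linalg.norm(u)
    angle = np.deg2rad(rng.normal(0.0, angle_sd_deg))
    return Rotation.from_rotvec(angle * u / un).apply(v)
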