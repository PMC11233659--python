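"""Configuration models for the synthetic study generator and power simulation.

All configs are pydantic models so that JSON files round-trip losslessly and
invalid values fail loudly at load time rather than deep inside a simulation.

Axis convention (fixed throughout the package): x = medial(-)/lateral(+),
y = caudal(-)/rostral(+), z = ventral(-)/dorsal(+). The sagittal plane is the
(y, z) plane. Units are newtons and seconds unless stated otherwise.
"""
from __future__ import annotations

import math
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .exceptions import ConfigurationError

#: Anatomical meaning of the three force axes.
AXIS_CONVENTION = {
    "x": "medial(-) / lateral(+)",
    "y": "caudal(-) / rostral(+)",
    "z": "ventral(-) / dorsal(+)",
    "sagittal_plane": "(y, z)",
}

SITE_SPINAL = "spinal_L5"
SITE_VL = "muscle_VL"
SITE_BF = "muscle_BF"

#: site pairs stimulated together in each co-stimulation block type
BLOCK_TYPE_SITES = {
    "spinal_muscle": (SITE_SPINAL, SITE_VL),
    "muscle_muscle": (SITE_VL, SITE_BF),
}

BLOCK_TYPES = tuple(BLOCK_TYPE_SITES)
CONDITIONS = ("site_A_only", "site_B_only", "co_stim")


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class StimTrain(_Frozen):
    """A biphasic stimulation train: fixed-period pulses for a fixed duration."""

    period: float = Field(gt=0, description="inter-pulse period, s")
    pulse_width: float = Field(gt=0, description="single-phase pulse width, s")
    train_duration: float = Field(gt=0, description="total train duration, s")
    amplitude: float = Field(default=1.0, gt=0, description="stimulator units (arbitrary)")

    @model_validator(mode="after")
    def _check(self) -> "StimTrain":
        if self.pulse_width >= self.period:
            raise ConfigurationError(
                f"pulse_width {self.pulse_width} must be < period {self.period}"
            )
        if self.n_pulses < 1:
            raise ConfigurationError("train must contain at least one pulse")
        return self

    @property
    def n_pulses(self) -> int:
        # tolerant floor: 0.520 / 0.013 must count as exactly 40 pulses
        return int(math.floor(self.train_duration / self.period + 1e-9))


class SiteParams(_Frozen):
    """Population-level response parameters for one stimulation site.

    ``base_direction`` is the population-mean force direction (unit vector);
    per-subject directions are rotated away from it by the generator.
    ``amplitude_gain_curve`` maps the recruitment-curve amplitude step
    (1-based) to relative force magnitude; ``reference_amplitude`` is the step
    used for the main co-stimulation study, where the gain is 1 so that the
    subject's drawn magnitude is produced unchanged.
    """

    base_direction: tuple[float, float, float]
    base_magnitude_mean: float = Field(gt=0, description="N, population mean")
    base_magnitude_sd: float = Field(ge=0, description="N, between subjects")
    transient_overshoot: float = Field(default=0.0, ge=0,
                                       description="initial transient, fraction of steady")
    transient_tau: float = Field(default=0.08, gt=0, description="transient decay, s")
    rise_tau: float = Field(default=0.02, gt=0, description="force rise time constant, s")
    amplitude_gain_curve: tuple[float, ...] = (0.1, 0.25, 0.45, 0.7, 1.0, 1.25, 1.45, 1.6)
    direction_rotation_per_amplitude: float = Field(
        default=0.0,
        description="sagittal-plane rotation per recruitment step, degrees",
    )
    reference_amplitude: int = Field(default=5, ge=1,
                                     description="1-based step used in the main study")

    @field_validator("base_direction")
    @classmethod
    def _unit(cls, v: tuple[float, float, float]) -> tuple[float, float, float]:
        n = float(np.linalg.norm(v))
        if n < 1e-12:
            raise ConfigurationError("base_direction must be nonzero")
        if abs(n - 1.0) < 1e-9:  # already unit: keep bytes stable on re-validation
            return tuple(float(c) for c in v)  # type: ignore[return-value]
        return tuple(float(c) / n for c in v)  # type: ignore[return-value]

    @model_validator(mode="after")
    def _check(self) -> "SiteParams":
        g = self.amplitude_gain_curve
        if any(b < a - 1e-12 for a, b in zip(g, g[1:])):
            raise ConfigurationError("amplitude_gain_curve must be non-decreasing")
        if self.reference_amplitude > len(g):
            raise ConfigurationError("reference_amplitude exceeds gain-curve length")
        return self

    def direction_array(self) -> np.ndarray:
        return np.asarray(self.base_direction, dtype=float)


def _default_sites() -> dict[str, SiteParams]:
    # Magnitude anchors: spinal 0.55 +/- 0.27 N, muscle 0.70 +/- 0.21 N.
    # Directions follow the anatomical descriptions: the knee extensor VL pulls
    # lateral/caudal/ventral, BF (knee flexor, hip extensor) caudal/dorsal, and
    # the L5 spinal site medial/caudal with its spread in the sagittal plane.
    return {
        SITE_SPINAL: SiteParams(
            base_direction=(-0.55, -0.55, 0.63),
            base_magnitude_mean=0.55,
            base_magnitude_sd=0.27,
            transient_overshoot=0.5,
            direction_rotation_per_amplitude=4.0,
        ),
        SITE_VL: SiteParams(
            base_direction=(0.40, -0.55, -0.73),
            base_magnitude_mean=0.70,
            base_magnitude_sd=0.21,
            transient_overshoot=0.0,
            direction_rotation_per_amplitude=0.2,
        ),
        SITE_BF: SiteParams(
            base_direction=(0.25, -0.85, 0.47),
            base_magnitude_mean=0.70,
            base_magnitude_sd=0.21,
            transient_overshoot=0.0,
            direction_rotation_per_amplitude=0.2,
        ),
    }


class GeneratorConfig(_Frozen):
    """Full description of one synthetic co-stimulation study."""

    n_subjects: int = Field(default=12, ge=1)
    n_blocks: int = Field(default=8, ge=1, description="blocks per co-stimulation type")
    sample_rate: float = Field(default=1000.0, gt=0, description="Hz")
    pre_stim_duration: float = Field(default=0.5, gt=0, description="s before onset")
    post_train_duration: float = Field(default=0.3, ge=0, description="s after train end")
    spinal_train: StimTrain = StimTrain(period=0.015, pulse_width=0.0002, train_duration=0.600)
    muscle_train: StimTrain = StimTrain(period=0.013, pulse_width=0.00012, train_duration=0.520)
    site_params: dict[str, SiteParams] = Field(default_factory=_default_sites)
    interaction_gain: float = Field(default=0.0, description="lambda, dimensionless")
    interaction_mode: Literal["gain", "occlusion", "facilitation"] = "gain"
    interaction_on: Literal["all", "spinal_muscle", "muscle_muscle"] = Field(
        default="all", description="block types the interaction term applies to")
    noise_sd: float = Field(default=0.02, ge=0, description="N per axis per sample")
    between_subject_dir_sd: float = Field(default=10.0, ge=0, description="degrees")
    within_subject_dir_sd: float = Field(default=4.0, ge=0, description="degrees")
    baseline_offset_range: float = Field(default=0.2, ge=0,
                                         description="N, uniform +/- per axis per trial")
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        missing = {s for pair in BLOCK_TYPE_SITES.values() for s in pair} - set(self.site_params)
        if missing:
            raise ConfigurationError(f"site_params missing sites: {sorted(missing)}")
        if self.pre_stim_duration < 0.4:
            raise ConfigurationError(
                "pre_stim_duration must be >= 0.4 s so a 400 ms baseline exists"
            )
        return self

    def train_for(self, site_id: str) -> StimTrain:
        return self.spinal_train if site_id.startswith("spinal") else self.muscle_train

    @property
    def max_train_duration(self) -> float:
        return max(self.spinal_train.train_duration, self.muscle_train.train_duration)

    @property
    def total_duration(self) -> float:
        return self.pre_stim_duration + self.max_train_duration + self.post_train_duration


class VarianceParams(_Frozen):
    """Variance structure of the log-error generative model used for power.

    Log-scale SDs describe a log-normal error model: per-subject random
    intercepts and type slopes (bivariate normal, possibly correlated) plus
    i.i.d. residuals. ``baseline_median_error_N`` anchors the natural-scale
    median error of the reference (muscle/muscle) type.
    """

    between_subject_sd_log: float = Field(default=0.6, ge=0)
    slope_sd_log: float = Field(default=0.6, ge=0)
    intercept_slope_corr: float = Field(default=0.2, ge=-1, le=1)
    residual_sd_log: float = Field(default=0.5, ge=0)
    baseline_median_error_N: float = Field(default=0.10, gt=0)

    def covariance(self) -> np.ndarray:
        c = self.intercept_slope_corr * self.between_subject_sd_log * self.slope_sd_log
        return np.array([
            [self.between_subject_sd_log**2, c],
            [c, self.slope_sd_log**2],
        ])


class PowerConfig(_Frozen):
    """Design and effect size for the Monte-Carlo power analysis."""

    n_subjects: int = Field(default=12, ge=2)
    trials_per_subject_per_type: int = Field(default=8, ge=2)
    effect: float = Field(default=0.1, ge=0,
                          description="N, natural-scale median error difference")
    alpha: float = Field(default=0.05, gt=0, lt=1)
    n_reps: int = Field(default=1000, ge=1)
    variance_params: VarianceParams = VarianceParams()
    seed: int = 0
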