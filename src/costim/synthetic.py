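"""Seeded synthetic co-stimulation studies.

Generates the trial structure and 3-axis isometric force traces of a
two-site stimulation experiment: for each subject, randomized blocks of
(site A alone, site B alone, co-stimulation) trials, repeated ``n_blocks``
times per co-stimulation type (spinal+muscle and muscle+muscle).

The force model is phenomenological. Each site's steady evoked force is a
per-subject vector (population direction tilted by a between-subject angle,
magnitude drawn truncated-positive normal). A trial multiplies that vector
by an envelope that rises exponentially at stimulus onset, carries an
optional decaying overshoot transient (spinal sites), and relaxes after the
train ends. Co-stimulation responses are the sum of the two single-site
responses plus an optional, tunable interaction term; with
``interaction_gain = 0`` the expected steady response is exactly additive,
which is the null hypothesis the downstream analysis tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from ._geometry import rotate_random_cone, rotate_sagittal
from ._rng import TAG_DESIGN, TAG_RECRUIT, TAG_SUBJECT, TAG_TRIAL, stream
from .config import (
    BLOCK_TYPE_SITES,
    BLOCK_TYPES,
    CONDITIONS,
    GeneratorConfig,
    SiteParams,
)
from .exceptions import ConfigurationError

_BT_CODE = {bt: i for i, bt in enumerate(BLOCK_TYPES)}
_COND_CODE = {c: i for i, c in enumerate(CONDITIONS)}


# ---------------------------------------------------------------------------
# design


@dataclass(frozen=True)
class TrialSlot:
    """One scheduled trial within a block."""

    subject_id: int
    block_type: str        # "spinal_muscle" | "muscle_muscle"
    block_id: int          # 1-based within (subject, block_type)
    slot_order: int        # 0..2 position within the block
    condition: str         # "site_A_only" | "site_B_only" | "co_stim"

    @property
    def site_a(self) -> str:
        return BLOCK_TYPE_SITES[self.block_type][0]

    @property
    def site_b(self) -> str:
        return BLOCK_TYPE_SITES[self.block_type][1]


@dataclass(frozen=True)
class StudyDesign:
    slots: tuple[TrialSlot, ...]

    def co_stim_count(self, block_type: str) -> int:
        return sum(1 for s in self.slots
                   if s.block_type == block_type and s.condition == "co_stim")

    def __len__(self) -> int:
        return len(self.slots)


def make_design(config: GeneratorConfig) -> StudyDesign:
    """Block-randomized trial schedule for the whole study.

    Each (subject, block type, block) gets an independent seeded permutation
    of the three conditions, so the schedule of any block is unaffected by
    how many other subjects or blocks exist.
    """
    slots: list[TrialSlot] = []
    for subject in range(1, config.n_subjects + 1):
        for bt in BLOCK_TYPES:
            for block in range(1, config.n_blocks + 1):
                rng = stream(config.seed, TAG_DESIGN, subject, _BT_CODE[bt], block)
                order = rng.permutation(len(CONDITIONS))
                for pos, cond_idx in enumerate(order):
                    slots.append(TrialSlot(subject, bt, block, pos,
                                           CONDITIONS[int(cond_idx)]))
    return StudyDesign(tuple(slots))


# ---------------------------------------------------------------------------
# subject parameters


@dataclass(frozen=True)
class RealizedSite:
    """Per-subject realization of one site's response parameters."""

    site_id: str
    direction: np.ndarray  # unit 3-vector
    magnitude: float       # N, steady-state at the reference amplitude
    params: SiteParams


def sample_subject_params(config: GeneratorConfig,
                          subject_id: int) -> dict[str, RealizedSite]:
    """Draw one subject's site vectors.

    Directions tilt away from the population direction by an angle
    ~ N(0, between_subject_dir_sd) about a random perpendicular axis;
    magnitudes are truncated-positive normal.
    """
    rng = stream(config.seed, TAG_SUBJECT, subject_id)
    out: dict[str, RealizedSite] = {}
    for site_id in sorted(config.site_params):
        p = config.site_params[site_id]
        direction = rotate_random_cone(p.direction_array(),
                                       config.between_subject_dir_sd, rng)
        direction = direction / np.linalg.norm(direction)
        if p.base_magnitude_sd == 0:
            magnitude = p.base_magnitude_mean
        else:
            a = -p.base_magnitude_mean / p.base_magnitude_sd
            magnitude = float(stats.truncnorm.rvs(
                a, np.inf, loc=p.base_magnitude_mean,
                scale=p.base_magnitude_sd, random_state=rng))
        out[site_id] = RealizedSite(site_id, direction, magnitude, p)
    return out


# ---------------------------------------------------------------------------
# traces


@dataclass
class ForceTrace:
    """One trial's 3-axis force recording on a uniform time grid."""

    t: np.ndarray             # (T,) s
    force: np.ndarray         # (T, 3) N, axis convention in costim.config
    stim_onset: float         # s
    train_duration: float     # s (for co-stim: the shorter of the two trains)
    baseline_offset: np.ndarray | None = None  # generator-injected; unknown to analysis
    meta: dict = field(default_factory=dict)

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    def copy_with(self, force: np.ndarray) -> "ForceTrace":
        return ForceTrace(self.t, force, self.stim_onset, self.train_duration,
                          self.baseline_offset, dict(self.meta))


def _envelope(t: np.ndarray, onset: float, train_dur: float,
              p: SiteParams) -> np.ndarray:
    """Rise + optional overshoot during the train, exponential relax after."""
    e = np.zeros_like(t)
    during = (t >= onset) & (t < onset + train_dur)
    after = t >= onset + train_dur
    tt = t[during] - onset
    e[during] = (1.0 - np.exp(-tt / p.rise_tau)) * (
        1.0 + p.transient_overshoot * np.exp(-tt / p.transient_tau))
    e_end = (1.0 - np.exp(-train_dur / p.rise_tau)) * (
        1.0 + p.transient_overshoot * np.exp(-train_dur / p.transient_tau))
    e[after] = e_end * np.exp(-(t[after] - onset - train_dur) / p.rise_tau)
    return e


def interaction_term(f_a: np.ndarray, f_b: np.ndarray, mode: str) -> np.ndarray:
    """Stylized departure-from-additivity term I(F_A, F_B).

    gain: scales the total (I = F_A + F_B); occlusion: removes the projection
    of the smaller vector onto the larger; facilitation: adds extra force
    along the combined direction, proportional to the magnitude product
    (normalized by 1 N).
    """
    f_a = np.asarray(f_a, float)
    f_b = np.asarray(f_b, float)
    if mode == "gain":
        return f_a + f_b
    if mode == "occlusion":
        small, large = (f_a, f_b) if np.linalg.norm(f_a) <= np.linalg.norm(f_b) else (f_b, f_a)
        ln = np.linalg.norm(large)
        if ln < 1e-300:
            return np.zeros(3)
        u = large / ln
        return -(small @ u) * u
    if mode == "facilitation":
        s = f_a + f_b
        sn = np.linalg.norm(s)
        if sn < 1e-300:
            return np.zeros(3)
        return (s / sn) * np.linalg.norm(f_a) * np.linalg.norm(f_b) / 1.0
    raise ConfigurationError(f"unknown interaction mode {mode!r}")


def _realized_steady(site: RealizedSite, amplitude_step: int,
                     jitter_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Trial-level steady vector for one site at a recruitment step."""
    p = site.params
    if not 1 <= amplitude_step <= len(p.amplitude_gain_curve):
        raise ConfigurationError(
            f"amplitude step {amplitude_step} outside gain curve of {site.site_id}")
    gain = p.amplitude_gain_curve[amplitude_step - 1]
    angle = (amplitude_step - p.reference_amplitude) * p.direction_rotation_per_amplitude
    v = site.magnitude * gain * rotate_sagittal(site.direction, angle)
    return rotate_random_cone(v, jitter_sd, rng)


def generate_trace(slot: TrialSlot, subject_params: dict[str, RealizedSite],
                   config: GeneratorConfig,
                   amplitude_steps: dict[str, int] | None = None) -> ForceTrace:
    """Simulate the force trace of one trial.

    The trace is ``baseline_offset + sum_site envelope(t) * steady_vector +
    noise``; for co-stimulation an interaction term ``lambda * I`` modulated
    by the product of the two envelopes is added when ``interaction_gain``
    is nonzero and ``interaction_on`` covers the slot's block type.
    """
    rng = stream(config.seed, TAG_TRIAL, slot.subject_id,
                 _BT_CODE[slot.block_type], slot.block_id, slot.slot_order)
    sr = config.sample_rate
    n = int(round(config.total_duration * sr))
    t = np.arange(n) / sr
    onset = config.pre_stim_duration

    if slot.condition == "site_A_only":
        sites = [slot.site_a]
    elif slot.condition == "site_B_only":
        sites = [slot.site_b]
    else:
        sites = [slot.site_a, slot.site_b]

    steps = {s: (amplitude_steps or {}).get(
        s, config.site_params[s].reference_amplitude) for s in sites}
    steady = {s: _realized_steady(subject_params[s], steps[s],
                                  config.within_subject_dir_sd, rng)
              for s in sites}
    envs = {s: _envelope(t, onset, config.train_for(s).train_duration,
                         config.site_params[s]) for s in sites}

    force = np.zeros((n, 3))
    for s in sites:
        force += envs[s][:, None] * steady[s][None, :]

    lam = config.interaction_gain
    if (slot.condition == "co_stim" and lam != 0.0
            and config.interaction_on in ("all", slot.block_type)):
        term = interaction_term(steady[slot.site_a], steady[slot.site_b],
                                config.interaction_mode)
        env_ab = envs[slot.site_a] * envs[slot.site_b]
        force += lam * env_ab[:, None] * term[None, :]

    baseline = rng.uniform(-config.baseline_offset_range,
                           config.baseline_offset_range, size=3)
    force += baseline[None, :]
    if config.noise_sd > 0:
        force += rng.normal(0.0, config.noise_sd, size=(n, 3))

    train_dur = min(config.train_for(s).train_duration for s in sites)
    meta = {
        "subject_id": slot.subject_id,
        "block_type": slot.block_type,
        "block_id": slot.block_id,
        "slot_order": slot.slot_order,
        "condition": slot.condition,
        "site_a": slot.site_a,
        "site_b": slot.site_b,
        "amplitude_a": steps.get(slot.site_a, np.nan),
        "amplitude_b": steps.get(slot.site_b, np.nan),
        "n_pulses_a": config.train_for(slot.site_a).n_pulses,
        "n_pulses_b": config.train_for(slot.site_b).n_pulses,
    }
    return ForceTrace(t, force, onset, train_dur, baseline, meta)


# ---------------------------------------------------------------------------
# whole studies and recruitment series


@dataclass
class TrialSet:
    """A complete simulated study: config, schedule, params and traces."""

    config: GeneratorConfig
    design: StudyDesign
    subject_params: dict[int, dict[str, RealizedSite]]
    traces: list[ForceTrace]


def generate_study(config: GeneratorConfig) -> TrialSet:
    """Simulate every trial of the design, reproducibly from ``config.seed``."""
    design = make_design(config)
    params = {sid: sample_subject_params(config, sid)
              for sid in range(1, config.n_subjects + 1)}
    traces = [generate_trace(slot, params[slot.subject_id], config)
              for slot in design.slots]
    return TrialSet(config, design, params, traces)


def generate_recruitment_trials(config: GeneratorConfig, subject_id: int,
                                site_id: str,
                                amplitude_steps: Sequence[int] | None = None,
                                ) -> list[ForceTrace]:
    """One single-site trial per amplitude step, for recruitment-curve analysis."""
    if site_id not in config.site_params:
        raise ConfigurationError(f"unknown site {site_id!r}")
    params = sample_subject_params(config, subject_id)
    p = config.site_params[site_id]
    steps = list(amplitude_steps or range(1, len(p.amplitude_gain_curve) + 1))
    block_type = "spinal_muscle" if site_id.startswith("spinal") else "muscle_muscle"
    out = []
    for step in steps:
        # reuse the trial machinery with a dedicated stream per step
        slot = TrialSlot(subject_id, block_type, 1, 0, "site_A_only")
        site_slot_params = dict(params)
        trace = _recruitment_trace(slot, site_slot_params, config, site_id, step)
        out.append(trace)
    return out


def _recruitment_trace(slot: TrialSlot, params: dict[str, RealizedSite],
                       config: GeneratorConfig, site_id: str,
                       step: int) -> ForceTrace:
    rng = stream(config.seed, TAG_RECRUIT, slot.subject_id,
                 sorted(config.site_params).index(site_id), step)
    sr = config.sample_rate
    n = int(round(config.total_duration * sr))
    t = np.arange(n) / sr
    onset = config.pre_stim_duration
    steady = _realized_steady(params[site_id], step,
                              config.within_subject_dir_sd, rng)
    env = _envelope(t, onset, config.train_for(site_id).train_duration,
                    config.site_params[site_id])
    force = env[:, None] * steady[None, :]
    baseline = rng.uniform(-config.baseline_offset_range,
                           config.baseline_offset_range, size=3)
    force += baseline[None, :]
    if config.noise_sd > 0:
        force += rng.normal(0.0, config.noise_sd, size=(n, 3))
    meta = {
        "subject_id": slot.subject_id,
        "block_type": "recruitment",
        "block_id": 0,
        "slot_order": 0,
        "condition": "recruitment",
        "site_a": site_id,
        "site_b": "",
        "amplitude_a": step,
        "amplitude_b": np.nan,
        "n_pulses_a": config.train_for(site_id).n_pulses,
        "n_pulses_b": np.nan,
    }
    return ForceTrace(t, force, onset,
                      config.train_for(site_id).train_duration, baseline, meta)
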