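"""Monte-Carlo power analysis of the mixed-model error comparison.

Errors are simulated from the same generative structure the inference
module assumes: log-normal errors with per-subject random intercepts and
type slopes drawn from a bivariate normal, plus i.i.d. log-scale residuals.
An effect of ``effect`` newtons shifts the spinal/muscle log-median so that
the natural-scale median error difference between co-stimulation types
equals ``effect`` at the configured baseline median. Each replicate is
analysed with :func:`costim.inference.fit_error_model` itself — power is
the fraction of replicates rejecting at ``alpha``, with a binomial
Monte-Carlo standard error.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import TAG_POWER, stream
from .config import PowerConfig
from .exceptions import DegenerateDataError
from .inference import fit_error_model

_TYPES = ("muscle_muscle", "spinal_muscle")


def log_effect_for(config: PowerConfig) -> float:
    """Log-scale type coefficient giving a natural-scale median shift of ``effect``."""
    base = config.variance_params.baseline_median_error_N
    return float(np.log((base + config.effect) / base))


def simulate_error_table(config: PowerConfig, effect_on: bool = True,
                         rep: int = 0,
                         log_effect: float | None = None) -> pd.DataFrame:
    """One replicate error table shaped like the analysis pipeline's output.

    ``log_effect`` overrides the derived type coefficient (used for
    parameter-recovery checks); ``effect_on=False`` forces it to zero.
    Deterministic for a fixed (config.seed, rep).
    """
    vp = config.variance_params
    beta = 0.0 if not effect_on else (
        log_effect_for(config) if log_effect is None else float(log_effect))
    rng = stream(config.seed, TAG_POWER, rep)
    n, m = config.n_subjects, config.trials_per_subject_per_type
    re = rng.multivariate_normal(np.zeros(2), vp.covariance(), size=n,
                                 method="svd")  # svd tolerates singular covariances
    eps = rng.normal(0.0, vp.residual_sd_log, size=(n, 2, m)) \
        if vp.residual_sd_log > 0 else np.zeros((n, 2, m))
    base = np.log(vp.baseline_median_error_N)
    rows = []
    for i in range(n):
        for k, typ in enumerate(_TYPES):
            y = base + re[i, 0] + (beta + re[i, 1]) * k + eps[i, k]
            for j in range(m):
                rows.append({"subject_id": i + 1, "costim_type": typ,
                             "block_id": j + 1,
                             "force_prediction_error": float(np.exp(y[j]))})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PowerResult:
    power: float
    mc_se: float
    n_rejections: int
    n_nonconverged: int
    n_reps: int
    effect: float
    config: PowerConfig

    def to_dict(self) -> dict:
        import json
        return {
            "power": self.power, "mc_se": self.mc_se,
            "n_rejections": self.n_rejections,
            "n_nonconverged": self.n_nonconverged,
            "n_reps": self.n_reps, "effect": self.effect,
            "config": json.loads(self.config.model_dump_json()),
        }


def estimate_power(config: PowerConfig, effect: float | None = None) -> PowerResult:
    """Rejection rate of the mixed-model type test over ``n_reps`` replicates.

    Replicates whose mixed model fails to converge at every fallback level
    count as non-rejections and are tallied separately.
    """
    eff = config.effect if effect is None else effect
    beta = float(np.log((config.variance_params.baseline_median_error_N + eff)
                        / config.variance_params.baseline_median_error_N))
    rej = 0
    nonconv = 0
    for rep in range(config.n_reps):
        table = simulate_error_table(config, effect_on=True, rep=rep,
                                     log_effect=beta)
        try:
            res = fit_error_model(table, response="force")
        except DegenerateDataError:
            nonconv += 1
            continue
        if not res.converged:
            nonconv += 1
            continue
        p = res.fixed_effects["costim_type[spinal_muscle]"]["p"]
        if np.isfinite(p) and p < config.alpha:
            rej += 1
    power = rej / config.n_reps
    mc_se = float(np.sqrt(power * (1 - power) / config.n_reps))
    return PowerResult(power, mc_se, rej, nonconv, config.n_reps, eff, config)


def power_curve(config: PowerConfig, effects) -> list[PowerResult]:
    """Power at several effect sizes with common random numbers.

    The same per-replicate random draws are reused at every effect size
    (the effect enters additively on the log scale), so the estimated
    curve is monotone up to Monte-Carlo noise.
    """
    effects = list(effects)
    if not effects:
        raise DegenerateDataError("effects list is empty")
    return [estimate_power(config, effect=e) for e in effects]
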