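#!/usr/bin/env python
"""Calibrate the power-simulation default variance parameters.

The reference study's simulation used an unpublished covariance matrix, so
this package's defaults are chosen by this script to satisfy two published
anchors:

(a) simulated median force prediction errors land in the reported
    0.10-0.12 N range (set directly by ``baseline_median_error_N``);
(b) the design of 12 subjects with eight observations per subject per type
    is adequately powered (>= 80%, with margin against Monte-Carlo noise)
    to detect a 0.1 N median-error difference at alpha = 0.05.

It scans the per-subject type-slope SD (the variance component that
dominates the power of the between-type comparison), reports median error
and power for each candidate, and selects the largest slope SD — i.e. the
most conservative between-subject heterogeneity — whose power estimate
still clears 0.85, a working margin over the 0.80 claim.
Residual and intercept SDs are held at values representative of
trial-to-trial and between-animal spread of log errors.

Usage: python scripts/calibrate_power.py [--n-reps 400] [--seed 7]
"""
from __future__ import annotations

import argparse

import numpy as np

from costim.config import PowerConfig, VarianceParams
from costim.power import estimate_power, simulate_error_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-reps", type=int, default=400)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--target-power", type=float, default=0.85)
    args = ap.parse_args()

    chosen = None
    for slope_sd in (0.8, 0.7, 0.6, 0.5, 0.4):
        vp = VarianceParams(slope_sd_log=slope_sd)
        cfg = PowerConfig(n_reps=args.n_reps, seed=args.seed, variance_params=vp)
        big = PowerConfig(n_subjects=2000, trials_per_subject_per_type=10,
                          seed=args.seed, variance_params=vp)
        med = simulate_error_table(big, effect_on=False)[
            "force_prediction_error"].median()
        res = estimate_power(cfg)
        print(f"slope_sd_log={slope_sd:.2f}  median_error={med:.3f} N  "
              f"power={res.power:.3f} (+/- {res.mc_se:.3f})")
        if chosen is None and res.power >= args.target_power:
            chosen = (slope_sd, med, res.power)
    if chosen is None:
        print("no candidate reached the target power")
        return
    slope_sd, med, power = chosen
    print(f"\nchosen: slope_sd_log={slope_sd:.2f} "
          f"(largest between-subject heterogeneity still powered >= "
          f"{args.target_power:.2f}; median error {med:.3f} N, "
          f"power {power:.3f})")


if __name__ == "__main__":
    main()
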