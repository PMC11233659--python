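# costim

Analysis pipeline for two-site functional electrical stimulation (FES)
experiments that test **linear summation of evoked isometric forces**: when
an epidural spinal site and a muscle site (or two muscles) are stimulated
together, is the evoked 3-axis force simply the vector sum of the forces each
site evokes alone?

The package is aimed at motor-control and neuroprosthetics researchers who
record limb-endpoint forces during stimulation trains and want a tested,
reproducible implementation of the standard linearity analysis: steady-state
force extraction, within-block linear-summation predictions, error
decomposition, mixed-model inference, recruitment-curve characterization and
simulation-based power analysis. Because trial-level data from such
experiments are rarely shared, a seeded synthetic study generator with the
same design (12 subjects × 8 randomized blocks per co-stimulation type) is a
first-class part of the package.

## The analysis in brief

For each co-stimulation trial, the prediction is formed from the two
single-site trials of the same block,

    p = v_A + v_B,        v = mean force over [onset+300 ms, onset+500 ms)

after demeaning each trace by its 400 ms pre-stimulus baseline. Deviations
from linearity are quantified per trial by

* force prediction error  ‖o − p‖₂ (N),
* magnitude error         |‖o‖ − ‖p‖| (N),
* direction error         ∠(o, p) (degrees),
* normalized error        ‖o − p‖ / ‖p‖,

with o the observed co-stimulation vector. Errors are compared between
spinal/muscle and muscle/muscle co-stimulation with a linear mixed model,

    log(error) ~ costim_type + (1 + costim_type | subject),

fit by maximum likelihood, with small-sample-corrected Wald t tests
(see `docs/methods.md`). Aggregate linearity is summarized by a combined R²
about the unity line, pooled over the three force axes. Direction spread of
recruitment curves uses the circular angular deviation s = √(2(1 − R)).
Power for a given design and effect size is estimated by Monte Carlo,
analysing each simulated replicate with the same mixed model.

## Worked example

Run the full pipeline on a synthetic study with the default design:

```
costim run --out run1 --seed 1
```

which simulates 576 trials, extracts vectors, computes errors, fits the
models and prints:

```
costim study report (seed=1, config=5f2a9900dc921a17)

muscle_muscle: n=96  median error 0.076 N (7.5% of predicted)  combined R^2 0.913
spinal_muscle: n=96  median error 0.074 N (9.8% of predicted)  combined R^2 0.943

recruitment spread muscle_VL: 3.11 deg (monotone magnitudes: True)
recruitment spread spinal_L5: 10.30 deg (monotone magnitudes: True)
within-subject deviation muscle: mean 2.86 deg, max 9.90 deg
within-subject deviation spinal: mean 3.06 deg, max 8.78 deg

model force: costim_type[spinal_muscle] est -0.093, p = 0.594 (correlated_intercept_slope)
model normalized: costim_type[spinal_muscle] est +0.239, p = 0.027 (correlated_intercept_slope)
model magnitude: costim_type[spinal_muscle] est -0.017, p = 0.938 (correlated_intercept_slope)
model direction: costim_type[spinal_muscle] est +0.225, p = 0.0435 (uncorrelated_intercept_slope)
model force_with_magnitude: costim_type[spinal_muscle] est +0.282, p = 0.0227 (uncorrelated_intercept_slope)
model early_late: period[late] est -0.023, p = 0.776 (correlated_intercept_slope)
```

Reading this: both co-stimulation types are predicted to within a ~0.075 N
median error (8–10% of the predicted magnitude) and combined R² above 0.9 —
the generator's default study contains no programmed interaction, so linear
summation holds up to noise and direction jitter. Spinal recruitment curves
rotate with amplitude (direction spread ~10°) while muscle curves do not
(~3°), individual trials never stray more than ~10° from a subject's mean
vector, and the raw force-error model finds no spinal-vs-muscle difference
(p = 0.59). The `(ladder)` tag records which random-effects structure
converged. Every printed number is recomputable from the CSVs persisted in
`run1/` (`trials.csv`, `traces.csv`, `vectors.csv`, `errors.csv`,
`windowed_errors.csv`, `recruitment.csv`, `report.json`).

Stages can also be run separately (`costim simulate | extract | metrics |
infer | power`) on each other's outputs, and everything is available as
library functions (`costim.generate_study`, `costim.fit_error_model`,
`costim.estimate_power`, ...).

To detect departures from linearity, inject one:

```python
from costim import GeneratorConfig, run_pipeline
cfg = GeneratorConfig(interaction_gain=0.3, interaction_mode="gain",
                      interaction_on="spinal_muscle")
report = run_pipeline(cfg, "run_gain", seed=2)
```

makes spinal/muscle co-stimulation 30% super-additive and the force-error
model's type effect strongly significant.

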