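# Methods

`costim` re-implements, as a reusable and testable pipeline, the analysis of a
two-site functional electrical stimulation (FES) experiment: does the
isometric force evoked by *co-stimulation* of an epidural spinal site and a
muscle site (or of two muscle sites) equal the **linear summation** of the
forces each site evokes alone? Because no trial-level data from such
experiments are publicly deposited, the package ships a synthetic force-trace
generator that emulates the study design, so that every stage of the analysis
— and its statistical calibration — can be exercised end to end.

## Study design being emulated

Twelve subjects. For each subject, trials are organized in blocks of three:
site A alone, site B alone, and co-stimulation of both, in randomized order;
blocks are repeated eight times per co-stimulation type. The two types are
spinal+muscle (L5 epidural site with vastus lateralis, VL) and muscle+muscle
(VL with biceps femoris, BF), yielding 96 co-stimulation trials of each type
at the default design. Stimulation trains are biphasic: 15 ms period / 600 ms
(40 pulses) for the spinal site and 13 ms / 520 ms (40 pulses) for muscle
sites. The prediction for each co-stimulation trial is formed from the two
single-site trials *of the same block*.

## Force model (synthetic_study)

Each trial's trace on a uniform grid (default 1 kHz; all windows are given in
seconds, so the rate does not affect results) is

```
F(t) = b + Σ_site e_site(t) · v_site + λ · e_A(t) e_B(t) · I(v_A, v_B) + ε(t)
```

* `v_site` — the trial's steady force vector: the subject's site vector
  (population direction tilted by an angle ~ N(0, between_subject_dir_sd =
  10°) about a random perpendicular axis; magnitude truncated-positive normal,
  spinal 0.55 ± 0.27 N, muscle 0.70 ± 0.21 N) scaled by the recruitment gain
  at the stimulated amplitude and tilted per trial by ~ N(0,
  within_subject_dir_sd = 4°). The magnitude anchors keep forces in the
  0.5–1.8 N band of rodent stance-phase ground reaction forces.
* `e_site(t)` — an envelope that rises exponentially at stimulation onset
  (rise_tau 20 ms), carries a decaying overshoot transient for spinal sites
  (overshoot 0.5 of steady, tau 80 ms; muscle sites plateau immediately) and
  relaxes after the train ends. Only its steady-window mean is
  contract-bearing; the functional form is a modelling convenience.
* `b` — a per-trial constant baseline offset, uniform ±0.2 N per axis, so
  that baseline demeaning is exercised non-trivially.
* `ε(t)` — i.i.d. Gaussian sample noise (noise_sd = 0.02 N per axis per
  sample).
* `I` — an optional interaction term controlled by `interaction_gain` (λ,
  default 0) and `interaction_mode`: `gain` scales the total (I = v_A + v_B),
  `occlusion` removes the projection of the smaller vector onto the larger,
  `facilitation` adds force along the combined direction in proportion to the
  magnitude product (per 1 N). With λ = 0 the expected co-stimulation steady
  response is exactly additive — the null the analysis tests. Real
  neuromuscular nonlinearities (antidromic collision, synaptic integration)
  are not modelled mechanistically; these modes exist to characterize the
  pipeline's sensitivity.

Axis convention (the source experiments never publish one): x =
medial(−)/lateral(+), y = caudal(−)/rostral(+), z = ventral(−)/dorsal(+);
the sagittal plane is (y, z). Default site directions follow the anatomical
descriptions of the evoked forces (VL lateral/caudal/ventral; BF
caudal/dorsal; spinal medial/caudal with its amplitude-dependent rotation in
the sagittal plane).

Randomness: one top-level seed; every subject, trial and replicate draws from
a `SeedSequence([seed, stream_tag, *keys])` stream, so adding subjects or
blocks never perturbs existing draws, and studies are reproducible to the
byte.

The main study stimulates every site at its reference amplitude (recruitment
gain 1), so subject magnitudes are produced unchanged and the calibration
anchors above hold by construction; amplitude selection
(`select_amplitude`, smallest in-band amplitude by default, mid-band
optional) operates on recruitment curves and raises an error, listing the
achieved magnitudes, when no amplitude reaches the band.

### What the generator does not emulate

Fused-tetanus ripple at the stimulation frequency, slow drift and fatigue,
amplitude-dependent noise, EMG, and any biophysically grounded co-stimulation
interaction. Passing tests therefore show that the *analysis* is correct and
calibrated for data with this covariance structure, not that real spinal and
muscle responses sum linearly.

## Extraction (force_extraction)

Traces are demeaned by subtracting the per-axis mean over the 400 ms
immediately before stimulation onset. The steady-state vector is the per-axis
mean over [onset + 300 ms, onset + 500 ms); windowed vectors are means over
consecutive 50 ms bins spanning the train. All windows are half-open [a, b)
on the sample grid so no sample is double-counted; times map to the nearest
sample with ties toward zero (error ≤ half a sample). For co-stimulation
trials whose two trains differ in length (600 vs 520 ms), onsets are taken as
simultaneous and windowed analysis runs over the shorter train, so every
window lies inside both trains. The early/late comparison aggregates the
per-window errors (not re-averaged raw force) within 100–300 ms and
300–500 ms.

## Error metrics (vector_metrics)

For predicted p = v_A + v_B and observed o: force prediction error ‖o − p‖;
magnitude error |‖o‖ − ‖p‖|; direction error = full 3-D angle between p and o
(sagittal-plane angles are a separate, explicit call); normalized error =
‖o − p‖ / ‖p‖. Zero-magnitude inputs raise `UndefinedDirectionError` rather
than returning 0°, so degenerate trials cannot silently contaminate circular
summaries. Within-subject angular deviation uses the arithmetic componentwise
mean vector (the joint magnitude-and-direction average), and direction spread
of recruitment curves uses the circular angular deviation s = sqrt(2(1 − R))
(R = mean resultant length); the circular SD sqrt(−2 ln R) is provided as an
alternative (`angular_sd`). The combined R² pools squared residuals about the
unity line (perfect prediction, not a fitted regression) over the three axes
and divides by the summed per-axis total sums of squares about each axis's
observed mean.

## Inference

Trials within a subject are correlated, so errors are compared between
co-stimulation types with linear mixed models: log(error) ~ type, per-subject
random intercept and random type slope, allowed to correlate, fit by maximum
likelihood (not REML; the fit method is recorded and test-pinned). The log
transform means a common rescaling of all errors moves only the intercept —
an exact, tested property. Direction errors can be exactly 0°, so that model
(only) adds a documented ε = 0.01° before the log; the offset is reported in
the result. The natural log is used; the base cannot affect inference.

Random intercept+slope structures frequently fail to converge at a dozen
subjects. Fitting walks a fallback ladder — (1) correlated intercept+slope,
(2) uncorrelated (cov_re constrained diagonal), (3) intercept only — and the
level used is recorded in every result; when the full model converges the
ladder never alters results.

**Small-sample testing.** Fixed effects are tested with Wald statistics. A
plain Wald z is anticonservative at these group counts (empirical type-I
≈ 0.09 at 12 subjects). The default (`df_method="between_subject"`) instead
(i) inflates the ML standard error by sqrt(n/(n−1)) — undoing the familiar
ML-vs-REML variance bias in a balanced design — and (ii) refers the statistic
to t with n − 1 degrees of freedom, the paired-contrast analogue for a
within-subject comparison across n subjects. On null simulations from the
shipped generative model this procedure is calibrated to the nominal level
(empirical type-I 0.050 at 12 subjects, 2000 replicates). The exactly
appropriate df would track the variance composition (Satterthwaite /
Kenward–Roger, not available for `MixedLM`); the fixed convention is
calibrated at the shipped defaults and documented here. Welch's
unequal-variance t test (Satterthwaite df) serves the independent-sample
comparisons (recruitment direction spreads; within-subject angular
deviations).

## Power simulation

Sample-size logic is reproduced by Monte Carlo, not formulas: errors are
simulated from the same generative structure the mixed model assumes —
log-normal errors, per-subject (intercept, slope) bivariate normal, i.i.d.
log-scale residuals — and each replicate is analysed by `fit_error_model`
itself, fallback ladder included (replicates failing every ladder level count
as non-rejections and are tallied). An effect of E newtons shifts the
spinal/muscle log-median by log((baseline + E)/baseline), i.e. the effect is
a natural-scale *median* difference (the generating covariance and the
mean-vs-median reading of "0.1 N difference" are not published; this choice
is flagged). `power_curve` reuses the same per-replicate draws across effect
sizes (common random numbers), so estimated curves are monotone up to
Monte-Carlo noise.

The source study's simulation covariance matrix is unpublished — the largest
gap this package fills with its own defaults. They are chosen by the shipped
`scripts/calibrate_power.py` against two published anchors: (a) the baseline
median error is ~0.10 N, matching the reported medians (0.10–0.12 N), and
(b) the design of 12 subjects × 8 observations per type is adequately
powered (≥ 80%, with a working margin: the script takes the largest
between-subject slope SD still reaching 85%) to detect a 0.1 N difference at
α = 0.05. The chosen values: intercept SD 0.6, type-slope SD 0.6,
intercept–slope correlation 0.2, residual SD 0.5 (all log-scale), baseline
median 0.10 N. Under these defaults the estimated power at the study design
is ~0.92 and the empirical type-I rate ~0.05.

## Numerical choices and degenerate inputs

* Pulse counts use a tolerance-guarded floor (floor(duration/period + 1e-9))
  so 520 ms / 13 ms counts as exactly 40.
* arccos arguments are clipped to [−1, 1]; near-parallel vectors give 0°,
  never NaN. Angle computations lose ~sqrt(machine-eps) precision near 0°.
* Interchange CSVs are written with 17 significant digits and read with
  round-trip float parsing, so write→read reproduces traces bit-exactly.
* Monotonicity of recruitment magnitudes is judged with a tolerance of 1% of
  the curve's maximum magnitude, absorbing sample noise.
* Reports contain no timestamps or host information; a rerun with the same
  config and seed is byte-identical.

## Test-suite problem sizes

The suite exercises the full design where the check depends on it (12 × 8
studies for additivity, calibration anchors and deviations; 2000-replicate
null and 1000-replicate power simulations; 100-replicate parameter-recovery
runs at 24 subjects × 16 trials) and reduced seeded designs for supporting
property checks (e.g. 20 replicate studies at 6 subjects × 4 blocks for
injected-nonlinearity detection, 50–60 replicates for early/late
calibration), sizes chosen to keep the default run fast while leaving the
Monte-Carlo standard errors well inside the asserted margins.

## Known limitations

* The package quantifies deviation from linearity only; it fits no
  alternative (nonlinear) summation model, and argues the null the same way
  the source analysis does — by non-significance, without equivalence
  testing (TOST).
* A ±2·SE recovery check whose statistic is t-distributed with ~23 df has an
  intrinsic coverage ceiling near 94%, so replicate-count thresholds close
  to that ceiling are sensitive to the Monte-Carlo seed even when the
  estimator and SE are calibrated.
* The within-subject direction jitter SD is shared across sites, so the
  generator does not reproduce the reported spinal-vs-muscle difference in
  within-subject variability (only recruitment-curve direction spread
  distinguishes the sites); the pipeline still computes and reports that
  Welch comparison.
* Single-site generator parameters are phenomenological; none of the
  defaults should be read as physiological measurements beyond the anchors
  cited above.
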