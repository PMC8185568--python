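# Methods

This note documents the models, parameter choices and numerical
conventions behind `wristfog`, and what the synthetic experiments do and
do not demonstrate.

## Problem setting

Freezing of gait (FoG) is detected window-by-window from one wrist IMU:
6 channels (ax, ay, az in g; gx, gy, gz in deg/s) at `fs = 128 Hz`,
classified into FOG / STOP / WALK (walking-with-turns). The label order
(FOG, STOP, WALK) is fixed everywhere — probability vectors, confusion
matrices, serialized checkpoints — and argmax ties break toward the
earlier label.

## Preprocessing and labeling

* **Normalization** divides each channel by its maximum *absolute* value
  over all cohort recordings, then rounds half-to-even to 4 decimals.
  Max-abs (not plain max) is required because the signals are signed;
  half-to-even makes the rounding platform-reproducible. Units are
  metadata only — normalization removes scale, so no unit conversion is
  ever performed.
* **Windowing**: `Wl = 3 s` windows advanced by a `Sl = 0.25 s` step
  (384 and 32 samples), `K = ⌊(N − 384)/32⌋ + 1` windows. The 0.25 s
  step is what yields one decision per 0.25 s in streaming mode.
* **Labeling** operates on half-open intervals `[start, end)`. A window
  is FOG if (a) any episode is entirely contained in it — this catches
  the very short episodes that make up roughly half of real ones — or
  (b) its total in-window FoG time is ≥ `Wl/2` = 1.5 s. Overlaps of
  multiple episodes are summed before the test: the rule concerns the
  FoG content of the window. An alternative reading — comparing the
  episode's *own* duration to `Wl/2` — is implemented behind
  `WindowConfig(fog_rule="episode_duration")`; it was not made the
  default because it labels windows that barely graze a long episode as
  FOG. Non-FoG windows take the class with the larger overlap; ties go
  to WALK. Boundary windows mixing STOP and WALK are kept (majority
  label), not dropped.

## The CNN

Architecture (defaults): two 1D convolution stages, valid padding,
stride 1, ReLU, kernel 10, with 100 then 40 filters; max-pool of 3 after
stage one, average-pool of 2 after stage two; flatten; dropout 0.5;
dense softmax with 3 outputs. Stage lengths at the default geometry:
384 → 375 → 125 → 116 → 58 → 2320 → 3 (~53k parameters). ReLU,
valid padding and pool-stride = pool-size are conventional choices for
this architecture class; a global-average-pooling variant (one value per
feature detector before the head) is available via
`ModelConfig(global_avg_pool=True)` for the reading of "one weight per
feature detector", but local pooling + flatten is the default because it
is the geometry the stage arithmetic supports.

Training: Adam (lr 1e-3, β₁ 0.9, β₂ 0.999), batch 64, cross-entropy,
up to 200 epochs with early stopping on a 10 % validation split
(patience 5, best-epoch weights restored). Optional inverse-frequency
class weights exist behind `TrainConfig(class_weights=True)` but are off
by default. One seeded `numpy` generator drives initialization (He for
conv, Glorot for the head), the validation split, batch order and
dropout masks, so a (data, config, seed) triple reproduces the fitted
model bit-for-bit. The forward/backward passes are plain numpy (im2col
lowering convolutions to BLAS matmuls, float32); at this parameter count
an epoch on ~1,400 windows takes about 1.5 s on one CPU core.

Hyperparameter search samples depth ∈ {2,3,4,5}, kernel ∈ [3,12],
filters ∈ [10,100] (seeded random draws or an explicit candidate list)
and selects by inner-validation loss; test folds are never touched
during the search.

## Features and baselines

The feature vector approximates the classical wrist-FoG set: per
channel — mean, SD, variance, min, max, RMS, energy, spectral entropy,
dominant frequency, locomotor-band power (0.5–3 Hz), freeze-band power
(3–8 Hz) and the freeze index (freeze/locomotor power ratio) — plus the
spectral block on the acceleration- and angular-rate-magnitude signals
(82 features). Spectra come from a single rectangular-window periodogram
of the mean-removed 384-sample window, the simplest reproducible
estimator at this length. Band powers integrate the PSD between exact
band edges (trapezoid with interpolated endpoints) so that a flat
spectrum gives band power ∝ bandwidth; a zero-variance channel defines
its spectral features as 0 (logged). Band edges follow the standard FoG
literature and are configurable.

Baselines: scikit-learn's decision tree and XGBoost with library-default
hyperparameters (logged at fit time), wrapped to expose the same
3-class predict interface as the CNN.

## Evaluation

LOSO CV is the primary protocol: one fold per subject, training on all
other subjects. Shuffled k-fold (default k = 10) is provided for
comparison; it shuffles at *window* level, so overlapping windows leak
across folds — an inherent property of that protocol, which is why a
subject-stratified variant exists behind a flag. Aggregates are reported
both from the pooled confusion matrix and as unweighted fold means;
undefined metrics (zero denominators, e.g. a held-out subject with no
FoG windows) are reported as missing, never coerced to 0.

## Synthetic cohorts

The generator produces the data the pipeline is tested on, with defaults
chosen as the study conditions:

* **Episode durations**: lognormal(μ = 1.0699, σ = 1.4302) truncated to
  [0.11, 98.8] s by rejection. μ, σ solve
  Φ((ln 3 − μ)/σ) = 0.508 and Φ((ln 5 − μ)/σ) = 0.647, i.e. the law is
  quantile-matched to the published percentiles (50.8 % < 3 s,
  64.7 % < 5 s). A two-parameter fit cannot also match the published
  mean/SD (9.12 ± 15.35 s) exactly — the truncated law's mean is ≈ 7 s —
  so mean and SD are documented as approximate, not targets. Truncation
  shifts the < 3 s mass by ≈ 0.2 pp, within sampling error at n = 10⁵.
* **Sessions** (default 600 s × 11 subjects): alternating WALK
  (25–50 s) and STOP (5–15 s) blocks; FoG episodes arrive as a Poisson
  stream (nominal 3.8/min) thinned to fit disjointly inside WALK blocks
  with a 2 s buffer. The nominal rate was set once so that the realized
  post-thinning cohort total is ≈ 184 episodes in expectation at the
  defaults, matching the published cohort's episode count; an
  infeasible rate (episodes cannot be placed disjointly) raises an
  error up front.
* **Signals**: WALK = gravity offset + arm-swing fundamental at the
  subject's gait frequency (~N(1.0, 0.1²) Hz) with a second harmonic,
  gyroscope swing, periodic yaw turn bursts, white noise. FOG = the
  swing attenuated to 25 % plus a trembling tone (centre ~U(4, 7) Hz)
  and freeze-band-limited noise, so in-episode windows have freeze
  index > 1 while walking windows sit ≪ 1. STOP = gravity + noise floor.
  Per-subject axis-weight, amplitude and frequency jitter give LOSO
  folds genuine subject idiosyncrasy. All class-distinguishing
  components are scaled by γ; at γ = 0 the three classes reduce to the
  identical gravity + noise process.

**What this does not show.** The generator is a stylized harness, not a
biomechanics simulation: real wrist FoG signatures vary across patients
far more than a tone-plus-band-noise model, annotation boundaries are
uncertain in real data, and the published clinical detection scores are
properties of a specific on-request dataset. Passing the synthetic
end-to-end tests demonstrates that the pipeline is implemented
correctly and can learn a separable spectral contrast under the LOSO
protocol — not that comparable accuracy would be reached on clinical
recordings.

## Problem sizes in the test suite

The classifier acceptance tests run on a reduced cohort — 4 subjects,
120 s sessions (≈ 1,900 windows) — which preserves the LOSO structure
and class mix while keeping a full run to a few minutes on one core;
the generator-calibration checks use the full 100,000-draw sample, and
cohort-statistics tests use the full 11 × 600 s defaults (generation is
cheap; only classifier training is not). Training in those tests uses
the library-default budget (200 epochs, patience 5).

## Numerical conventions and edge cases

* Rounding is half-to-even at 4 decimals everywhere a file is written.
* Interval arithmetic is half-open; window spans are sample-aligned, so
  grid-aligned annotations incur no floating-point ambiguity.
* An all-zero channel across a cohort is an error (its normalization
  scale is undefined), as are overlapping or zero-length annotation
  intervals, single-class training sets, and model geometries whose
  feature length collapses below 1 (reported with the offending stage).
* A recording's time column, when present, is validated (median spacing
  within 1 % of 1/fs) but never used for indexing; the sample index is
  authoritative.

## Known limitations

* The CNN engine is CPU-only numpy; it is sized for this problem class
  (~10⁵ windows, ~10⁵ parameters), not for GPU-scale work.
* 10-fold CV numbers on overlapping windows are optimistic by
  construction; use LOSO (or the stratified k-fold flag) for honest
  generalization estimates.
* The feature set is a canonical approximation of the wrist-FoG
  literature's, not a reproduction of any specific published list.
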