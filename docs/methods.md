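# Methods

This note documents the models, the parameter choices that matter, the
numerical conventions, and what the synthetic test bed does and does not
establish about real data.

## Windowed Granger causality

**Model.** For an ordered pair (source, target), a window of `k` volumes
starting at volume `t`, and an autoregressive specification
(`order_p` lags, linear or polynomial basis, `train_span` training
samples), two one-step-ahead predictors of the target are fitted by
ordinary least squares on the `train_span` samples ending at `t − 1`:
the restricted predictor uses the target's own last `p` (basis-expanded)
values plus an intercept, the full predictor additionally the source's
last `p` values. Both then forecast the `k` window samples from the
actually observed lags, and `F = L1 / max(L2, eps)` compares their window
mean squared errors. Values at or above a threshold ω are kept, values
below are zeroed.

**Why out-of-sample.** Coefficients are estimated strictly before the
window and errors measured strictly inside it. This keeps the window error
an honest forecast error (no leakage), makes `F ≈ 1` the null behaviour
for independent series, and is what lets short-window values track
*time-varying* coupling: a window in which the source genuinely helped
shows `F > 1` even though the coefficients were learned earlier. The full
model nests the restricted one, so `E[L2] ≤ E[L1]` holds in expectation;
on any single out-of-sample window either ordering can occur. An
`in_sample` mode (fit on the window itself) exists for oracle tests,
where `L2 ≤ L1` holds deterministically.

**Standardisation.** Both series are z-scored with the training span's
mean and standard deviation before fitting, making MSEs — and hence F —
invariant to per-ROI offset and common rescaling, and comparable across
ROIs with different BOLD baselines. A zero-variance training span falls
back to unit scale (a constant target is then predicted exactly).

**Nonlinearity.** "Nonlinear autoregression" is realised as polynomial
expansion of each lagged value (powers 1..degree, no cross terms). The
linear basis is the default; the polynomial basis is a first-class option.

**Defaults and units.** `k = 4` volumes (the window length at which the
causal sequence tracks a 10 s block design at TR = 2 s), `p = 1`,
`train_span = 40` volumes, stride 1, `eps = 1e−12`. `train_span` must be
at least twice the full model's term count. A window whose full-model MSE
underruns `eps` (noise-free coupling) is reported at the cap and flagged
`saturated` rather than dropped.

**Degenerate designs.** Rank-deficient least-squares designs (constant
series, all-zero source) are refitted with a ridge penalty of `1e−8` and
logged; with an all-zero source the full predictor then equals the
restricted one to ~1e−9, so `F = 1` as it should.

**Threshold calibration.** ω is the empirical `1 − α` quantile of F
evaluated on surrogates in which the source series is circularly shifted
by a seeded random offset (drawn at least `k + p` samples away from zero
shift, modulo the series length). Circular shifting destroys source →
target cross-lag structure while preserving both autocorrelation
functions, so the quantile is a per-pair null level. Defaults: α = 0.05,
500 surrogates (at least 100 enforced), each surrogate evaluated on a
seeded random subsample of 20 admissible windows — a pool of ≥ 10 000 null
F values, which stabilises the tail quantile at a fraction of the cost of
sweeping every window for every surrogate. Per-pair thresholds are the
default; a pooled global threshold is an option. Measured null
false-positive rates fall in 3–7 % across seeds at the 5 % nominal level —
marginally conservative, because the surrogate pool reuses one finite
target series.

## Synthetic study conditions

**Latent dynamics.** Node signals follow a first-order vector
autoregression whose cross-coupling matrix switches with the experimental
condition; per-condition systems must have spectral radius < 1 (checked
before simulating). Three independent knobs modulate a condition:
directed coupling (`coupling_schedule`), mean drive
(`amplitude_schedule`), and per-node innovation SDs
(`noise_sd_schedule`). The third exists because coupling feeds the
source's variance into the target: switching coupling alone also raises
the target's marginal variance, an amplitude-like cue. For experiments
meant to modulate *connectivity only*, `matched_noise_schedule` solves the
per-condition discrete Lyapunov equations for diagonal innovation
variances that hold every node's stationary variance at its rest-state
value.

**Hemodynamics.** Latent signals are convolved with a causal double-gamma
kernel (response gamma peaking at 5 s, undershoot at 15 s, ratio 1/6),
truncated at 30 s and normalised to unit sum. Its first sample at TR = 2 s
is ~0: a volume contains essentially no same-volume latent activity, which
is the physical origin of the decoding latency the DA curves measure.

**Observation.** ROI spheres are painted into a centred RAS+ grid (2 mm
isotropic voxels by default) over a baseline of 100, with i.i.d. Gaussian
voxel noise; overlapping spheres and spheres leaving the grid are
rejected. Voxel membership is by voxel-centre distance (closed ball).
What the generator does *not* emulate: scanner drift, spikes, motion,
physiological noise, spatial correlation of noise, multi-subject
variability. Passing tests therefore show that the estimator recovers the
causal structure its model class describes under hemodynamic observation —
not that it is robust to real scanner artefacts.

**Screening rules.** The first 10 volumes of a run are discarded
(pre-steady-state magnetisation) and, when building training baselines,
the first 4 volumes of each constant-condition block are trimmed
(hemodynamic transition). Both are configurable. The rest baseline of the
ACTIVE feature is the mean over transition-trimmed rest volumes; in
streaming mode it freezes after the first completed rest block (mirroring
a pre-task baseline), configurable to rolling. The "resting" reference of
ACTIVE is the same ROI's rest-period mean, not a dedicated rest region.

## Classification and evaluation

Feature rows are indexed by window start; the row's label is the condition
at the start volume, so a task block of 5 volumes contributes 5 rows whose
windows extend into the block (and, for late positions, past its end).
Cross-validation folds are grouped by block — all samples of one maximal
constant-label run share a fold, dealt round-robin within each class —
so temporally adjacent, HRF-correlated volumes never straddle the
train/test split; K defaults to 5. Features are standardised with
training-fold statistics only. Cohen's κ is computed from the pooled
confusion matrix with the chance-corrected formula; a degenerate
one-cell matrix returns 0 with a warning. The classifier grid mirrors the
standard suite: Gaussian naive Bayes; polynomial-kernel SVM (exponent 1);
RBF SVM with C = 19 and `gamma="scale"`; LightGBM (depth 5, learning rate
0.8, 1000 trees) and XGBoost (depth 8, learning rate 0.08, 1000 trees) as
optional extras.

The DA curve reports, for each within-block position m (1..5 at 10 s
blocks, TR 2 s), the fraction of task blocks whose m-th volume was
classified correctly, using held-out predictions; only fully covered
blocks contribute.

## The connectivity-versus-activation experiment

The comparison that contrasts DWGC features with activation-only features
uses study conditions chosen for identifiability:

* two directed pairs carry a *tonic* rest coupling (0.4) whose gain each
  imagery condition modulates — the own pair up to 0.8, the other pair to
  0. Task networks modulating standing connectivity is the
  neurophysiologically standard picture, and it keeps the training-span
  coefficient estimates relevant inside every window, so window F moves
  *up* on the potentiated pair and *down* on the silenced one;
* innovation variances are Lyapunov-matched across conditions, so
  amplitude and variance carry no class information;
* one session of 8 runs (24 task blocks each) is pooled; the paired
  comparison is 20 repeated block-grouped 5-fold cross-validations of
  both feature sets on identical folds, with a paired t-test, and DA
  curves come from pooled-fit held-out predictions.

Under the alternative design in which task creates coupling from zero and
rest has none, the two feature sets tie at desk scale: the window-level F
carries only a small per-window signal (the training span sees any one
condition in ~1/12 of its volumes), while coupling-induced instantaneous
correlation leaks class information into multivariate activation
features. The gain-modulation design isolates the effect the comparison
is about.

## Real-time replay

The replay loop consumes volumes in acquisition order (NIfTI file, 4D
array, or any iterator of 3D volumes), extracts ROI means, updates the
frozen baseline, computes the newest complete window for every ordered
pair and classifies, logging per-stage wall-clock seconds. Decisions
depend only on volumes already seen; the emitted features and labels are
bit-identical to the batch pipeline (the batch extractor deliberately
reduces voxels per volume in the same order as the stream). Per-volume
latency is logged for information only — it is hardware-dependent and not
a correctness property. A failing volume source ends the run with a
partial decision log and a warning.

## Problem sizes

Test and acceptance computations use desk-scale sizes chosen as the
package's own study conditions: direction recovery over 50 (tests) / 30
(script) replicates of 600-volume runs; null calibration from 500
surrogates against 1000 fresh null windows; oracle-agreement checks on
10 / 6 four-node datasets of 1200 volumes; the feature comparison on one
pooled 8-run session (~1100 task rows); rendering round trips on 24³
grids. The full suite runs in about a minute on one CPU; the acceptance
script in well under a minute.

## Known limitations

* Pairwise (bivariate) GC only: a strong i → j coupling inflates the
  reverse window F above its null through the smoothing observation
  process; thresholds are calibrated per direction but do not partial out
  third nodes (no conditional/multivariate GC, no spectral GC).
* The MSE-ratio F on k = 4 out-of-sample points is intrinsically noisy
  (coefficient-of-variation near 1 under the null); single-window values
  are features for a classifier, not test statistics.
* ROI coordinates are taken at face value in the image's affine frame;
  no registration, atlas lookup, or activation mapping is provided.
* The window-count convention (first start at `train_span + p`, last start
  `T − k`, 0-based) is fixed by enumeration tests; streaming and batch
  share it exactly.
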