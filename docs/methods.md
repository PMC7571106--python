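# Methods

## Problem setting

The package classifies short windows of wrist-worn IMU signals as normal or
abnormal (impaired) walking, a proxy for fall-risk screening. The positive
class throughout is *abnormal gait*: sensitivity is the rate at which
impaired walking is detected, and a missed detection is treated as the
costly error (trial-level ties are broken toward abnormal for the same
reason; the tie-break is configurable).

## Synthetic gait simulator

Real wrist IMU recordings of normal and impaired walking are not publicly
available at the scale the pipeline needs, so `wristgait.synthetic_gait`
generates a cohort with the statistical structure the classifier relies on.
The signal model is harmonic-plus-noise driven by an explicit stride clock:

- Each subject carries random effects: base stride frequency
  (uniform 0.8–1.2 Hz; one stride = two steps), arm-swing acceleration
  amplitude (1.2–2.5 m/s²), per-channel phase offsets, a noise scale, and
  handedness. Stride intervals are drawn per stride as
  `N(1/f, cv/f)` (truncated at 0.3 of the mean), and the instantaneous
  phase is piecewise linear between stride boundaries, so stride-time
  variability is realized as genuine cycle-length jitter, not additive
  noise.
- Accelerometer axes carry a quasi-static gravity projection (device frame:
  x across the face, y along the forearm, z face normal; gravity loads
  mainly on y) plus three phase-locked harmonics of the stride frequency
  and white noise. The gyroscope carries angular-rate harmonics scaled from
  the swing amplitude; the magnetometer sees a heading field with a smooth
  180° mid-trial turn (the walker returns along the path) and a small
  stride ripple; the rotation-vector channels are slow orientation drifts
  with a small stride component.
- The abnormal condition applies four effects with these defaults: stride
  frequency reduced by 15 %, swing amplitude reduced by 40 %, stride-time
  coefficient of variation raised from 0.02 to 0.10, and stumble-like
  perturbation bursts at 0.2 events/s (Gaussian-windowed oscillatory
  transients on the accelerometer and gyroscope). The values sit in the
  range reported for impaired versus healthy gait: slower cadence, weaker
  and more irregular arm swing, and a several-fold rise in stride-time
  variability. Setting all effects to zero makes the two labels
  exchangeable, which the tests verify with a label-permutation test.
- Trials are parameterized by duration rather than distance; a 15 m
  out-and-back walk at ordinary speeds corresponds to roughly 20–40 s, the
  simulator default. Every session is seeded from the dataset seed plus its
  (subject, wrist, condition, trial) coordinates, so datasets are
  byte-identical given a configuration.

What the simulator deliberately does not model: biomechanically validated
limb dynamics, pathology-specific gait signatures, sensor calibration
errors, gyroscope drift, or non-walking hand activity. Passing tests
therefore demonstrate that the pipeline and architectures behave correctly
and can learn class structure of the kind the application assumes — not
clinical performance on real patients.

## Preprocessing

The chain is: decimate 100 Hz → 50 Hz (anti-alias low-pass via
`scipy.signal.decimate`, zero-phase) → order-10 Butterworth band-pass
0.5–3.5 Hz → rotation augmentation (training data only) → per-channel
z-scoring → 8 s windows with 2 s overlap between consecutive windows
(hop = 6 s), trailing remainder discarded.

Numerical conventions worth stating:

- "Order 10" is the order of the band-pass transfer function (lowpass
  prototype order 5). The filter is designed in second-order sections and
  applied forward–backward (`sosfiltfilt`), so the effective magnitude
  response is the squared single-pass response and the phase is zero; the
  single-pass response matches the analytic Butterworth form with
  bilinear-prewarped frequencies to machine precision.
- The augmentation is the fixed rotation diag(−1, −1, 1) applied to every
  3-axis sensor triplet — a 180° turn about the face normal, emulating the
  watch strapped the other way round. It is an exact involution and is
  applied to the rotation-vector components with the same vector map, an
  approximation of the proper orientation conjugation (the simulator's
  rotation channels are synthesized as vector components, so the
  approximation is self-consistent here).
- The scaler uses population (1/N) standard deviations and is fitted per
  LOSO training fold — on the training sessions plus their rotated copies,
  matching the order augment → scale — never on test data. A zero-variance
  channel raises an error rather than silently propagating NaNs.
- Windows inherit the label, subject, wrist and trial identity of their
  source session; augmented windows are flagged so they can never enter a
  test set.

## Architectures

Each selected sensor axis ("per-axis" mode, the default: the 12 signals are
12 channels; a per-sensor grouping is available) feeds an identical branch:
Conv1D(10 filters, width 5, same padding) + BatchNorm + ReLU, twice; max
pool (4); flatten — in parallel with BiLSTM(20, sequences) → BiLSTM(10,
final states) → dropout. Branch outputs are fused per signal in a dense
layer (32 units), then across signals in a shared dense layer (64) and a
2-way softmax. The data-level variant runs one branch pair over the
multivariate window; the decision-level variant concatenates branch outputs
directly into the output layer; the ablations keep a single path per branch
and drop the per-signal fusion dense.

Hyperparameters the architecture description leaves open were fixed once
and are configurable: pool size 4, dropout 0.5, per-signal dense 32, shared
dense 64, Glorot-uniform initialization, forget-gate bias 1, early stopping
on a 10 % subject-stratified validation split (patience 5 by default,
monitoring validation loss, best weights restored). "Binary cross-entropy"
with a 2-unit softmax is implemented as 2-class categorical cross-entropy,
which is identical for one-hot binary labels.

The engine (`wristgait._nn`) is NumPy with hand-derived backward passes.
All parallel branches are stacked on a leading axis so each layer is a
batched BLAS call; the BiLSTM folds its two directions into that stack,
hoists per-timestep input projections out of the recurrence, and keeps a
batch-last memory layout so per-step slices are contiguous. Large
intermediates live in reused buffer pools. Gradients of every layer and of
the assembled network are verified against central finite differences in
float64. One integer seed drives weight initialization, shuffling, dropout
and the validation split; runs are bit-reproducible on a fixed BLAS.

## Evaluation

Leave-one-subject-out: one fold per subject, the scaler and model fitted
only on the remaining subjects, augmentation applied to training data only.
Pooled (micro-averaged) confusion counts are the headline metrics;
per-fold metrics are also reported. Accuracy, sensitivity and specificity
follow the standard binary definitions with abnormal as positive. Metrics
with empty denominators raise rather than returning 0. The wrist policy
selects training and test wrists independently (left/right/both), enabling
the six train-test wrist-transfer combinations.

The threshold analysis reclassifies stored probabilities: a window is
called normal only when its normal-class probability strictly exceeds the
threshold (0.5–0.9), so raising the threshold can only grow the abnormal
set — window-level sensitivity is non-decreasing and specificity
non-increasing by construction. Trial labels are the majority vote of the
trial's windows.

McNemar's paired test compares classifiers on identical instances: with
discordant counts b and c, the statistic is the continuity-corrected
(|b−c|−1)²/(b+c); the p-value uses the exact two-sided binomial(b+c, ½)
tail for b + c < 25 and the χ²(1) tail otherwise, with p = 1 when b = c.
The implementation is cross-checked against an independent exact-binomial
oracle and against `statsmodels` in the tests. Significance is read at
α = 0.05.

## Study configurations and problem sizes

`wristgait.experiments` pins the two stock studies. Both keep the full
design — two wrists, five normal and five impaired trials per subject,
100 Hz simulation, the complete preprocessing chain, the standard training
recipe (Adam 0.001, batch 256, early stopping) — and shrink what a single
CPU core can afford: the accuracy benchmark uses 5 subjects, 16–20 s
trials and an epoch cap of 6; the architecture-ablation comparison uses 4
subjects and fixed-length training (no early stopping: at that cohort
size the validation split is a handful of windows and best-epoch
selection on it is noise), repeated over seeds, since it is a relative
comparison. Larger cohorts, longer trials and the full 30-epoch cap are a
configuration change, not a code change.

## Known limitations

- The simulator's class separation is controllable and, with the default
  impairment effects, intentionally strong; absolute accuracies on it say
  nothing about real patients.
- The NumPy engine trains small networks adequately but has no GPU path
  and no graph-level optimizations; wall-clock cost grows linearly with
  window length and cohort size.
- The 396-feature catalog used by some classical pipelines is not fully
  enumerable from its description; the baseline set implements the 14
  named statistics per signal, with a hook for extensions.
- Bit-reproducibility holds for a fixed BLAS/threading configuration;
  across BLAS builds, results agree only to floating-point tolerance.
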