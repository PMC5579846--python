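# Methods

This note records the scientific and numerical choices behind `oitkit`:
what each stage computes, which conventions were pinned where more than
one reasonable choice existed, what the synthetic benchmark does and
does not emulate, and the known limitations.

## Transforms

### Heuristic orientation-invariant transform

The transform maps a 3×L segment to nine channels: the per-sample norms
of the signal and its first and second differences, the angles between
consecutive samples of each of those three sequences, and the angles
between consecutive cross-product rotation axes of each sequence.
Invariance to a fixed proper rotation is exact: rotations preserve norms
and pairwise angles, and cross products of co-rotated vectors co-rotate.

Pinned conventions:

* **Common valid length L′ = L − 4.** The deepest stencil is the ninth
  channel, whose sample n needs v[n..n+4]. All nine channels are
  truncated to the same index range so the output is rectangular, which
  downstream feature extraction requires. (Counting endpoints, the
  stencil spans five consecutive samples, i.e. four sampling periods.)
* **Zero-vector angles are 0.** The angle between vectors is
  `arccos` of the normalized inner product; it is undefined when either
  operand is the zero vector and is set to 0 there. The convention is
  applied uniformly to all six angle channels.
* **Clipping.** The arccos argument is clipped to [−1, 1]; round-off
  can push it past the domain by ~1e−16, and clipping guarantees finite
  output on any finite input.
* **Unnormalized rotation axes.** The cross products p, q, r enter only
  through angles, so they are deliberately not normalized; this avoids a
  0/0 at near-parallel consecutive samples.
* Differences beyond second order are not offered: the two highest
  channels are already the noisiest in practice, and deeper stencils
  would shrink L′ further.

Only pre-multiplication by a rotation (`V → RV`) is meaningful for
column-vector data and only that case is implemented and tested.

### SVD-based orientation-invariant transform

Each segment's (scaled, concatenated) 3×SL matrix `V̄` is factored by a
compact SVD `V̄ = U Σ Wᵀ`; the output is `Σ Wᵀ = Uᵀ V̄`, the data in its
own principal axes, split back per sensor. Choices:

* **Per-sensor-type scaling.** Before concatenation each sensor type is
  divided by its pooled standard deviation over a reference corpus (all
  axes, units and recordings of that type), so that a sensor measured in
  large numerical units cannot dominate the joint decomposition. In
  cross-validation the scales are fitted on the training folds by
  default; an `all_data` mode reproduces the pooled convention (which
  leaks test statistics and is flagged as such). The output stays in the
  scaled units — features are min-max normalized later anyway.
* **Sign canonicalization.** An SVD determines the rows of `Σ Wᵀ` only
  up to sign. Each output row is flipped so that its entry of largest
  absolute value (earliest column on exact ties) is positive. This makes
  the transform a deterministic function, which moment features (mean,
  skewness) require; without it, two runs could legitimately return
  opposite-sign rows. Ties occur only on a measure-zero set.
* **Degeneracy.** A numerically rank-deficient segment (smallest
  singular value < 1e−12 × largest) has non-unique principal axes; a
  warning is recorded and the output is still returned, since noise in
  real recordings makes exact degeneracy a measure-zero event.
* Each segment is transformed independently in both training and test;
  the transform is local and needs no cross-segment smoothing. The
  rotation `Uᵀ` itself is discarded, never reported as an orientation
  estimate.

A corollary used by the tests: because `Uᵀ` is orthogonal, the transform
preserves the per-segment Frobenius norm, and the output row powers are
non-increasing.

## Rotation simulation

Random mounting is simulated per (segment, unit): one rotation matrix is
drawn and applied to *all* sensor types of that unit (they share the
physical housing), and each segment gets a fresh matrix. Matrices are
built as `Rx(θ)·Ry(φ)·Rz(ψ)` from angles drawn independently and
uniformly on [0, 2π). Uniform Euler angles do **not** sample SO(3)
uniformly — they over-weight the poles — but they are the protocol this
pipeline deliberately mirrors, and every generated matrix is verified
orthonormal with determinant +1 to 1e−10.

## Windowing and features

Windows are `L = round(window_s × rate)` samples (5 s by default; 2.56 s
with 50 % overlap reproduces the 128-sample smartphone convention),
starting at multiples of `hop = round(L(1 − overlap))`; a trailing
stretch shorter than one window is discarded, because every downstream
stage requires fixed-length segments. Recordings shorter than one window
yield no segments rather than an error.

Per channel, in fixed order: min, max, mean, skewness, kurtosis
(population moments, kurtosis non-excess, both 0 on zero variance); the
biased mean-removed autocorrelation at lag 0 (exactly the population
variance) and at lags 5, 10, …, 50 with lags ≥ L dropped; and the five
largest one-sided DFT magnitude peaks with their frequencies in Hz
(bin · rate / L), greedily selected with pairwise bin distance ≥ 11,
zero-filled when fewer admissible peaks exist. That is
`5 + (1 + #lags) + 10` features per channel: 26 at L = 125, 23 at
L = 40. Two asymmetric conventions are intentional: the lag set
*truncates* with short windows while the peak slots *zero-fill*; this
pair of conventions is the only combination consistent with both of
those per-channel widths, given that min and max are included among the
base statistics. Zero-magnitude spectrum bins are not counted as peaks.

Features are min-max scaled to [0, 1] per subject and per column, using
each subject's own extrema over all of their rows; a column constant
within a subject maps to 0. This normalization precedes the train/test
split, so each subject's range leaks across the split — it is kept
because it is the convention of the protocol being reproduced, and it is
the documented default rather than a silent one. PCA (scikit-learn, full
SVD solver) then projects onto the first M = 30 directions; directions
are fitted on the training folds by default, with an `all_data` pooled
mode. `scree` exposes the sorted eigenvalues for choosing M.

## Classifiers

* **Gaussian MAP ("BDM").** Per-class maximum-likelihood mean and
  covariance, empirical priors, decision by log prior + log density.
  A covariance that fails its Cholesky factorization is ridged by
  `1e−6 · (trace/M) · I`, escalating tenfold until positive definite.
  With equal priors and an exactly spherical shared covariance the rule
  provably reduces to Euclidean nearest-mean (used as a test oracle).
* **k-NN.** Euclidean metric, k = 7, majority vote; vote ties go to the
  tied class with the smallest mean neighbor distance, then class order.
* **SVM.** RBF kernel with the pinned pair C = 40, γ = 0.2, one-vs-one
  via scikit-learn/libsvm. Note γ = 0.2 presumes features on the
  normalized [0, 1] scale. The default multi-class fusion is libsvm's
  pairwise max-vote; a `confidence` mode (argmax of summed signed
  pairwise decision values) is selectable, since descriptions of
  "highest confidence" fusion are ambiguous between the two.
* **MLP.** One hidden layer of `round(½(log₂(2K) + 2K − 1))` sigmoid
  units for K classes (round half-up; the formula averages an optimistic
  log₂(2K) and a pessimistic 2K − 1 hyperplane count), sigmoid outputs,
  one-hot targets, squared error. Training is online back-propagation
  with learning rate 0.3, weights initialized uniformly in [0, 0.2], and
  a fresh seeded visiting order each epoch. The epoch error Eᵢ is the
  training-set mean of the summed squared output errors, evaluated after
  the epoch; training stops when `min(Eᵢ₋₉..Eᵢ) > Eᵢ₋₁₀ − 0.01` (so a
  flat error sequence stops at exactly epoch 11) or at a safety cap of
  1000 epochs — the adaptive rule alone cannot bound runtime, and
  whether the original protocol used batch or online updates is
  unspecified; online with a cap is this package's choice.

All argmax/vote ties everywhere resolve by sorted class order, for
bit-reproducibility.

## Cross-validation and the five cases

`run_case` executes, per fold: windowing → case-specific step (nothing /
per-segment-per-unit random rotation / norm / heuristic / SVD) → feature
extraction → per-subject normalization → PCA → classifier. P-fold
partitions are random, seeded and non-stratified (sizes differ by at
most one); leave-one-subject-out builds one fold per subject. Accuracy
is the fraction of correctly labelled test segments; the confusion
matrix pools folds; the reported band is mean ± 2 sample standard
deviations over folds. All randomness derives from one pipeline seed
split into independent streams (rotation, partition, classifier init).

For end-to-end invariance checks, `make_feature_table` can inject random
per-(segment, unit) rotations *after* the SVD scales are fitted: the
scales are corpus constants of the method, while the injected rotations
emulate mounting at wearing time. Under this protocol the heuristic and
SVD feature tables are identical (to 1e−6) with and without injected
rotations, and so are the predicted labels.

## The synthetic benchmark

Defaults: 5 subjects × 6 activities × 2 units (accelerometer +
gyroscope), 25 Hz, 60 s per recording — 360 five-second segments. Sizes
were chosen so a full five-case k-NN comparison runs in well under a
minute on one core while leaving every stage statistically non-trivial.

Construction: activity 1 is stationary (near-zero dynamic amplitude);
the five dynamic activities are three-harmonic sums (decay 0.45) whose
axis-amplitude profiles take one of three shapes of equal total energy —
concentrated on one axis, isotropic, planar — and whose fundamental
frequencies come in shared bands (0.9 Hz and 1.7 Hz; all shapes of a
band share the band center exactly). Accelerometer channels add a
9.8-unit gravity offset along a direction drawn once per
(subject, activity); white Gaussian noise (σ = 0.3 accelerometer, 0.2
gyroscope) is added throughout. Subjects differ by log-normal amplitude
jitter (σ = 0.2 per channel), fundamental-frequency jitter (σ = 0.03),
random phases and their gravity directions.

The design is deliberate: because band members share their fundamental
and total energy, the *rotation-invariant* content of the raw per-axis
features (frequencies, total power) identifies only the band, and
separating activities within a band requires cross-axis structure —
exactly what per-segment random rotation scrambles and what both OITs
re-expose (the heuristic through norm/angle waveforms, the SVD through
the singular-value profile). On the default benchmark at seed 0 this
yields: reference k-NN 10-fold accuracy 100 %, random rotation 79.2 %,
SVD transform 100 %, leave-one-subject-out ≤ 10-fold. These numbers are
recomputed by the test suite, not quoted from anywhere.

What the generator does **not** emulate: biomechanics (gyroscope
channels are independent harmonic processes, not derivatives of an
orientation trajectory), soft-tissue artifacts, sensor drift or
saturation, transitional activities, or class imbalance. Passing
end-to-end tests therefore demonstrates the correctness and invariance
of the pipeline machinery and the qualitative case ordering — not
real-world accuracy levels, which depend on data this package does not
ship. The gravity high-pass utility is a conventional zero-phase
2nd-order Butterworth (default cutoff 0.3 Hz) for building derived
body-acceleration channels; it is not claimed to match any particular
dataset provider's filter.

## Degenerate inputs and numerical tolerances

Rotation matrices are validated to 1e−10; heuristic invariance holds to
~1e−13 in float64 and is asserted at 1e−8; SVD invariance likewise at
1e−8 after sign canonicalization; end-to-end feature invariance at 1e−6
(feature extraction amplifies round-off through the DFT). Constant
channels produce min = max = mean, zero variance, zero shape moments and
a DC-only spectrum. Windows shorter than 5 samples cannot support the
heuristic transform and raise a dedicated error.
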