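# Methods

## The recognition pipeline

The package implements a band-power pipeline for binary preference
recognition from frontal EEG: epochs → power spectra → band powers →
asymmetry indices → feature selection → holdout classification. Its
scientific core is the observation that approach/withdrawal motivation and
affective valence express themselves as left/right power asymmetries of the
frontal alpha (and, secondarily, beta and theta) rhythms, so a handful of
asymmetry indices can summarize a 2,000-dimensional spectral feature vector
almost losslessly for this task.

## Synthetic study generator

Real neuromarketing recordings are noisy, proprietary and hard to
re-distribute, so the generator emulates the canonical study design
directly: 25 subjects × 42 product-viewing trials (1,050 epochs), 14
channels in the Emotiv EPOC+ 10–20 montage, 128 Hz sampling, 4 s epochs
(512 samples, so a full-epoch 512-point FFT needs no padding), activity
confined to 4–45 Hz as after the usual band-pass.

Signal model per channel: for each of theta/alpha/beta/gamma, three
sinusoids with frequencies drawn uniformly in the band and uniform phases,
scaled to a per-band amplitude; plus 1/f pink noise (spectrally shaped white
noise). Defaults: amplitudes theta 4, alpha 6, beta 3, gamma 1.5 µV
(alpha-dominant resting-like spectrum), pink-noise SD 5 µV. Between-subject
variability is a multiplicative log-normal jitter (σ = 0.1) on the band
amplitudes, constant within subject. Per-subject like-rates are Beta(5,5)
clipped to [0.2, 0.8], so subject-pooled splits stay roughly balanced but
not exactly so.

The class effect is a single dial δ ∈ [0, 1): for a liked stimulus the
alpha amplitude at the left frontal electrodes (AF3, F3) is scaled by
(1 − δ) and at the right (AF4, F4) by (1 + δ), with the mirror-image
scaling on beta; disliked stimuli reverse the pattern, and non-frontal
channels never carry it. This makes the approach/withdrawal and Vamv
valence indices positive in expectation for "like", and δ = 0 makes the
two classes identically distributed — the basis of the null-calibration
tests. The default δ = 0.5 gives near-perfect separability of the index
features (AUC ≈ 1), which is intentionally stronger than real scalp EEG;
what passing tests demonstrate is that the pipeline recovers a planted
frontal asymmetry through every stage, not that real data are this clean.
The generator also omits eye-blink/EMG artifacts, non-stationarity within
epochs, volume-conduction correlations between channels, and electrode
noise, so absolute accuracies on synthetic data say nothing about
accuracies on recordings.

Determinism: every epoch draws from an RNG stream keyed on
(seed, subject, trial), so datasets are bit-identical given (config, seed)
and any epoch can be regenerated in isolation.

## Spectral features

- PSD: one-sided boxcar periodogram, nfft = 512 at 128 Hz → 257 bins,
  density scaling so that Σ PSD·Δf equals the mean squared signal
  (Parseval; verified to 1% on random epochs). No Welch averaging — the
  per-channel dimension of 257 is part of the design contract.
- Band powers: mean of PSD bins with half-open intervals [low, high);
  gamma is [30, 45] including the 45 Hz ceiling bin left by the band-pass.
  Powers are floored at 1e−12 before any ratio or logarithm downstream.
- Morlet block: complex Morlet transform (7 cycles) at 61 linearly spaced
  center frequencies over 4–45 Hz, time-averaged squared magnitude;
  computed with MNE's array interface and cross-checked in the tests
  against a direct wavelet convolution.
- Spectrogram block: Hann window, 128-sample segments, 50% overlap,
  time-averaged rows → 65 features per channel.
- Assembly: 4×257 per-channel PSD + 2×257 cross-channel sum/average +
  4×61 Morlet + 4×65 spectrogram + 10 indices = 2,056 named features, with
  queryable block boundaries. (Published dimension accountings of this
  feature set do not always add up to their printed totals; this package
  documents and tests its own accounting.)

## Preference indices

The ten indices are computed exactly as written in the README. Two
conventions the literature leaves open:

- a two-electrode argument such as α(AF4, F4) is the arithmetic mean of
  the two electrodes' band powers (mean rather than sum keeps the
  log-difference and ratio indices comparable with their single-electrode
  variants);
- the choice indices use the natural log; their ratio structure makes them
  base-invariant (property-tested to 1e−12).

Structural guarantees, all property-tested: the eight asymmetry indices
vanish on a left/right-symmetric table and negate under a hemisphere swap;
Touchette AW and effort-1 are bounded in [−1, 1]; Touchette AW, effort-1,
Vamv, Ram15 and Kirk are invariant under a common rescaling of all powers.
The choice-index denominator log p(AF3) + log p(AF4) changes sign as powers
cross 1.0; values with |denominator| < 1e−9 are returned as computed but
flagged with a runtime warning rather than clipped.

## Feature selection

- Mutual information: plug-in estimator on equal-frequency discretized
  features (3 bins, log2). Three bins is deliberately coarse — it is robust
  on ~1,000-row tables and keeps the estimator's finite-sample bias small.
- mRMR: greedy forward selection; the first pick maximizes relevance
  I(x; y), later picks maximize relevance minus (MID) or divided by (MIQ,
  the default) the mean MI with the already-chosen set. Pairwise MI is
  cached; ties break to the lower feature index. Known limitation: the MIQ
  quotient can promote pure-noise features whose redundancy denominator is
  near zero, so rankings of strongly inter-correlated informative features
  (e.g. the alpha-asymmetry family) are less stable under MIQ than under
  MID; both schemes are exposed.
- ReliefF: all instances, Manhattan metric on min-max normalized features,
  10 neighbors by default, misses weighted by class prior; weights lie in
  [−1, 1] and are invariant to affine rescaling of any feature. Verified
  against a direct evaluation of the update formula.
- RF importance / RF-RFE: impurity-decrease importances from a 500-tree
  forest; RFE drops ⌈10% of remaining⌉ lowest-importance features per
  round until 10 survive, then ranks survivors by a final fit. The round
  step is a fraction of the *remaining* set, which standard RFE
  implementations do not offer directly.
- PCA: mean-centered full-SVD projection with a deterministic sign
  convention (largest-magnitude loading positive). The component count is a
  required parameter; the benchmark grid's preset is 1 component (the
  conservative reading of the reference configuration, which is stated
  inconsistently in the literature this design follows).

## Classification benchmark

Stratified 80/20 holdout (1,050 → 840/210). Classifiers: 1-NN, 500-tree
random forest, LDA, RBF-SVM at library defaults, and a hinge-loss MLP
(64–32 rectified hidden layers, single linear output, ±1 labels, full-batch
Adam at 1e−3, ≤ 200 epochs with patience-20 early stopping, seeded He
initialization) — hand-written because mainstream MLP implementations do
not expose a hinge objective. Features are z-scored with training-set
statistics for all scale-sensitive classifiers; the forest is exempt.

Metrics are computed from the 2×2 confusion matrix with class-frequency
weighting, under which the weighted recall equals the accuracy; the
F-measure is the harmonic mean of the weighted precision and recall.

Leakage control: selectors and standardization are fitted on training rows
only (default). Because published pipelines are often ambiguous about this,
a legacy mode that fits selectors on the full table is provided, and a
canary test (a feature equal to the label on test rows only) asserts the
default mode cannot exploit it.

## Problem sizes and numerical choices

Tests and the acceptance script run the full 25 × 42 study design for the
structural and calibration checks; the selector-recovery analyses append
200 standard-normal noise features to the ten indices (the RFE
configuration check uses 290, giving a 1,050 × 300 table). Null calibration
uses 10 independent seeds and a 3-binomial-SE band around chance. Oracle
tests (greedy-mRMR enumeration, ReliefF direct formula, Kendall pair
counting, ANOVA-vs-t², confusion arithmetic) run on 20–80-row instances
where exhaustive evaluation is exact. All randomness flows from explicit
integer seeds; there are no tolerance-free floating-point equality
assertions except where the computation is identical by construction.
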