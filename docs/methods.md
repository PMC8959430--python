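# Methods

This note documents the models and procedures implemented in `kdemg`, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical choices that affect results.

## Signal model and preprocessing

A recording is a `SignalRecord`: a channels × samples matrix with sampling
rate, movement label (0 = rest), repetition index and subject id. The
preprocessing chain is:

1. **Band-pass filtering.** Butterworth, applied forward–backward
   (`sosfiltfilt`) so the output is zero-phase; features are therefore never
   delayed relative to the labels. Defaults: 4th order, 20–500 Hz for
   2 kHz sequential recordings; 8th order, 5–500 Hz for the 1.2 kHz
   simultaneous protocol. The "order" parameter is the analogue prototype
   order; forward–backward application doubles the effective attenuation.
2. **Standardization.** Channels are z-scored with the *sample* (n−1)
   standard deviation. The experiment drivers pool the statistics per
   subject over all of a subject's records, mirroring standardization of the
   continuous recording before segmentation: per-segment standardization
   would erase the between-movement amplitude differences that carry most of
   the class information. The per-record operation `standardize_channels`
   is also available.
3. **3-sigma outlier removal.** A single pass per channel removes samples
   with |x| > 3·sd; no re-estimation loop. Because removal is per channel,
   the result is ragged, so the pipeline applies it per channel *after*
   window extraction — windows stay time-aligned across channels and the
   removed fraction is tiny (≈0.27% for Gaussian data). Channels with more
   than half their samples flagged trigger a warning, not an error.
4. **Windowing.** Sliding windows (width W, step S, count ⌊(T−W)/S⌋+1),
   the middle third of a contraction (0-based slice `[n//3 : (2n)//3]`), or
   the whole segment. For the 2 kHz protocol the default sliding window is
   400 ms with a 100 ms *overlap* (step 300 ms); for the 1.2 kHz
   simultaneous protocol the stated 40 ms *increment* is the step. Both
   readings are exposed as explicit `width_ms`/`step_ms` parameters. Before
   sliding-window extraction the drivers cut 10% off each end of a record
   (`edge_trim_frac`), so no window straddles the onset/offset ramp — the
   windowed analogue of excluding rest/contraction boundary windows.

## Density estimation

`kde_diffusion` implements the adaptive diffusion estimator: the histogram
of the (≥30) samples on a 2^k-point grid spanning the data range extended by
10% per side is DCT-transformed; the optimal squared bandwidth t\* solves
the fixed-point equation t = ξγ^[7](t) built from successive plug-in
functionals of the smoothed spectrum; the density is the inverse transform
of the damped coefficients and the bandwidth is h = √t\*·span. The root is
bracketed and solved with Brent's method (xtol 1e−9, ≤50 iterations,
expanding bracket); on failure the bandwidth falls back to the
normal-reference plug-in rule with a logged warning. Grid: 4096 points by
default (a power of two for the transform); small negative ringing is
clipped to zero, which leaves the trapezoidal integral within 1% of unity
on well-behaved inputs.

`kde_gaussian_fixed` is the plain fixed-bandwidth estimator
f̂(x) = (1/(nh))·Σφ((x−xᵢ)/h). Density derivatives use the closed Gaussian
form with probabilists' Hermite polynomials (He₁(u)=u, He₂(u)=u²−1), chosen
so the estimate equals the exact analytic derivative of the Gaussian mixture
— verified against central finite differences of the density to a relative
deviation below 1e−3. Order r = 0 reproduces the density; samples are summed
in sorted order so estimates are exactly permutation-invariant. First- and
second-order difference operators on a value sequence are provided for
comparison; the central difference is computed literally as the average of
consecutive first-order differences, so that identity is exact in floating
point.

## Features

Per channel-window, one diffusion density estimate feeds all three features:

* **TMD** = trimmed mean of the grid values of f̂. Trimming is count-based:
  sort, drop ⌊p/100·n⌋ observations per side (default 5%/5%), average the
  rest — deterministic and exactly reproducible against a sort-and-drop
  oracle.
* **ED** = ApEn of the grid-ordered density values, m = 2, r = 0.2·sd
  (population sd of the sequence), Chebyshev distance, self-matches
  included; a constant sequence returns 0. Neighbour counting uses a k-d
  tree over the delay embeddings; counts are integers identical to the
  definitional double loop, so the vectorisation changes nothing beyond
  speed. The defaults stand in for a heuristic tolerance-tuning procedure
  whose internals are not reproducible from public sources; both parameters
  are configurable per call.
* **TMAVDD** = trimmed mean (same 5%/5%) of |f̂′| on the same grid, with the
  first derivative's bandwidth reused from the diffusion estimate.

Features are computed on the estimator's grid values rather than at the raw
sample points: that is what the diffusion estimator naturally returns, and
ApEn requires an ordered sequence — the grid ordering by abscissa provides
it. Classic comparison features (RMS, waveform length, mean absolute value)
and 3-level sym4 DWT coefficient energies (periodization boundary, so the
four energies sum exactly to the signal energy) are included as baselines.
Feature tables are channel-major (`ch01_TMD, ch01_ED, ch01_TMAVDD, ch02_…`);
rows with any non-finite value are dropped and logged, never imputed.

## Feature selection

CFS merit: Merit_S = k·r̄_cf / √(k + k(k−1)·r̄_ff). The default correlation
measure is symmetric uncertainty after equal-frequency discretization;
|Pearson| (one-vs-rest averaged against the class) is available. The bin
count follows the square-root rule capped at 10: with a fixed fine binning,
small training splits (40 rows in the repetition hold-out) produce saturated,
noisy entropy estimates and the search collapses onto near-singleton subsets
that cost measurable test accuracy; √n binning removes this failure mode
while reproducing 10 bins for n ≥ 100.

Best-first search starts from the empty set, expands by single-feature
additions, always expands the best unexpanded subset (lexicographic
tie-break, so the search is fully deterministic), backtracks through the
open list, and stops after 5 consecutive fully expanded non-improving
subsets (`max_stale`, configurable). On problems with independent features
the search provably visits the optimum prefix; agreement with exhaustive
enumeration is part of the acceptance checks.

## Classifiers and fusion

* **LDA** on the raw selected features.
* **SVM**, RBF kernel, on z-scored features. C and γ come from an internal
  stratified 3-fold grid search (C ∈ {0.1,1,10,100}, γ ∈ {0.01,0.1,1,10}) —
  an explicit stand-in for an analytic parameter-setting method that is not
  reproducible from public sources. Posteriors are the softmax of the
  one-vs-rest decision values rather than Platt scaling: Platt's internal
  5-fold CV is undefined for classes with fewer than five training rows
  (four repetitions per class in the hold-out scheme) and adds
  nondeterminism, while BKS consumes labels and uses posteriors only as a
  fallback.
* **MLP**: one hidden layer of 15 tanh units, linear output with softmax
  posteriors, adam back-propagation, seeded, on z-scored features. Early
  stopping on a 10% validation split is enabled only when the training set
  has at least 200 rows: below that the validation split is a handful of
  rows and stopping fires before the network has learned anything (observed
  directly on 40-row training sets).
* **BKS fusion**: every training row is filed under its (LDA, SVM, MLP)
  decision tuple; a cell predicts the majority of the true labels it
  accumulated; ties and unseen tuples fall back to the class with the
  highest mean posterior across learners. On the training distribution BKS
  is the Bayes rule over decision tuples, so its training accuracy is never
  below the best single learner. By default all learners see the full
  CFS-selected subset; a seeded random partition of the selected features
  into three disjoint subsets is available (`feature_distribution=
  "random_partition"`) as the alternative reading of distributing features
  across base learners.
* **Boosted trees** for the simultaneous task: multiclass gradient-boosted
  decision trees with 600 estimators, maximum depth 18, learning rate 0.1
  (`tree_method="hist"`, single-threaded, seeded — bit-reproducible).

## Evaluation

Per class, PR = TP/(TP+FP), RL = TP/(TP+FN) (0 when the denominator is 0),
Acc_i = (TP+TN)/N, F = 2·PR·RL/(PR+RL). When a class has no true positive
its precision and recall are both zero, F_i is NaN and the macro-F is
reported as NaN — never zero-filled; a separate per-movement
misclassification counter (a movement is "missed" in a set if any of its
windows is wrongly labelled, as false negative or false positive) covers
that case. Micro-averaged precision, recall, F and the overall accuracy are
identical by construction; the implementation preserves the identity to
machine precision.

Split schemes: the repeated hold-out is the fixed three-way partition of six
repetitions (test {1,4}, {2,5}, {3,6}); fourfold CV is stratified and
seeded. Fleiss' kappa is computed from the items × categories count table
with a large-sample-SE 95% CI; McNemar's test is the exact two-sided
binomial below 25 discordant pairs and the continuity-corrected chi-square
above (zero discordant pairs → p = 1).

## Synthetic data

Each movement class is defined by a per-channel amplitude vector and a
spectral sub-band inside the global 20–450 Hz band, drawn once from a
dedicated profile seed; noise uses an independent seed stream so class
structure can be held fixed while noise is resampled. A repetition is
band-limited Gaussian noise shaped in the class sub-band, scaled per
channel, multiplied by a trapezoidal envelope (10% ramps), plus white sensor
noise at the configured SNR (20 dB default). The sequential default mirrors
a 2 kHz / 5 s contraction / 3 s rest / 6 repetitions protocol; the
simultaneous variant produces rest, four single movements and the four valid
two-movement combinations (superposed component signals, so channel power is
approximately additive) at 8 channels / 1.2 kHz / 3 s / 4 repetitions.

Class amplitude profiles are rejection-sampled to a minimum pairwise L2
separation (default 1.5): classes represent distinct muscle-activation
patterns, and separability is a controlled property of the generator rather
than an accident of the draw. A Laplace-amplitude variant
(`amplitude_dist="laplace"`) deliberately violates Gaussianity to exercise
the density features on heavier tails.

What the generator does *not* emulate: motor-unit physiology, electrode
shift, inter-subject variability, fatigue, crosstalk structure, or real
label noise from imperfect stimulus following. Passing the end-to-end checks
therefore demonstrates that the pipeline is implemented correctly and
behaves as expected on separable, stationary signals — not that the
accuracies transfer to real recordings.

## Problem sizes and determinism

The end-to-end runs in the test suite and the acceptance script use, as this
package's own desk-scale choices: a 1024-point KDE grid inside the feature
pipeline (4096 remains the estimator default), the 10-class / 8-channel /
6-repetition sequential configuration, 160 ms windows with an 80 ms step for
the simultaneous experiment (the driver's default remains 160/40), and
non-overlapping epochs (step = width) in the online simulation. Online
per-epoch processing times are measured and reported, never asserted —
they are hardware-dependent.

All randomness flows through explicit seeds (generator profile/noise seeds,
classifier seeds, fold shuffling); re-running any experiment with the same
config reproduces every metric bit-for-bit, and the acceptance script
verifies this with a second run.

## Known limitations

* The diffusion bandwidth assumes a roughly continuous sample distribution;
  heavily quantised windows can trigger the normal-reference fallback.
* ApEn on a long oversampled density grid is dominated by grid resolution;
  ED values are comparable only across equal grid sizes.
* CFS assumes feature relevance is visible marginally; purely interactive
  features would be dropped.
* The BKS table grows with the product of learner decisions actually
  observed; unseen tuples at test time fall back to posteriors, which is
  the dominant regime when training sets are very small.
* The MAT-file adapter covers the common variable layout (`emg`,
  `stimulus`/`restimulus`, `repetition`/`rerepetition`) only.
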