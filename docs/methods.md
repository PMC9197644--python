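# Methods

This note documents the models, estimators and design choices behind the
package, including the places where the construction was genuinely open and a
choice had to be made.

## Signal model and band decomposition

A segment is a single-channel EEG trace in microvolts with a declared
sampling rate (default 256 Hz, default duration 10 s; both configurable —
at least 2 s and at least 90 Hz are required so the γ band is representable).
Preprocessing removes the mean and linear trend and clips amplitudes beyond
`k·SD` of the detrended signal (default k = 5), a minimal spike guard; ICA or
wavelet artifact rejection is out of scope.

The five rhythm bands are fixed at δ [0.5, 4), θ [4, 7], α [8, 15],
β [16, 31], γ [32, 45] Hz.  The small gaps between the printed band edges
(7–8, 15–16, 31–32 Hz) are kept as stated rather than interpolated, since
features are computed per band independently.

Band-passing uses the two-pass (forward–backward) magnitude response
|H(ω)|² of an order-8 elliptic design (0.01 dB passband ripple, 60 dB
stopband), applied in the frequency domain.  Zero phase is essential because
permutation entropy reads ordinal patterns, which phase distortion would
scramble.  The frequency-domain application was chosen over recursive
`filtfilt` after measurement: the δ-band poles (radius ≈ 0.9996 at 256 Hz)
ring for several seconds, and on 4–10 s segments the recursive edge
transients inflated δ-band variance by up to 4× on some realizations.  With
the circular application the five band variances sum to within ~5% of the
broadband [0.5, 45] Hz spectral mass for white noise, and refiltering a band
signal changes its variance by ~1–2% (theoretical ratio for the δ band:
0.987).

## Features

Each band contributes four values (20 per segment, band-major order):

* **Hurst exponent** — rescaled-range (R/S) analysis over ≥ 8 log-spaced
  window sizes between 10 and n/2, least-squares slope of log(R/S) against
  log(window), with the Anis–Lloyd–Peters expected-R/S correction: the
  estimate is `0.5 + slope − slope₀`, where slope₀ is the slope the
  closed-form expectation predicts for uncorrelated data.  Plain R/S biases
  white noise to ≈ 0.56 at these lengths; the corrected estimator recovers
  0.49 (H = 0.5) and 0.74 (H = 0.8) on average at n = 4096.
* **Fluctuation index** — mean absolute first difference,
  `(1/(N−1)) Σ |x[i+1] − x[i]|`.  This volatility proxy is the one feature
  whose precise definition had to be fixed by this package; it is isolated
  behind a single function so it can be swapped.
* **Sample entropy** — `−ln(A/B)` with B (A) the number of unordered pairs of
  length-m (m+1) templates within Chebyshev distance `r·SD`, self-matches
  excluded, the same n−m template positions used at both lengths.  Defaults
  m = 2, r = 0.2·SD (field convention).  Constant input returns 0 by
  convention; no (m+1)-matches returns +∞.  Pair counting uses a k-d tree.
* **Permutation entropy** — Shannon entropy of ordinal-pattern frequencies,
  normalised by ln(order!) into [0, 1].  Defaults order 3, delay 1; argsort
  with positional tie-breaking defines the patterns.

Feature tables are min-max scaled to [0, 1] with bounds fitted on the
training split only (sigmoid ELMs are scale-sensitive); test values are
clipped into the unit interval.

## Classifiers

**ELM.**  Hidden weights and biases are drawn uniformly on [−1, 1] from a
seeded generator (default L = 100 sigmoid units); the output weights solve
the ridge system `β = (I/γ + HᵀDH)⁻¹ HᵀD Tᵀ` (default γ = 1; γ → ∞
approaches the interpolating pseudo-inverse solution).  Argmax decoding, ties
to the lowest class index.  Stress classes order by severity
(low < moderate < high), so a tie favours the *lower* stress level — the
minority class never wins by tie-breaking artefact.

**LW-ELM.**  The m × n target matrix sets `t_ij = N_major/N_i` (scheme
`ratio`) or its square (`ratio_squared`) when sample j belongs to class i,
−1 otherwise.  On balanced data both schemes reduce exactly to ±1 coding, so
LW-ELM degenerates to the plain ELM.

**AdaBoost** (reference/oracle): normalised weights, error
`ε = Σ w_j 1[pred ≠ y]`, coefficient `½ ln((1−ε)/ε)` (a printed 1/n factor
alongside already-normalised weights would double-count and is omitted),
symmetric exponential reweighting, early stop at chance-level or perfect
rounds.  For K > 2 the SAMME coefficient `ln((1−ε)/ε) + ln(K−1)` is used;
the IELM path does not rely on it.

**IELM.**  One-hot binarisation makes each class a label (q = c), the only
reading under which per-label imbalance ratios are meaningful for a
single-label task.  Construction per round t (hidden-layer seed = seed + t):

1. one hidden layer shared by all labels;
2. per label l, a ridge solve with the label's current weight column as
   diagonal costs and LW targets (positives `N_major/N_l`, negatives −1).
   The weight column is normalised to mean 1 before entering the solve so
   that γ retains its unweighted meaning and uniform weights reproduce the
   plain solve exactly;
3. block coefficients `ς^{lj} = ½ ln(correct/wrong block mass)` and the
   global `ς_t` over all mass, log arguments clipped at 1e-10;
4. within-block reweighting (mistakes × e^{+ς}, correct × e^{−ς}) with each
   block renormalised to 1/(2q).

The initial distribution assigns the minority side of each label raw weight
√R_j against 1 before block normalisation.  Because normalisation is per
block, the √R factor cancels within a block — the imbalance compensation is
carried entirely by the equal-block-mass constraint, which gives each
minority *sample* weight ∝ 1/n_minority.  The raw √R construction is kept
(with an `use_sqrt_ratio` toggle) for fidelity and to keep the two
normalisation conventions distinguishable.

Decoding sums `ς_t · sign(H_t(x) β_l)` per label and takes the argmax.  On a
balanced two-class problem with one round this is exactly the plain ELM
decision, a degeneracy the tests assert.

**Known trade-off.**  The construction compensates imbalance twice — equal
block masses in the costs *and* inflated minority targets — and the sign
decoding discards margins.  On strongly overlapped synthetic data this buys
large minority-recall gains (0.18 → 0.86 at separation 1.5) at a real cost in
overall accuracy (0.76 → 0.52).  Macro recall moves in the ensemble's
favour; raw accuracy may not.  Applications that weight accuracy over
minority recall should prefer the standalone LW-ELM, which on the same data
raises minority recall to ≈ 0.67 with ≈ 0.02 accuracy loss.

## Feature fusion

Per band, feature weights are proportional to each feature's standalone
classification accuracy, `w_i = f_i/Σf` (positive accuracies required; 4-dp
half-up rounding for display).  Fusion feeds the classifier the 20-dim
element-wise weighted vector by default; the five scalar band scores
`F_band = Σ w_i P_i` are available behind a flag but discard most of the
information.  The package bundles a reference accuracy table from a published
stress-classification experiment; its weight table is reproduced by the
`weights` command.  One cell of that published weight table (β-band sample
entropy) recomputes to 0.2212 rather than the printed 0.2213; the package
reports the recomputed value, which matches the published combination
formula.

## Metrics

Accuracy, per-class recall, macro recall (unweighted mean — the single-number
recall summary for a multi-class task) and the confusion matrix.  Relative
improvement is `100·(new − baseline)/baseline`.  Comparison baselines (RBF
SVM, linear SVM, random forest) are thin adapters over scikit-learn —
benchmarks, not contributions.

## Synthetic data

The generator emulates the statistical structure the pipeline consumes, not
physiology (no blinks, spindles or mains hum):

* class mix default (low, moderate, high) = (0.42, 0.46, 0.12), i.i.d. draws;
* per class, band-limited unit-RMS Gaussian noise scaled by a band-amplitude
  map in which β/γ power rises and α power falls with stress (defaults: α
  10→8→5, β 4→6→9, γ 2→3→5 µV RMS from low to high), summed over bands;
* plus `noise_sd` × fractional Gaussian noise with a class Hurst target
  (0.75/0.65/0.55 from low to high: calmer states drift more persistently);
* fGn by Davies–Harte circulant embedding (exact covariance; validated
  against the closed-form lag-1 autocorrelation 2^{2H−1} − 1);
* subjects group 4 consecutive segments (for subject-wise bookkeeping);
* everything reproducible bit-exactly from (config, seed).

For classifier studies, `generate_feature_dataset` skips signal synthesis:
20-dim unit-variance Gaussian clusters whose unit-norm mean directions are
drawn from the seed and scaled by `separation` (default 1.5, which places the
plain ELM near the high-0.7 accuracy regime typical of published ELM
baselines on this task).  Passing tests on these fixtures demonstrates the
algorithmic properties — weight conservation, degeneracies, minority-recall
lift — not performance on real EEG, where feature correlations, subject
effects and nonstationarity are all absent from the generator.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale by choice: feature
extraction fixtures use 2–4 s segments, classifier comparisons n = 500 with
10 paired seeds, Hurst recovery n = 4096 with 20 seeds.  Numerical choices:
log-argument clipping at 1e-10 for all coefficient formulas; argmax ties to
the lowest class index; constant signals are rejected by the Hurst estimator
(zero variance) and dropped with a warning during table extraction; sample
entropy returns +∞ when no (m+1)-template pair matches and that row is then
dropped as non-finite.

## Limitations

* The fluctuation index definition is this package's choice; other
  volatility measures exist.
* The train/test split is stratified by class, not grouped by subject, in
  the default pipeline; with real multi-segment recordings a subject-grouped
  split is the right protocol (subject ids are generated and carried for
  that purpose).
* The IELM accuracy/minority-recall trade-off above.
* True multi-label tasks (overlapping label sets) are representable in the
  weight bookkeeping but not exercised by the stress task or the CLI.
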