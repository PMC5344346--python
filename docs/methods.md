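# Methods

## Problem and model

Seizure detection is cast as binary classification of fixed-length
single-channel EEG windows (seizure vs non-seizure). Each window is
decomposed with the multilevel Mallat filter bank (PyWavelets `wavedec`,
symmetric half-point boundary extension, held fixed), producing detail
coefficient series at levels 1..j and one approximation series. Band
index equals detail level, so band 1 is the highest-frequency band and
band j+1 the final approximation; this indexing makes "drop band 1"
(the top octave) a natural restriction. Band intervals are attached by the
dyadic tiling of (0.5 Hz, Nyquist) — 0.5 Hz because the preprocessing
high-pass defines the lower edge of usable signal. Conventional rhythm
names are attached by interval intersection: delta (0–4 Hz), theta (4–7),
alpha (8–15), beta (16–31), gamma (>31). As printed, these ranges leave
7–8 Hz unassigned; `rhythm_overlap` reports an empty list there rather
than inventing a convention.

## Maximum decomposition level

`max_decomposition_level(N, F) = floor(log2(N / (F − 1)))`, the standard
dyadic-support rule. With it, a 5120-sample window (20 s at 256 Hz)
supports 12 haar levels, 8 db10 levels and 5 discrete-Meyer levels, and a
4097-sample window (23.6 s at 173.61 Hz) supports 12 haar levels. The
additive variant `L < log2(N/(F−1)) + 1` that sometimes appears in the
literature over-counts by one against these figures and is not used.

## The discrete Meyer filter

PyWavelets ships a 62-tap truncation of the Meyer lowpass. Two properties
make it unsuitable here: its length implies a maximum level of 6 on 5120
samples where the classical 102-tap dmey filter gives 5, and its filter
bank is only approximately orthogonal (multilevel round-trip error about
5e-3). The package therefore constructs the 102-tap filter itself: the
Meyer scaling symbol (C3 auxiliary polynomial) is sampled on a 2^14 grid,
inverse-transformed, truncated to 102 centred taps, and projected onto the
exact orthogonality constraints (even-lag autocorrelations = delta) by a
least-change Gauss–Newton iteration. The projection moves the taps by
about 8e-5 in sup norm and restores perfect reconstruction to machine
precision, so dmey participates in round-trip guarantees on equal terms
with the orthogonal families. The construction runs once per process and
is cached.

## Features

Per band: Max, Min, Mean, STD (sample, n−1), skewness and kurtosis
(population-moment; kurtosis not excess-corrected, normal → 3), Energy
(Σc²), nSTD = STD/(Max−Min), nEnergy = Energy/n with n the coefficient
count. Conventions that the originating literature leaves unstated were
fixed as follows: moments follow the defaults of the numerical
environments this family of pipelines is usually built in; the "size of
the band" normalizing Energy is the coefficient count (the quantity
available per band vector), not the bandwidth in hertz; features are
computed on raw coefficients, not absolute values (Max/Min would be
redundant otherwise). Degenerate bands (constant, single-coefficient, or
with moments that underflow) return 0 for the undefined ratios instead of
raising or propagating NaN, so exhaustive searches never abort mid-run.

## Classifier and cross-validation

RBF-kernel SVM with per-fold feature standardization; regularization
weight 1.0 and scikit-learn's variance/dimension-scaled kernel width
(`gamma="scale"`) by default, both exposed because reported accuracies
depend on them. Leave-one-subject-out CV keeps any subject's data out of
its own training fold; pooled stratified k-fold is used for datasets
without subject structure. Folds are pooled into a single (micro)
confusion matrix; rates with zero denominators are NaN. Seizure is the
positive class.

## Search blocks

Wavelet–level selection scores each (wavelet, level) with all bands and
all nine features. Family winners follow either argmax (ties: lower
level, then shorter filter, then name) or the threshold rule: lowest
level reaching the accuracy threshold, then smallest vanishing moments,
falling back to argmax with a warning when nothing reaches it.

Band–feature selection fixes one (wavelet, level), computes the full
feature matrix once, and scores every non-empty (band subset, feature
subset) pair by slicing columns — `(2^(j+1)−1)(2^m−1)` combinations — on
the same CV folds for every combination (fold reuse keeps comparisons
fair; the caching is pure engineering and changes no result). The winner
maximizes pooled accuracy; ties prefer the smaller dimension (consistent
with the low-computational-cost objective) and then lexicographic
subsets, so reruns are reproducible. Restricting the candidate sets is
the intended speed lever — e.g. to bands covering clinically suspected
rhythms — and the only one: no greedy subset heuristics are provided.

## Synthetic data

The generator emulates a small multi-subject cohort. Non-seizure windows
are 1/f^beta Gaussian noise shaped in the frequency domain (beta = 1 by
default, a standard EEG background slope). Seizure windows add
random-phase components inside each configured effect band with per-bin
amplitude `gain` times the background envelope, so the expected
seizure/non-seizure power ratio in the band is 1 + gain². A log-normal
per-subject factor (sd 0.2) scales effect amplitudes, giving
leave-one-subject-out folds genuine between-subject shift. Defaults — 6
subjects, 20 windows per class per subject, 20 s at 256 Hz, one theta
(4–7 Hz) effect at gain 3 — are the package's reference study conditions
and are used unchanged by the recovery and calibration tests.

What the generator does not model: spike-wave morphology, artifacts (eye
blink, EMG), channel covariance, non-stationarity within a window.
Passing tests therefore demonstrate that the pipeline recovers planted
band-limited power differences under subject heterogeneity — not clinical
performance on real recordings, which additionally depends on unmodeled
structure and on SVM hyperparameters.

## Numerical and statistical notes

- Pooled LOSO accuracy under a true null is centred at 0.5 but spreads
  wider than the iid binomial because fold predictions are correlated
  through shared training data; with 6 subjects × 40 windows the
  across-realization sd is roughly 1.4× binomial. The calibration checks
  use the 99% binomial band as a fixed, seeded sanity bound and the
  label-shuffle check inherits additional optimism from maximizing over
  candidates; both are documented bounds, not exact null quantiles.
- Windowing uses half-open [start, end) intervals; window k covers
  [k·w, (k+1)·w). Seizure labels require full containment of the window
  in an annotated interval; boundary-straddling windows are discarded to
  avoid label noise, and trailing partial windows are discarded.
- The preprocessing high-pass is a causal 48th-order Hamming-window FIR
  at 0.5 Hz, applied single-pass (not zero-phase) so results are exactly
  reproducible. At this order the transition band is wide (~17 Hz at
  256 Hz): the designed response at 0 Hz is ≈0.9, i.e. the filter trims
  drift but does not null DC; rhythm-band content above ~10 Hz passes
  within 1%.
- Class balancing subsamples each subject's majority class uniformly at
  random with an explicit seed; subjects lacking a class are dropped with
  a warning.
- Multi-channel records are segmented per channel; each channel window is
  an independent labeled segment.
- EDF fixtures are written by a minimal in-package 16-bit EDF writer
  (integer sampling rate, whole-second records) and read back through
  MNE; synthetic fixtures are labeled as such.

## Problem sizes used by the test suite

Recovery and calibration run at the reference conditions (6 subjects × 40
windows, 20 seeds for recovery); contrast and monotonicity properties use
4 subjects × 16–20 windows over 10 seeds; estimator- and CLI-level tests
use 3 subjects with short windows. These sizes are the package's chosen
demonstration scale for its distributional checks.

## Known limitations

- Full exhaustive search at published scale (130,305 combinations with
  thousands of windows) is supported but slow by construction; restrict
  candidates or reduce levels for interactive use.
- The UBonn reader ingests one file per segment; no archive download or
  directory conventions are built in.
- No CHB-MIT summary-format parser: annotations arrive as a
  subject_id,record_id,start_s,end_s CSV.
- No artifact rejection beyond the high-pass filter, no montage logic, no
  CWT or wavelet-packet variants, no ROC/AUC or latency metrics.
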