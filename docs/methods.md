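# Methods

This note documents the models implemented in `emoeeg`, the assumptions they
make, the synthetic data they are validated on, and the numerical and design
choices that were genuinely open.

## Signal model and preprocessing

A trial is a single- or multi-channel time series in microvolts with a
sampling rate `fs` (default 1000 Hz, so content up to ~500 Hz is
representable).  Preprocessing is a zero-phase order-5 Butterworth low-pass
at 256 Hz (applied forward and backward with `sosfiltfilt`, i.e. an effective
10th-order magnitude response and no phase distortion — band energies are the
discriminative quantity, and phase lags would smear them across windows),
followed by polyphase resampling to 512 Hz.  The resampling rate is chosen so
that a 4-level wavelet-packet decomposition produces 16 terminal bands of
exactly 16 Hz (edges 0, 16, …, 256 Hz), making band indices interpretable as
frequency intervals.  If a trial's rate already places the cutoff at or above
Nyquist, the filter stage is skipped (the signal is band-limited by
acquisition).

## Feature families

**Multi-scale sample entropy (MSpEn).**  SampEn(m, r) = −ln(A/B), where B is
the number of template pairs of length m within Chebyshev tolerance r
(self-matches excluded, pairs drawn from the N − m templates that admit an
extension) and A the number still within r at length m + 1.  Parameters:
m = 2, r = 0.2·STD of the series (population SD), coarse-graining scale
t = 2 (non-overlapping window means).  One value per channel, computed on the
preprocessed series.  If A or B is zero, or the tolerance collapses to zero
on a constant series, the value is undefined; it is reported as an `inf`
sentinel and affected trials are dropped from feature tables with a logged
warning rather than poisoning a classifier with infinities.

**Wavelet-packet band energy (E_i).**  Full 4-level decomposition with the
db4 wavelet (Mallat algorithm as implemented by PyWavelets).  Terminal nodes
are re-ordered from the natural (Paley) order to frequency order so node k
spans [16k, 16(k+1)) Hz; without this re-ordering band indices would not be
monotone in frequency.  E_i is the sum of squared coefficients of node i and
P_i = E_i / E_total.  The feature vector keeps the first four nodes
(0–64 Hz), which cover the conventional delta through gamma rhythm range;
higher nodes carry only noise after the 256 Hz low-pass.  Boundary handling
is periodic extension by default, which makes the decomposition exactly
energy-preserving for orthogonal wavelets (Parseval, verified to 0.1%);
symmetric extension is available in the config for signals where wrap-around
discontinuities matter more than exact energy bookkeeping.

Note a physical limitation: db4 has a wide transition band, so a pure tone
near a band edge leaks a few percent of its energy into the neighboring
node (a 10 Hz tone at 512 Hz puts ~95% in node 0 and nearly all the
remainder in node 1).  Band energies are therefore smoothed versions of the
ideal brick-wall band powers.

**Wavelet-packet entropy (WpEn).**  WpEn = −Σ P_i ln P_i over all 16 nodes
(natural logarithm; zero-probability nodes contribute 0), bounded by
[0, ln 16].  It is invariant to amplitude scaling of the signal, whereas E_i
scales with the squared amplitude — both behaviors are tested.

Entropy-unit convention: WpEn uses the natural log; the C4.5 information
measures use log base 2 (bits).  Both are kept as conventionally defined
rather than unified.

## C4.5 decision tree

Continuous attributes only (all features here are continuous); a split is
binary, `value ≤ threshold` left, with candidate thresholds at midpoints of
consecutive distinct sorted values, searched per node (standard C4.5
practice, rather than a one-shot global discretization).  The split criterion
is the gain ratio; candidates whose split information is zero (one-sided
partitions) are invalid.  `best_split` is an exhaustive argmax over all
(attribute, threshold) pairs, with a deterministic tie rule: lexicographically
smaller attribute name, then smaller threshold.  It reports "no split" when
the best achievable gain is zero — but tree *growth* accepts zero-gain splits
(`allow_zero_gain`), because parity-style label patterns (XOR) have
individually uninformative attributes yet are perfectly separable at depth 2;
this is what guarantees 100% training accuracy on any consistent dataset and
matches the fully-grown-tree requirement of the forest.  Leaves take the
majority class, ties resolved to the lexicographically smaller label.
Optional pessimistic-error pruning (0.5 continuity correction per leaf) is
available but off by default: the forest requires unpruned trees, and no
pruning parameters are standard for this stack.  Missing values are not
handled — the feature extractor never emits them, and vectors lacking a
tested attribute raise an error.

## Improved random forest

T trees (default 100), each grown on a bootstrap resample (|D| draws with
replacement); at every node m = ⌈√M⌉ attributes are drawn without
replacement and scored by

    Gain(A) / (SplitInfo_A(D) + a · r̄(A))

where r̄(A) is the mean absolute Pearson correlation between A and the other
drawn attributes and a ≥ 0 weights the redundancy penalty (default 1.0; the
constant is exposed because no canonical value exists).  Design choices:

- **|r| rather than signed r**: negative correlation is still redundancy; a
  signed penalty would *reward* anti-correlated attributes.
- **Reference set** = the node's drawn subset, with the correlation matrix
  computed once per tree on its in-bag rows.  Per-node recomputation on
  node-local rows was rejected: deep nodes hold a handful of rows, where
  sample correlations are noise, and the per-tree matrix keeps the cost at
  one O(M²) pass.
- **a = 0 reduction**: with the penalty off, the criterion is exactly the
  plain gain ratio; the test suite verifies node-for-node identical forests
  given identical RNG streams.
- **Vote weight Ac_tree** is the tree's accuracy on its out-of-bag rows.
  An unpruned tree scores ≈100% on its own bootstrap sample, which would
  collapse weighted voting into majority voting, so the in-bag reading of
  the weight is kept only behind `weight_on="in_bag"`; an empty OOB set
  falls back to in-bag accuracy with a warning.  With uniform weights the
  vote reduces exactly to the majority rule (verified exhaustively for up to
  5 trees).  Vote ties resolve to the lexicographically smaller class.

Per-tree RNG streams are spawned deterministically from `random_state`
(`numpy` SeedSequence), making a fitted forest bit-reproducible.

Both classifiers follow scikit-learn estimator conventions (get/set_params,
`fit`/`predict`/`predict_proba`/`score`, `classes_`, `feature_names_in_`)
without depending on scikit-learn at runtime, so they compose with sklearn
pipelines and model selection while remaining self-contained.

## Synthetic cohort

Real recordings for this task are not publicly available, so validation uses
a generator that emulates the *spectral* structure the features consume:

- Five rhythm bands — delta 0.5–4, theta 4.5–8, alpha 8.5–16, beta 16.5–32,
  gamma 32.5–60 Hz.  Each band contributes 8 sinusoids at evenly spaced
  frequencies across the band with ±40% spacing jitter and uniform random
  phases.  Even spacing (rather than i.i.d. frequency draws) avoids
  near-coincident sinusoids whose slow beating would inflate
  trial-to-trial band-energy variance far beyond what band-limited
  oscillatory activity shows.
- Class structure: happy trials are alpha-weighted
  (delta .30 / theta .20 / alpha .30 / beta .15 / gamma .05), angry trials
  beta-weighted (alpha .15 / beta .30, rest equal).  Emotional modulation of
  the alpha/beta balance is the canonical spectral signature in EEG affect
  research, and band-power contrasts are exactly what E_i/WpEn measure.
- Amplitudes: total oscillatory RMS 20 µV; background is 1/f-shaped noise
  (spectral exponent 1.0, the standard EEG background model) at 8 µV RMS.
- Cohort structure: per-subject multiplicative band-power jitter
  (log-normal, σ = 0.15), applied identically to both classes, emulates
  individual differences without moving class separability on average; a
  `separation` knob in [0, 1] shrinks the two class profiles toward their
  common mean — 0 yields identically distributed classes (the null used for
  chance calibration), 1 the full contrast.
- Defaults: 10 subjects × 80 trials (40 per class), 2 s per trial at
  1000 Hz, one channel (no channel count is canonical for this protocol;
  multi-channel trials are supported with per-channel feature
  concatenation).

What the generator does *not* emulate: eye-blink/EMG artifacts,
non-stationarity within a trial, event-locked transients, volume-conduction
correlations between channels, or any genuine neural dynamics.  Passing
tests on this cohort therefore demonstrate that the pipeline recovers known
band-power class structure under realistic noise and subject variability —
not that it would reach comparable accuracy on human recordings.

## Experiment protocol and problem sizes

Per subject: a stratified seeded shuffle split, half train / half test
(40/40 at the default 80 trials); a `sequential` first-half/second-half mode
is available for a literal fixed-order protocol.  Accuracy is the only
metric; per-cell test counts and an optional repeat mode (`n_repeats` with
distinct derived seeds) are provided because a single 40-item test set
carries ±8% binomial noise.  The validation suite runs the full
10-subject × 80-trial cohort once for the null calibration and averages ten
seeded cohort replicates for the signal-recovery checks; these sizes keep
the whole battery at a few minutes on one CPU while leaving the binomial
error of each grand mean (n = 400 per cell) near ±2.5%.

## Numerical choices

- Entropy terms use the 0·log 0 := 0 convention throughout.
- Gain-ratio comparisons use a 1e-12 tolerance; within tolerance the tie
  rule above applies, which also makes the exhaustive-oracle comparison in
  the tests exact.
- Sample-entropy match counting is vectorized over an (N−m)² boolean matrix;
  it is checked against a brute-force O(N²) loop implementation exactly
  (integer counts), not just to floating tolerance.
- Pearson correlation on zero-variance input is defined as r = 0 with a
  warning (a constant attribute is uninformative, not undefined-redundant).
- Segment CSVs store full-precision floats (`repr`) and are parsed with
  pandas' round-trip float parser, so write/read round-trips are exact.

## Known limitations

- Band energies inherit db4's soft band edges (see above); a longer filter
  (e.g. db8) would sharpen bands at the cost of longer minimum segments.
- The redundancy penalty uses linear correlation only; nonlinearly redundant
  attributes are invisible to it.
- The C4.5 implementation handles continuous attributes only (sufficient
  here); categorical multiway splits and missing-value fractioning are out
  of scope.
- With single-attribute families (MSpEn, WpEn), the forest's attribute
  sampling is inert and trees differ only through their bootstraps, so the
  ensemble's edge over the single tree is small for those families.
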