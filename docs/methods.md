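# Methods and numerical conventions

This note records every convention, default, and design decision that affects
numbers produced by the package, plus the rationale for the synthetic
generator and the reduced problem sizes used in the acceptance checks.

## Cross-entropy metrics

Both metrics compare templates (windows) of `m` consecutive points from one
z-normalized series against all templates of the other under the Chebyshev
distance with tolerance `r`.

Conventions:

- **z-normalization** uses the population (divide-by-N) standard deviation,
  so `r` is in SD units.  Constant or non-finite series raise
  `DegenerateSeriesError`; `N < m + 2` raises `SeriesTooShortError`.
- A template pair **matches when distance ≤ r** (inclusive).
- **Cross-SampEn** (canonical form): both template lengths use
  `i, j = 1 .. N − m`; matches are pooled over all template pairs at each
  length, and the value is `−ln(A/B)` with `A`, `B` the pooled counts at
  lengths `m + 1` and `m`.  It is symmetric in its arguments and
  nonnegative.  A `variant="literal"` (per-template average of
  log-probabilities, zero counts floored to one match) is provided for
  audit.
- Cross-SampEn degenerate cases (`on_no_matches="surrogate"`, the default):
  `B = 0` returns the resolution bound `2 ln(N − m)`; `A = 0` returns the
  surrogate upper bound `−ln((1/(N−m)²)/(B/(N−m)²))` (one fictitious match).
  `on_no_matches="inf"` returns `inf` in both cases.  Occurrences are
  logged.
- **Cross-ApEn**: `φ^m` averages over the `N − m + 1` length-m templates and
  `φ^{m+1}` over the `N − m` length-(m+1) templates — only that many exist,
  so the two averages use different denominators.  The metric is direction
  dependent; `cross_apen(u, v)` uses reference templates from `u`.  The
  **bias-max correction** (default) substitutes, for a zero-match
  length-(m+1) template, the floor probability `(N − m + 1)^{-1}`; a
  zero-match length-m template takes its own corrected length-(m+1)
  probability, and the final length-m template (which has no length-(m+1)
  counterpart) takes the floor.  `bias_zero` (zero terms contribute 0) and
  `none` (NaN with a warning on zero counts) are provided for audit.
- Because of the differing denominators, Cross-ApEn of a perfectly matching
  periodic pair is close to but not exactly zero (about −0.01 for an
  8-sample alternating pair); Cross-SampEn is exactly zero there.

### Optimized counting

`_kernels.match_counts` walks the template-distance matrix along diagonals,
maintaining the Chebyshev distance of a length-L template as a running
maximum, and histograms matches over all template lengths up to `l_max` and
all tolerances in one pass.  `grid_cell_values` turns those counts into every
(m, r) cell value for the default settings.  Counts are exact integers — the
optimized path is count-identical to naive enumeration, and the test suite
verifies value agreement with the brute-force oracle (`oracle.py`) to 1e-12
across the whole default grid.

## Preprocessing

- Band filters are linear-phase Hamming-window FIR designs applied
  forward–backward (zero phase, via FFT convolution with odd-extension
  padding equivalent to `scipy.signal.filtfilt` to ~1e-15).
- The default FIR order covers **3 cycles of the band's low edge**
  (`ceil(3·fs/low)`, rounded up to even).  This is deliberately modest; the
  order is configurable (`fir_order`), and the scaled validation runs use a
  sharper shared order (330 at fs = 100 Hz) so that narrow neighboring bands
  are well separated.
- Epochs are non-overlapping and contiguous; the trailing partial epoch is
  discarded.  Epochs containing a flat (zero-variance) channel are skipped
  when averaging coupling matrices, never zero-filled.

## Screening and grid selection

- One Kruskal–Wallis test (midranks, tie-corrected, chi-square p) per
  (band, channel-pair) on subject-level epoch-averaged values — never
  epoch-level values, which would inflate n.  All-identical values give
  (H, p) = (0, 1) by convention.
- BH-FDR correction is applied **within each band** across its connections
  (`fdr_scope="band"`; `"global"` pools all bands).  Reject iff adjusted
  p ≤ α.
- Directed (Cross-ApEn) matrices are symmetrized by averaging the two
  directions before testing; the statistical unit is the unordered pair.
- Grid selection counts significant connections summed over bands per
  (metric, m, r) cell and takes the argmax.  Ties break toward Cross-SampEn
  (always defined and symmetric), then smaller m (better-populated
  statistics), then larger r (smoother estimates).  If the best count does
  not exceed the α-level chance count, the result is flagged
  non-discriminative.

## Feature selection (FCBF)

- Features are discretized with equal-frequency rank bins
  (`⌈log₂ n⌉ + 1` bins by default); rank-based binning makes selection
  invariant under monotone transformations.  Ties share a bin.
- Symmetrical uncertainty `SU = 2·I(X;Y)/(H(X)+H(Y))` with natural-log
  entropies; `SU = 0` when either entropy is zero.
- FCBF keeps features with `SU(feature, class) > δ` (default δ = 0), ranked
  by decreasing SU with ties broken by canonical band order then feature
  name, and drops a candidate when an already-kept feature `F'` has
  `SU(F', F) ≥ SU(F, class)`.
- Caveat: SU estimates are noisy below roughly 10 samples per class —
  chance features can outrank genuinely predictive ones and knock them out
  through the redundancy rule.  The scaled end-to-end validation uses 12
  training subjects per group for this reason.

## Classification

- Patients (MCI / AD) are the positive class.  Features are z-scored with
  training-set statistics inside the fitted pipeline (no leakage).
- QDA with covariance shrinkage (`reg_param = 1e-6` by default); exactly
  singular class covariances escalate to strong shrinkage with a logged
  warning, or raise with a remediation hint when shrinkage is disabled.
- SVM: polynomial kernel, degree 3, cost 1, `coef0 = 1`, variance-scaled
  kernel coefficient.  Decision tree: Gini, no depth limit, minimum leaf 2,
  seed-controlled.
- Reports carry integer confusion counts and Acc / Se / Sp / PPV / NPV as
  percentages (2-decimal rounding for display, full precision internally).
  Zero-denominator metrics are reported as undefined, never 0.
  `reconstruct_confusion` inverts rounded Se/Sp percentages into the integer
  confusion matrix they imply at given group sizes.

## Synthetic cohort generator

The generator is a statistical test bed, not a physiological EEG model
(no 1/f background, no alpha peak, no volume conduction).  Each subject's
channel is, per band,

```
channel = [κ·s + (1 − κ)·n_c] / sqrt(κ² + (1 − κ)²)  summed over bands, + observation noise
```

with one shared source `s` per band per subject and independent
band-limited Gaussian channel noises `n_c`.

Two empirically-driven choices matter:

1. **The shared source is a stable rhythm** (sinusoid at a subject-specific
   frequency in the middle of the band, random phase), not filtered noise.
   Cross-entropy metrics respond to shared *pattern recurrence*, not linear
   correlation: mixing two Gaussian band-limited signals leaves Cross-SampEn
   nearly unchanged even at high mixing weights, whereas a regular waveform
   common to both channels lowers it reliably once it dominates (κ ≳ 0.6).
   The healthy-control baseline is therefore κ = 0.9, with patient effects
   κ − 0.15 (MCI, beta1) and κ − 0.25 (AD, theta and beta1) inside the
   sensitive range, so patients show *higher* cross-entropy in affected
   bands.  A per-subject κ jitter (SD 0.1) keeps the groups realistically
   overlapping: the milder MCI effect stays genuinely harder to classify
   than the AD effect.
2. **Generation-side band confinement is strict**: noise sources are
   filtered with a sharp FIR (transition ≈ quarter band width) over a
   passband inset 10% of the band width from each edge.  Without this, the
   group-dependent noise weight (1 − κ) of one band leaks through the
   analysis filters of adjacent bands and smears group effects across
   bands.

Subject seeds are spawned from the master seed (`numpy.random.SeedSequence`),
so cohorts are bitwise reproducible and subjects independent.  Generator
defaults mirror a realistic study design (19 channels at 200 Hz, 20/17
train/test subjects per group, 46 five-second epochs).

## Scaled validation problem sizes

The simulation-heavy acceptance checks run at reduced sizes chosen for
single-CPU runtime; these are this package's own choices:

- **Parameter recovery** (25 cohorts): 5 channels at 100 Hz, five bands
  (gamma dropped — its 70 Hz edge exceeds the 50 Hz Nyquist), 8 training
  subjects per group, 10 × 2-s epochs, analysis `fir_order = 330`.
  Checks that grid search selects Cross-SampEn with m = 1 in ≥ 80% of
  cohorts and that flagged connections concentrate (≥ 70%) in the effect
  bands.  Concentration is evaluated pooled over all cohorts' flagged
  connections: with a per-band shared rhythm, the pairs of one band are
  strongly dependent, so BH flags whole bands nearly all-or-nothing and a
  null band comes up fully flagged with probability ≈ α per cohort; pooling
  measures the discovery-level false fraction, which is what FDR controls.
- **End-to-end ordering** (50 cohorts): as above but 12 train / 17 test
  subjects per group and 5 × 2-s epochs, full pipeline per cohort.  Checks
  that HC-vs-AD test accuracy (mean over the three models, which avoids
  spurious ties from the coarse accuracy granularity of small test sets)
  exceeds HC-vs-MCI in ≥ 80% of cohorts and that both exceed chance.

## Known limitations

- The literal Cross-SampEn variant floors zero per-template counts and can
  be undefined when all templates match; it exists for audit only.
- Cross-ApEn values under `bias_max` are bounded but biased near zero for
  short series; comparisons should hold N fixed.
- The generator's rhythm-plus-noise model produces band-specific coupling
  differences detectable by cross-entropy; it does not attempt realistic
  EEG morphology, nonstationarity, or artifacts.
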