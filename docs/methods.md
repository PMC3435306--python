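# Methods

`maldiforest` implements a complete discovery pipeline for case/control
classification of low-molecular-weight (1–10 kDa) MALDI-TOF profile
spectra, together with a synthetic-cohort generator that makes every stage
testable against known ground truth. This note documents the models,
the defaults and why they were chosen, the numerical decisions, and what
the synthetic data can and cannot say about real cohorts.

## The synthetic cohort generator

Each spectrum is generated on a common m/z grid (default 1 Da steps over
1,000–10,000 Da) as

```
I(m) = t · ( Σᵢ Aᵢ fᵢ^{[case]} exp(−(m − cᵢ − jᵢ)² / 2σᵢ²) + b(m) + ε(m) )
```

with

* **peaks**: Gaussian with m/z-proportional width, `σᵢ = r·cᵢ`
  (`resolution_factor r = 0.002`), the simplest shape consistent with
  broad linear-TOF peaks. Default 153 peaks (148 background + 5 markers),
  matching the scale of the emulated experiment (35 cases, 23 controls).
* **centers**: drawn in log-m/z space, where the "≥ 4σ apart" constraint
  becomes a constant gap `u = −ln(1 − 4r)`; the slack beyond the mandatory
  gaps is split Dirichlet-uniformly. This yields the exact requested count
  with a guaranteed hard separation in one pass.
* **background amplitudes**: log-uniform over `peak_height_range`
  (default 5–50 intensity units).
* **markers**: multiplicative case/control fold changes
  (default 0.79, 0.90, 0.94, 0.96, 1.5). The case-group mean amplitude is
  exactly `FC ×` the control-group mean — noise-free cohorts reproduce the
  configured fold change to machine precision. Marker *base* amplitudes
  are set to `marker_delta / |FC − 1|` (default `marker_delta = 0.45`),
  i.e. every marker carries the same absolute case−control separation.
  This emulates a *discovered* panel: a panel reported by a screening
  study is by construction composed of peaks that were individually
  informative. If marker amplitudes were drawn like the background, the
  FC = 1.5 peak would dominate by two orders of magnitude in
  signal-to-noise — single-handedly saturating the classifier (making
  panel selection degenerate) — while the FC = 0.96 peak would be
  statistically invisible at n = 58. Amplitudes are floored at
  `2 × noise_sd` so every marker stays detectable on the mean spectrum;
  the FC = 1.5 marker therefore sits below the background height range,
  which is intentional.
* **baseline**: `b(m) = baseline_amplitude · exp(−(m − m₀)/decay)`
  (defaults 20 units, 1,500 Da), a smooth stand-in for the matrix-cluster
  chemical background that dominates low m/z.
* **noise terms**: additive Gaussian `ε` (`noise_sd = 0.5`), per-peak
  per-spectrum m/z jitter (`mz_jitter_sd = 1 Da`), and a log-normal
  multiplicative scale `t` (`tic_scale_sd = 0.2`). The scale is drawn once
  per *sample* and shared by its technical replicates: it models the
  preparation, which is what makes replicates cluster by sample in raw
  intensity space. It is exactly the variation TIC normalization removes.
* `noise_sd` and `marker_delta` were chosen together so each marker has a
  per-feature standardized separation of roughly 1.2–1.5 after peak
  quantification — individually informative but far from perfectly
  separating, the regime in which a published profiling classifier
  reporting ~77–80 % accuracy operates. The paper-scale defaults indeed
  produce full-set cross-validated accuracy near 80 %.

All randomness flows from one integer seed through a single
`numpy.random.default_rng` stream with a fixed draw order (centers →
marker assignment → amplitudes → per sample: scale; per replicate:
jitter, noise), so a cohort is bit-reproducible from its config.

**What the generator does not emulate:** isotope envelopes, adducts,
detector saturation, autocorrelated ("chemical") noise, mass-calibration
drift, batch effects, and — importantly — per-subject biological
covariance between analytes. Passing tests therefore demonstrate that the
pipeline recovers planted structure under idealized independence
assumptions; they do not certify performance on real CSF cohorts.

## Preprocessing

Fixed stage order: resample → QC → baseline correction → TIC
normalization → replicate averaging.

* **Resampling**: linear interpolation onto the common grid (default 1 Da
  over the simulation range). Monotone and local; values never leave the
  range of the neighbouring inputs.
* **QC** (before any intensity manipulation): exclude spectra with raw
  TIC < `min_tic` (default 1e−9, i.e. effectively only degenerate
  spectra) or Pearson correlation to the cohort mean < 0.5. Every
  exclusion is reported with its reason; a run in which nothing survives
  is an error, not an empty result.
* **Baseline**: rolling minimum over `window_da` (default 200 Da)
  followed by a moving average of the same width, clamped from above by
  the signal. On a pure exponential background the estimate is within 5 %
  of truth away from the edges; under a 10 Da-wide peak the corrected
  apex is within 10 % of its true height. Corrected intensities are
  clamped at 0 (they are physical).
* **TIC normalization**: rescale so intensities sum to `target_tic`
  (default 1.0); idempotent, exact to 1e−9 relative. An all-zero spectrum
  raises a QC-exclusion error rather than passing silently.
* **Replicates** are preprocessed independently and averaged per sample
  afterwards: classification is per patient, not per acquisition.

A known quantification bias: the windowed-maximum statistic includes the
residual of the baseline estimate (a few percent of the local background),
which attenuates the *ratio* estimate of low-amplitude peaks toward 1.
The absolute case−control separation is unaffected (the residual is
common to both classes), so classification and ranking are insensitive to
it; fold changes of peaks comparable in height to the baseline residual
are conservative.

## Peak detection and quantification

Peaks are found once, on the mean of the preprocessed spectra, then all
samples are quantified at the same positions.

* Candidates are strict local maxima of a lightly smoothed mean spectrum
  (moving average, default 5 Da — narrower than any peak, enough to kill
  one-point noise maxima).
* **Height** is the prominence above a local floor built like the
  baseline operator (rolling minimum + equal-width smoothing over
  `noise_window_da`, default 250 Da). A local-median trend was rejected:
  at high m/z, peaks are wide enough to fill most of any window, pushing
  the median above the valleys and making genuine peaks "negative".
* **Noise** is a robust scale estimate of the high-frequency residual
  (raw − smoothed): the local lower quartile of its absolute value,
  scaled by 3.1388 to a Gaussian sd. The classical MAD × 1.4826 was
  rejected after measurement: narrow low-mass peaks leak into the
  smoothing residual and inflate the MAD several-fold in crowded regions,
  hiding small genuine peaks. The lower quartile tolerates up to 75 %
  contamination. All filters use reflected edge padding; replicating a
  single boundary value across half a window collapses the edge noise
  estimate.
* Candidates with SNR ≥ `snr_min` (default 2) are thinned greedily,
  strongest first (equal heights keep the lower m/z), to a minimum
  spacing of `min_separation_da` (default 5 Da — true peaks can sit ~8 Da
  apart at the low-mass end under the 4σ rule). At a 2σ threshold some
  noise maxima are accepted by construction; on default noisy cohorts
  they act as additional null features and are eliminated by the
  classifier's feature ranking.
* Windows: half the distance to the nearest retained neighbour, capped at
  0.3 % of the peak mass. Peak ids are masses rounded to 2 decimals
  (collisions get `_b`, `_c`, … suffixes).
* **Quantification** (per sample, replicates averaged): the maximum
  baseline-corrected normalized intensity in the window (default), robust
  to small jitter; a trapezoidal `area` option is available.

## Classification, panel selection, validation

* **Random Forest**: 500 trees by default, `mtry = ⌊√p⌋`, bootstrap
  sampling with replacement; tree induction is scikit-learn's. On top of
  the fitted trees the package computes out-of-bag (OOB) vote fractions
  (share of a sample's OOB trees voting "case"), the OOB error under the
  strict major-vote rule (case iff fraction > 0.5; exactly 0.5 is
  control), and Breiman-style mean decrease in accuracy: per tree, the
  drop in OOB accuracy when one feature's OOB values are permuted;
  averaged over trees, with a z-score = mean / SE over trees. Features a
  tree never splits on contribute an exact 0.
* **AUC** is computed on vote fractions by midrank concordance
  (ties count ½); the ROC uses "case iff score > cutoff", one point per
  distinct cutoff from above the maximum to below the minimum, and its
  trapezoidal area equals the rank AUC identically.
* **Repeated stratified 10-fold CV**, 10 repetitions: every sample is
  tested exactly once per repetition, so a 58-sample cohort yields 580
  pooled predictions (350 case, 230 control). Metrics are computed on the
  pooled predictions (accuracy, sensitivity, specificity as percentages
  to one decimal), the AUC on the pooled vote fractions. Any feature
  selection runs inside the training fold only.
* **RFE**: fit, compute MDA, remove every feature with MDA *strictly
  below* the median of the current set (features exactly at the median
  survive — this makes the schedule deterministic: from 153 distinct
  values, 153 → 77 → 39 → 20 → 10 → 5 → 3 → 2), record the set, repeat
  until fewer than two features would remain or nothing is removed. Each
  recorded set is scored by repeated CV and the highest pooled AUC wins;
  ties break toward the smaller set.
* **Nested validation**: the honest generalization estimate reruns the
  elimination schedule from scratch inside every training fold and keeps
  the recorded set whose size fraction is closest to the globally
  selected one. With the selector disabled this reduces exactly to plain
  repeated CV.
* **Seeds**: one pipeline seed deterministically derives per-repetition,
  per-fold and per-forest seeds via named `SeedSequence` streams (all
  below 2³¹).

## Univariate screening

Two-tailed Wilcoxon rank-sum per feature: exact enumeration when the
smaller group has ≤ 8 observations and the pooled values are tie-free,
otherwise the normal approximation with midranks, tie correction and
continuity correction (at the 35/23 study scale the approximation regime
always applies). When the statistic sits exactly at its null expectation
the two-sided p is 1 by symmetry. The worst-case disagreement between the
two modes at the 8-vs-8 boundary is just over 0.01, at the distribution
centre. Fold change is the ratio of class means (case/control; < 1 means
downregulated), undefined when the control mean is non-positive.
Tiers use raw p-values: ≤ 0.05 significant, ≤ 0.1 trend. No multiple-
testing correction is applied to the tiers; a Benjamini–Hochberg column
is emitted as clearly supplementary output. Constant features get p = 1
with a warning. The same routine accepts external wide concentration
tables (e.g. ELISA or MRM panels in ng/ml).

## Problem sizes used by the test suite and acceptance script

The library defaults (500 trees, 10×10 CV) are what an analysis run
should use. The demonstration scale used by `tests/` and
`scripts/acceptance.py` reduces the forests to 60–100 trees for CV
scoring and 300 for importance ranking, and scores RFE candidate sets
with 3 CV repetitions over 10 simulation seeds; criterion-level
quantities that depend on CV bookkeeping (the 580/350/230 structure) keep
the full 10 repetitions. Null-calibration statements are made on the mean
pooled AUC over seeds, because a single 58-sample null AUC has a standard
deviation of about 0.08.

## Known limitations

* The generator's independence assumptions (uncorrelated noise, no
  between-analyte covariance) make the classification task cleaner than
  real CSF profiling; recovery results are upper bounds in that sense.
* Detection at `snr_min = 2` deliberately admits borderline noise maxima;
  raise the threshold for conservative peak lists.
* Fold-change estimates of peaks near the baseline-residual scale are
  attenuated toward 1 (see above).
* The mzML support is minimal (MS1 profile spectra, zlib/uncompressed,
  32/64-bit floats) — sufficient for round-tripping this package's own
  exports and readable by standard tools, not a general-purpose reader.
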