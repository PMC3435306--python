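# maldiforest

Biomarker discovery from MALDI-TOF profile mass spectra, for the
case/control screening setting typical of body-fluid proteome profiling
(for example, low-molecular-weight cerebrospinal-fluid profiles of ALS
patients vs controls at the scale of a few dozen samples).

The package covers the full path from raw profile spectra to a validated
biomarker panel:

1. **Simulation** — labeled synthetic profile cohorts (Gaussian peaks with
   m/z-proportional width, exponential chemical background, additive
   noise, per-sample intensity scale, m/z jitter, technical replicates)
   with full ground truth, so every downstream stage is testable without
   any external data.
2. **Preprocessing** — resampling to a common grid, QC filtering,
   rolling-minimum baseline correction, total-ion-count (TIC)
   normalization, replicate averaging.
3. **Peak detection and quantification** — peaks found on the cohort mean
   spectrum by local signal-to-noise, every sample quantified by the
   windowed maximum, yielding a samples × peaks feature matrix.
4. **Classification and panel selection** — a Random Forest with
   out-of-bag (OOB) vote fractions and permutation importance (mean
   decrease in accuracy, MDA). Panel selection is recursive feature
   elimination that removes, at each step, all peaks with MDA strictly
   below the median MDA, and picks the candidate set with the highest
   cross-validated AUC. Performance is estimated by repeated stratified
   10-fold cross-validation (every sample tested once per repetition;
   with 10 repetitions a 58-sample cohort yields 580 pooled predictions),
   with an optional fully nested variant that reruns the selection inside
   every training fold.
5. **Univariate screening** — per-peak two-tailed Wilcoxon rank-sum tests
   and fold changes (case mean / control mean; < 1 means downregulated),
   with significance tiers p ≤ 0.05 ("significant") and p ≤ 0.1 ("trend");
   also applicable to external concentration tables (ELISA/MRM panels).

At its core: a sample's ensemble vote fraction ∈ [0, 1] acts as a degree
of class membership; classes are assigned by strict major vote (> 50 %),
the ROC/AUC is computed on the vote fractions themselves
(AUC = P(random case outranks random control), ties counting ½), and
feature importance is Breiman's MDA — the loss of OOB accuracy when a
feature's out-of-bag values are permuted — reported raw and as a z-score
(mean / SE over trees).

See `docs/methods.md` for the model details, defaults, numerical
decisions and limitations.

## Worked example

Simulate a cohort at the default study scale (35 cases, 23 controls, 153
planted peaks of which 5 carry fold changes 0.79–1.5), run everything,
and write all artifacts plus `report.json`:

```
$ maldiforest run-all --outdir run --seed 7 --trees 150 --repetitions 3
peaks: 183; full AUC 0.831; panel size 23 AUC 0.939; report at run/report.json
```

What the numbers mean: detection at the default 2σ threshold found the
153 planted peaks plus ~30 noise-level maxima (183 features). Using all
features, pooled repeated CV gives AUC 0.831. The median-MDA elimination
recorded candidate sets of sizes 183 → 92 → 46 → 23 → 12 → 6 → 3 → 2 and
selected the 23-peak panel (CV-AUC 0.939, accuracy 88.5 %); the selected
panel contained all 5 planted markers (`report.json` →
`truth_recovery`). The honest nested estimate — selection redone inside
every training fold — is AUC 0.873, the expected step down from the
optimistically selected 0.939. The univariate screen called 12 peaks
significant (p ≤ 0.05) and 11 a trend (p ≤ 0.1).

Each stage can also run standalone on the previous stage's files
(`maldiforest simulate | preprocess | detect | classify | stats`), and the
same pipeline is available as a library:

```python
from maldiforest import SimConfig, generate_cohort, detect_peaks, quantify, rfe
from maldiforest.preprocess import preprocess_cohort

cohort, truth = generate_cohort(SimConfig(seed=7))
prep = preprocess_cohort(cohort)
peaks = detect_peaks(prep.mean)
features = quantify(prep.cohort, peaks)
trace = rfe(features, seed=7)
print(len(trace.selected_set), trace.selected_cv.auc)
```

Measured cohorts enter through the same door: two-column text spectra
(m/z, intensity) or mzML plus a `samples.csv` sheet
(`spectrum_id,sample_id,replicate,label`), via
`maldiforest run-all --input <dir>`.

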