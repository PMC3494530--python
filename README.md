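# seldiflow

A tested, reusable pipeline for SELDI-TOF-MS biomarker discovery in
case/control studies, built around the design of ovarian-tumor serum and
tissue profiling on ProteinChip arrays (CM10 / Q10 surfaces; benign, LMP
and cancer patient groups; a training cohort plus an independent
validation cohort measured later).

It is aimed at statisticians and bioinformaticians who need the full
chain — from raw m/z–intensity profiles to honestly cross-validated
classification — with every training-derived quantity frozen before it
touches validation data, so that reported validation accuracy cannot be
inflated by information leaks.

## What it does

- **Synthetic cohorts** (`simcohort`): SELDI-like spectra on a TOF grid
  (spacing ∝ √(m/z)), Gaussian peaks with FWHM = m/z / R, an exponential
  chemical-noise baseline, additive detector noise, per-spectrum intensity
  scale jitter, stratified chip allocation with technical replicates, and
  planted marker peaks with known fold changes — ground truth for every
  downstream test.
- **Pre-processing** (`preprocess`): morphological baseline correction
  (rolling minimum + smoothing over a window in Da) and total-ion-current
  normalization: each spectrum is scaled so its mean intensity over the
  normalization mass window (e.g. 2–20 kDa for serum CM10) equals the
  cohort-mean target — or a *frozen* target when preprocessing validation
  data.
- **Peak detection** (`peaks`): two-pass S/N detection in the ProteinChip
  parameterization (first pass S/N, min peak threshold % of spectra,
  cluster mass window % of mass, second pass S/N; serum defaults
  5 / 25 / 0.3 / 2, tissue 5 / 5 / 0.3 / 2), greedy cross-spectrum peak
  clustering, and intensity-matrix extraction with the half-minimum
  substitution for non-positive values followed by log2.
- **Quality control** (`qc`): technical-replicate reproducibility
  (Pearson r, median CV), per-peak two-way ANOVA for chip effects
  (type-II sums of squares), complete-linkage hierarchical clustering on
  1 − Pearson correlation with automated outlier fencing, column
  z-scoring.
- **Differential expression** (`diffexpr`): empirical-Bayes moderated
  t-test — per-peak variances shrunk toward a prior fitted by moment
  matching on log variances,

      s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d),
      t̃_g  = (x̄_A − x̄_B) / (s̃_g · √(1/n_A + 1/n_B)),

  with d₀ + d degrees of freedom — plus one-way F for three classes,
  Benjamini–Hochberg FDR control per comparison, fold changes
  FC = 2^(Δ log₂ means), and cross-experiment peak matching by relative
  mass tolerance.
- **Classification** (`classify`): DLDA (Gaussian classifier with a
  shared diagonal covariance) and linear SVM, evaluated over hundreds of
  class-balanced random training/test splits. Inside every training set
  a nested 5-fold cross-validation selects the number of top-|t| (or
  top-F) peaks from {5, 10, …, 50} and the SVM cost — with the ranking
  recomputed inside each inner fold — giving nearly unbiased outer error
  estimates.
- **Frozen validation** (`freeze_validate`): the normalization target,
  peak-cluster windows, per-peak substitution constants and the fitted
  classifier are serialized into a self-contained JSON bundle and applied
  unchanged to an independent cohort; no validation-derived number enters
  any step.

## Worked example

The bundled demonstration configuration simulates a 24-patient serum-like
training cohort (12 cancer / 12 benign, one CM10 surface, 6 planted
markers at fold changes 2.5 and 0.4, technical replicates on 1/8 of the
samples) plus a 12-patient validation cohort from the same generative
model, and runs the whole pipeline:

```bash
seldiflow run --out demo/
```

The generated `demo/report.md` contains (numbers printed by the run with
the default seed 17):

```
- replicate pairs: 3 (median r = 0.9986, median CV = 0.0636)
- clusters with chip effect at p<0.05: 13.0%

benign vs cancer: 6 of 46 peaks differentially expressed (adjusted p < 0.05)

| m/z  | adjusted p | FC   |
| 8713 | 4.8e-10    | 3.41 |
| 3030 | 2.5e-09    | 0.31 |
...

| model | accuracy | sens  | spec  |
| DLDA  | 100.0    | 100.0 | 100.0 |

Independent validation (frozen pipeline):
accuracy 100.0%, sensitivity 100.0%, specificity 100.0%
```

Reading: the 46 detected peak clusters include all 46 planted peaks; the
6 significant peaks are exactly the 6 planted markers (FC above 1 =
higher in cancer); with strong planted effects, double-CV and frozen
validation both reach 100% accuracy. Smaller effect sizes (the
`marker_fold_changes` and `bio_sd` settings) give the intermediate
accuracies typical of real serum data.

Other entry points: `seldiflow simulate | qc | de | classify | validate |
report`, and the library API (`seldiflow.generate_cohort`,
`seldiflow.double_cv`, `seldiflow.apply_frozen`, …).

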