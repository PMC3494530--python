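# Methods

This note documents the models, algorithms and numerical choices behind
seldiflow, what the synthetic-data generator does and does not emulate,
and the problem sizes used by the verification suite.

## The analysis problem

Surface-enhanced laser desorption/ionization time-of-flight mass
spectrometry (SELDI-TOF-MS) measures, per sample and chip surface, an
intensity profile over m/z. A biomarker-discovery study asks which peaks
differ between patient groups (here benign ovarian tumor, tumor of low
malignant potential, cancer) and how well the groups can be classified
from the peak profile. Two failure modes dominate this literature:
technical artifacts (chip effects, baseline drift, intensity scale
differences) mistaken for biology, and information leaks from test or
validation data into preprocessing or model selection. The pipeline is
organized around defeating both.

## Synthetic cohorts

The generator produces the study design end to end: classes with
configurable sizes (defaults 53/18/57 for a serum-like training cohort,
16/5/21 validation, 40/20/24 tissue-like), one spectrum per sample per
surface, stratified chip allocation, technical replicates, and planted
markers with known fold changes.

Signal model per spectrum:

    I(m) = s · [ Σ_j 2^{a_j} · exp(−(m − μ_j)² / 2σ_j²) + A·e^{−m/τ} + c ] + ε(m)

- **Grid**: equal steps in time of flight, m/z = t², so spacing grows as
  √(m/z); default 8 000 points over 1 500–20 000 Da (serum) or
  2 000–50 000 Da (tissue).
- **Peaks**: FWHM = m/z / R with R = 400 — linear-TOF resolution is
  roughly constant, so widths scale with mass. Positions are log-uniform
  with a minimum relative spacing of 1.2%, which keeps planted peaks
  resolvable and unambiguous against the 0.3% clustering window. Base
  log2 amplitudes are Uniform(3, 6.5).
- **Class effects** act on log2 amplitudes: cancer markers are shifted by
  log2(FC); the LMP class follows a preset — identical to benign
  ("benign-like", matching the serum finding that LMP and benign serum
  are indistinguishable), halfway ("intermediate"), or its own shift
  pattern ("distinct", the tissue scenario).
- **Biological spread** `bio_sd` (default 2/3 log2 units) is the
  between-sample within-class sd, shared between a sample's technical
  replicates. At log2 FC = 1 this gives effect size d ≈ 1.5. The spread
  is a required ingredient of any realistic cohort even though it is easy
  to forget: without it, replicate averaging and moderated-variance
  shrinkage have nothing to act on.
- **Technical structure**: per-spectrum multiplicative scale factor
  exp(N(0, 0.2)) (what TIC normalization must undo); per-chip additive
  log2 offsets N(0, 0.3) on a random 20% of peaks (what the chip ANOVA
  must detect); baseline A = 50, τ = 3 000 Da, offset c = 1; detector
  noise sd 0.5 + 1e−5·m/z.
- **Chips**: capacity 8 spots (A–H). Within each class, shuffled samples
  are dealt round-robin over chips, so per-chip class counts deviate from
  proportionality by at most one sample. A fraction of samples (default
  1/16 ≈ one per two chips) is duplicated on a free spot of the same chip
  when available — intra-chip technical replicates.
- **Reproducibility**: all randomness flows from one seed through
  `SeedSequence` spawn keys indexed by (purpose, surface, sample), so any
  subset of the cohort regenerates identically regardless of order. A
  separate `structure_seed` pins the peak landscape so a validation
  cohort can share the training cohort's generative model while drawing
  new patients.

Not emulated: isotope structure, adducts, matrix clusters, detector
saturation, mass-calibration drift between cohorts, peak-shape asymmetry.
Consequently, passing tests demonstrate the statistical machinery —
normalization, detection, error control, leak-freedom — under a faithful
noise/design model, not robustness to every instrumental artifact of real
spectra.

## Pre-processing

**Baseline.** Rolling minimum over a window expressed in Da (converted to
point ranges locally on the non-uniform grid via a sparse-table range-min
query), then a moving average of the same width; default window 200 Da.
This is a morphological envelope in the spirit of vendor baseline tools:
it maps a constant spectrum to zero exactly, passes an isolated peak
essentially unchanged when the window exceeds the peak width, and removes
an A·exp(−m/τ) baseline to within a few percent of A (bias ≈ window/2τ).
Corrected intensities may be negative; the matrix-extraction stage
applies the half-minimum substitution.

**TIC normalization.** TIC here is the *mean* baseline-corrected
intensity over the normalization mass window — 2–20 kDa (serum CM10),
1.7–20 kDa (serum Q10), 2.5–50 kDa (tissue CM10), 2–50 kDa (tissue Q10).
Every spectrum is multiplied by target/TIC. On a training cohort the
target is the cohort mean of the TICs; on a validation cohort it is the
*frozen* training target, so validation spectra get per-spectrum
coefficients against a training-derived constant and the validation
cohort mean is never computed. Spectra with non-positive TIC are flagged
as QC failures rather than scaled by a negative factor.

**Replicate averaging.** Technical replicates are averaged on the log2
matrix scale (arithmetic mean per peak), after extraction, before any
statistics. Instrument m/z calibration is out of scope; masses are taken
as given.

## Peak detection and the intensity matrix

Noise is estimated robustly: the spectrum is detrended with a short
(31-point) moving median, and 1.4826 × MAD of the detrended signal is
computed in contiguous blocks spanning 2% of the local m/z (at least 50
points), then interpolated to every grid point and floored at 1e−12. The
MAD is used rather than the sd so that peaks do not inflate their own
noise estimate.

Candidates are strict local maxima of the 3-point-smoothed trace. The
S/N numerator is the *median-detrended* height — this stops the smooth
percent-level residual left by baseline correction on a steep low-mass
baseline from producing systematic false candidates — while the reported
candidate height remains the corrected intensity.

Clustering is greedy: repeatedly seed at the candidate m/z whose relative
window (± 0.3% of mass by default; the "% of mass" parameter is read as a
half-width, with a total-width mode available) captures the most
candidates, ties toward lower m/z; absorb the window; center = median
absorbed m/z. Clusters supported by fewer than the minimum peak threshold
(25% of spectra for serum, 5% for tissue) are discarded on *first-pass*
support; a second pass at S/N 2 then fills in support for surviving
clusters but can never create one — the documented two-pass semantics.

Matrix values are the maximum corrected, normalized intensity inside the
cluster window (so spectra without a first-pass candidate still get a
value); per cluster, values ≤ 0 are replaced by half the minimum positive
value of that cluster (a frozen training constant when applying a frozen
pipeline), then log2. Cluster ids are "M⟨rounded m/z⟩" with "a"/"b"
suffixes on rounding ties. A combined CM10/Q10 dataset is the column
union with surface-prefixed ids.

## Quality control

- Spectrum screen (in place of manual visual inspection): fail when the
  baseline carries > 90% of the raw TIC or the corrected TIC is
  non-positive.
- Replicate pairs: Pearson r of log2 profiles and the median per-peak
  coefficient of variation on the natural scale.
- Chip effects: per-peak two-way ANOVA with patient status and chip as
  main effects, type-II sums of squares (allocation is stratified but not
  perfectly balanced); the status × chip interaction is tested only when
  within-cell replication leaves residual degrees of freedom, otherwise
  omitted with a note. Implemented as vectorized least-squares over all
  peaks at once and verified against statsmodels' `anova_lm(typ=2)`.
- Outliers: complete-linkage clustering on 1 − Pearson correlation; a
  sample is flagged when its first merge height exceeds the 75th
  percentile of merge heights + 3 × IQR (configurable). Constant rows
  have undefined correlation and are flagged and excluded from the tree.
  Excluded samples are tracked in the QC report and absent from all
  downstream stages; counts reconcile exactly.
- Heatmap-style column z-scores use the sample sd (ddof = 1).

## Differential expression

The moderated t follows the standard empirical-Bayes hierarchical model:
per-peak variances s² with d residual df are modeled as scaled-F around a
prior (d₀, s₀²) estimated by moment matching of log s² using the
digamma/trigamma closed forms (trigamma inverted by Newton iteration).
When the observed variance of log s² does not exceed the sampling floor,
d₀ = ∞ and the posterior variance is s₀² everywhere; when all variances
are exactly equal, (∞, common value) is returned directly. d₀ = 0 is
admitted as the classical pooled-t limit, so the unmoderated test is a
special case rather than separate code. P-values use a t distribution
with d₀ + d df (capped at 1e6 when infinite). The estimator is verified
against the reference R implementation (limma's `fitFDist`) to 1e−6 on a
fixed fixture.

Fold change is reported on the natural scale as 2^(Δ log2 means), i.e. a
geometric-mean ratio — an interpretation, since published tables usually
leave FC undefined. Benjamini–Hochberg adjustment is applied within each
pairwise comparison (per surface); three-class screening uses one-way F.
Cross-experiment peak matching (e.g. serum vs tissue) is greedy
nearest-neighbor on relative mass with the clustering window (0.3%) as
the default tolerance; the tolerance is exposed because published
matching rules are typically unstated.

## Classification

"Balanced" random splits are stratified: per-class training counts follow
class proportions via largest-remainder rounding (a forced-equal mode
exists). DLDA uses class means, a pooled within-class diagonal variance
(Σ(n_k − 1) denominator) and equal priors; prediction is the
diagonal-Mahalanobis argmin with ties toward the class earlier in sorted
order. The SVM is linear with cost grid {0.01, 0.1, 1, 10, 100}.

The double CV: for each of the (default 500) outer splits, a stratified
5-fold CV on the training part alone scores every (k, cost) pair with the
feature ranking recomputed inside each inner fold — ranking once per
outer training set would leak across inner folds. Ties prefer smaller k,
then smaller cost. The winner is refit on the whole outer training part
with features ranked on that part, and evaluated once on the untouched
test part. Aggregates are unweighted means over splits; per-split values
are kept. For three classes only accuracy and the row-percentage
confusion matrix are reported, since sensitivity/specificity are
two-class notions.

## Frozen validation

The frozen bundle contains the normalization target, baseline window and
mass window, cluster definitions, per-cluster substitution constants, the
empirical-Bayes hyperparameters and the serialized classifier (DLDA
parameters, or the hyperplane of a binary linear SVM) with its selected
features, plus a SHA-256 fingerprint of the canonical JSON. Applying it
performs baseline correction, per-spectrum normalization against the
frozen target, extraction at the frozen windows only (no new detection),
imputation with the frozen constants, and prediction — and never mutates
the bundle (asserted byte-for-byte in tests). The bundle carries no
instrument-calibration coefficients because calibration is out of scope.

## Verification problem sizes

The acceptance script and test suite run, per seed: 1 000 DLDA oracle
fixtures; 10 000 BH vectors against a brute-force step-up; null
calibration on 2 000 peaks at n = 20/20; FDR on 100 runs of 150 peaks
with 10% signal; double-CV chance-level on 100 × 150 pure noise with 200
splits and k ∈ {5…50}; marker recovery through the full spectrum-level
pipeline on 50 cohorts of 30 + 30 samples (a scaled-down serum design;
60 peaks of which 10 markers at log2 FC 1, bio sd 2/3, i.e. d ≈ 1.5);
peak fidelity on 100 spectra with 20 peaks at S/N ≈ 10; frozen-validation
generalization over 30 train/validate cycles at d = 2; and a double demo
run compared by checksum. These sizes were chosen to estimate each
quantity stably on a single CPU in well under a minute each.

## Known limitations

- The baseline estimator under-tracks sharp curvature within its window;
  the detrended S/N numerator compensates at detection time, but very
  wide peaks (width ≳ window) would be partially eaten by the envelope.
- The noise model is additive Gaussian; count-like (Poisson) behavior at
  very low intensity is not modeled.
- Frozen SVM bundles support binary problems only (DLDA covers the
  three-class case).
- The "min peak threshold" is applied to first-pass support only; vendor
  semantics on this point are not publicly documented, and the
  alternative (post-second-pass support) would retain strictly more
  clusters.
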