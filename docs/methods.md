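# Methods

`msipredict` implements a complete analysis chain for outcome prediction
from MALDI mass-spectrometry-imaging (MALDI-MSI) tryptic-peptide profiles of
head-and-neck squamous cell carcinoma (HNSCC) tissue: spectrum
preprocessing, univariate ROC screening, L1-penalized logistic
classification with patient-grouped cross-validation, cross-cohort
transfer, and peptide/protein annotation — together with a synthetic cohort
generator that provides ground truth for every stage.  This note documents
the models, the parameters that matter, the numerical choices, and what the
synthetic experiments do and do not establish.

## Data model

An MSI acquisition yields one spectrum per 50 µm pixel of a tissue section.
After vendor-style export all spectra share one m/z axis, so the in-memory
shape is a dense table: `MSIDataset` holds the axis, an
`n_spectra x n_channels` intensity array, per-spectrum metadata
(patient, cohort, slide, x, y, and an `roi_flag` marking pixels inside the
pathologist-annotated tumor region), and a patient table with the two-year
outcome label — `NED` (no evidence of disease) or `RecPro`
(recurrence/progression).  After peak alignment the data collapse to an
`AlignedFeatureMatrix` of spectra x features with strictly increasing
centroid m/z values and a ±0.2 Da alignment half-width.

## Preprocessing

The chain runs in a fixed order, recorded in the provenance log:

1. **Top-hat baseline removal** — the signal minus its morphological
   opening with a flat structuring element (`structure_width` points, odd).
   The opening tracks the slowly varying chemical baseline under the peaks;
   the residual is non-negative and pointwise ≤ the input, and is invariant
   to additive offsets.  For profile-resolution spectra a width of ~200
   points is typical; the channelized synthetic data use width 5.
2. **TIC normalization** — each spectrum is scaled to unit total ion count,
   removing per-pixel acquisition variation (and any multiplicative
   per-slide batch factor).  All-zero spectra are flagged and excluded.
3. **Peak detection and alignment** — local maxima of the dataset mean
   spectrum above a prominence threshold become feature centroids (default
   threshold: 3x the median of the mean spectrum, a scale-free cut above
   the noise floor); maxima closer than twice the alignment tolerance are
   merged to the more intense one.  The per-spectrum feature value is the
   windowed **maximum** within centroid ±0.2 Da — consistent with
   centroided reflectron-TOF data; a windowed sum would also be defensible
   but is not what vendor pipelines report for sharp peaks.

Feature **down-sampling (2x)** for the all-features model averages
consecutive non-overlapping column pairs (new centroid = pair midpoint);
an odd trailing column is kept unchanged, which preserves information and
gives 711 → 356 columns.

**Per-patient standardization** z-scores each feature within each patient
(population SD, ddof = 0; zero-SD features → 0), removing systematic
between-patient intensity differences.  Two points matter:

* The statistics come only from the patient's own spectra, so standardizing
  before cross-validation leaks nothing across patients.
* The statistics are computed over the patient's **whole section** (tumor
  plus surrounding non-tumor tissue), while screening, model fitting and
  evaluation are restricted to `roi_flag` pixels.  This is not a detail: if
  the per-feature mean were computed on exactly the analyzed tumor spectra,
  every patient's centered feature would sum to zero, the class-conditional
  training means would vanish identically, and the gradient of the weighted
  logistic likelihood at zero coefficients would be exactly zero — the
  convex fit would provably return the all-zero model regardless of the
  data.  Computing the normalization over the full section (as an
  export-time pipeline naturally does) retains the tumor-vs-section
  contrast that carries the class signal.  We verified the degenerate
  behaviour empirically before adopting this design.

## Univariate screening

For each aligned feature, the RecPro-vs-NED ROC-AUC is computed on a
class-balanced spectrum subsample (the larger group is down-sampled without
replacement to the smaller group's size; seeded and logged).  Orientation:
AUC = P(random RecPro spectrum > random NED spectrum) + 0.5·P(tie), equal
to the Mann-Whitney U divided by n₁n₂, so peptides *lost* in recurrent
tumors show AUC < 0.5.  A two-sided Wilcoxon rank-sum p-value accompanies
each AUC — exact enumeration for n₁+n₂ ≤ 12, tie- and continuity-corrected
normal approximation otherwise — followed by Benjamini–Hochberg correction
(Bonferroni selectable).  A feature is **discriminatory** when AUC > 0.7 or
AUC < 0.3 (strict) *and* adjusted p < 0.001.  Because the balanced
subsample is a random draw, `screening_stability` reports per-feature
selection fractions over repeated draws.

The rank-sum p-values treat spectra as independent although pixels within a
patient are correlated; at ~100k spectra they are therefore
anti-conservative and act mostly as a gate behind the AUC thresholds —
matching how such screens are used in practice.

## Outcome classification

`OutcomeModel` / `OutcomeCVResults` follow the model/results convention.
The classifier is logistic regression with an L1 penalty,

  minimize  (Σᵢ wᵢ ℓᵢ(β, b)) / Σᵢ wᵢ  +  λ‖β‖₁,

with inverse-class-frequency weights wᵢ, unpenalized intercept b, and
per-spectrum log-loss ℓᵢ.  The solver is saga (liblinear penalizes the
intercept and was rejected); λ maps to the solver's `C` as 1/(λ·n) because
the balanced weights sum to n.  Convergence: gradient-based tolerance 1e-4,
max 3000 iterations; non-convergence is flagged on the results object, not
raised.  The regularization strengths reported for the clinical runs (7000
for all features, 30 for the restricted subset) are on a library scale tied
to the raw spectrum count and are kept as configuration comments; the
default λ = 0.03 was calibrated once on the desk-scale synthetic cohort and
then frozen.

**Cross-validation** is 5-fold, grouped by patient and class-stratified at
patient granularity: within each outcome class, patients are shuffled
(seeded) and dealt round-robin to folds, so fold sizes differ by at most
one patient per class and no patient ever appears in both train and test
(asserted at run time).  With 11 NED patients stratification is necessarily
approximate.  Two feature modes mirror the published design: `all_mz`
(2x down-sampled full matrix) and `restricted` (the screened subset).

**Evaluation.**  NED is the positive class: sensitivity = NED recall,
specificity = RecPro recall, balanced accuracy = their mean (asserted as an
identity on every emitted row), ROC-AUC from P(NED).  Spectra-level metrics
pool the test-fold tumor spectra; patient-level calls sum each patient's
per-spectrum class probabilities and take the argmax (exact ties →
RecPro — the conservative call when the model is used to flag risk).  A
patient's majority vote counts as correct only when strictly more than 50%
of their spectra are individually correct; exactly 50% is a miss.  Each
split's row is reported alongside the arithmetic mean over splits.

**Coefficient stability** reports features with nonzero coefficients in at
least two splits, their sign consistency (all nonzero coefficients share a
sign) and mean coefficient.  **Cross-cohort transfer** applies every
split's model to a second cohort projected onto the training feature
centroids and standardized on its own patients.

## Synthetic cohorts

The generator emulates the study conditions so that every stage is testable
without the (undeposited) clinical data.  Defaults are the desk-scale
training-cohort analogue: 31 patients (20 RecPro / 11 NED), 180–220 tumor
spectra per patient, 700 features in m/z 600–3200 with 30 planted signal
features at standardized effect 1.0, contiguous subclone patches covering
20% of tumor pixels, 4 slides, and a 40% non-tumor margin.  The transfer
analogue has 29 patients (15/14).  A full-scale run (~3500 spectra/patient)
is a parameter change, not a different code path; the desk scale keeps the
complete test suite within minutes on one CPU.

Log-intensity of pixel i, patient p, slide s, feature j:

  log I = base_j + b_s + u_pj + f_j(x, y) + c_ij + e_ij

* `base_j ~ N(5, 1)` — typical log-abundance; shared between cohorts
  generated on the same feature space (the same peptides have the same
  typical abundances), which also fixes the TIC composition.
* `b_s ~ N(0, 0.10)` — per-slide batch factor, identical across features,
  so TIC normalization removes it (as for a real acquisition batch).
* `u_pj ~ N(0, 0.15)` — patient-feature random effect (biological
  between-patient variation).
* `f_j` — Gaussian random field (smoothed white noise, correlation length 2
  pixels), demeaned and scaled to SD 0.30 per section: within-section
  texture only; patient-level offsets belong to `u_pj`.  Features planted
  in pairs for the same synthetic protein share one field per patient, so
  peptides of one parent protein co-localize — this is what gives the
  two-peptide validation rule true positives.
* `e_ij ~ N(0, 0.35)` — pixel noise.
* `c_ij` — the planted class term, applied only in tumor pixels:
  ±Δ/2·(1/(1−2f_sub)) with the sign flipped inside subclone patches
  (thresholded smoothed field covering fraction f_sub of tumor pixels).
  `effect_size` is defined as the **marginal** standardized group
  difference Δ/σ_within, with σ_within² = 0.15² + 0.30² + 0.35²; the
  1/(1−2f_sub) compensation keeps that definition exact for any subclone
  fraction < 0.5.  The default direction is negative (lower in RecPro),
  matching the oriented AUC < 0.3 regime of interest.
* Non-tumor margin pixels carry a class-independent healthy-tissue profile
  (`healthy_shift_j ~ N(0, 0.5)`, shared across cohorts) and no class term.

The emitted axis interleaves two background channels between peak channels
and adds a smooth exponentially decaying baseline (about half the median
peak height at the low-mass end, with per-pixel scale jitter), so that
top-hat removal and peak detection have real work to do.  Subclone patches
are what produce the intermediate per-patient accuracies (roughly 25–65%
of spectra correct) seen in heterogeneous tumors: inside a patch all
planted features jointly follow the opposite class profile, so those pixels
are confidently misclassified while the patient-level sum usually survives.

The companion peptide-library generator emits tryptic-looking sequences
whose neutral monoisotopic masses equal planted feature m/z − 1.00728 Da
(the [M+H]+ proton), plus optional jitter; multi-peptide proteins draw
their peptides from one co-localized signal pair, and optional
single-peptide proteins provide negative controls for the validation rule.

**What the synthetic data do not model:** peak shapes and isotope
envelopes, matrix cluster ions, mass-calibration drift, spatially varying
tissue composition beyond one margin compartment, correlated biology among
null features, or patient covariates.  Passing the recovery suite shows the
pipeline is correct and well-calibrated under this generative model; it
does not certify clinical performance.

## Annotation

Imaging features are matched to the bottom-up library by mass: observed
m/z is treated as [M+H]+ (library masses offset by +1.00728 Da;
configurable off), candidates within ±0.2 Da are ranked by smallest
absolute deviation, then highest −logP score (a final lexicographic key
makes exact ties independent of row order).  Protein identifications
validate in two stages: ≥ 2 supporting matched peptides, and minimum
pairwise correlation of the supporting features' tumor-pixel intensity
vectors ≥ 0.4 (Pearson default, Spearman selectable) — a quantitative
stand-in for the "similar tissue distribution" criterion that published
workflows assess visually.

## Numerical and degenerate-input conventions

* Strict inequalities at the screening thresholds (AUC exactly 0.3/0.7 is
  not selected) and at majority voting (exactly 50% is a miss).
* Patient-sum probability ties → RecPro.
* Zero-SD features standardize to 0; all-zero spectra are excluded at TIC
  with a warning; an empty peak list yields an empty matrix with a warning.
* Exact rank-sum enumeration below 13 pooled observations; midrank ties
  throughout.
* Seeds: every random operation (generation, subsampling, fold assignment,
  solver) takes an explicit seed; pipeline runs echo all seeds into
  `provenance.json` and re-running a configuration is bit-identical.

## Problem sizes used in the test and acceptance runs

Screening/classification recovery runs use the default desk-scale cohort
(31 patients x ~200 tumor spectra, 700 features, 30 planted, seeds 1–5);
null-calibration replicates use the same cohort at ~60 spectra/patient
(the chance-level property does not depend on the pixel count); transfer
runs use 29-patient second cohorts on the shared feature space.  These
sizes are the package's chosen defaults for a reproducible desk-scale
study; all of them are ordinary `CohortSpec` parameters.
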