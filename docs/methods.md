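# Methods

`hyperrad` implements a lesion-level analysis of hyperprogressive disease
(HPD) under immune checkpoint inhibition: radiomic description of lesions on
co-registered CT and FDG-PET, a tumor-growth-rate (TGR) definition of lesion
hyperprogression, predictive modeling of that label from baseline imaging,
and landmark survival analysis of the resulting patient groups. Real patient
imaging is not distributed with the package; every component is exercisable
on synthetic phantoms and simulated cohorts whose generators are part of the
tested API.

## Growth model and hyperprogression definitions

Lesion growth is modeled as exponential in volume with volume proportional
to the cube of the RECIST long diameter D, so between two scans at times
t1 < t2:

    TG = 3 · ln(D2/D1) / (t2 − t1)   [day⁻¹]

TG is computed on a reference period (pre-baseline → baseline scan) and an
experimental period (baseline → follow-up). A **hyperprogressive lesion
(HPL)** must (a) progress by the single-lesion RECIST rule — diameter
increase ≥ 20 % and ≥ 5 mm from baseline to follow-up — and (b) at least
double its growth rate: TG_exp ≥ 2·TG_ref with TG_exp > 0. When TG_ref ≤ 0
(stable or shrinking before treatment) any positive post-treatment growth
exceeds twice the reference rate, so such lesions count as HPL when they
meet the RECIST rule; they carry a `ref_nonpositive` flag so sensitivity
analyses can exclude them. The doubling criterion is a ratio, so it is
invariant to the time unit used.

Patient status applies the RECIST 1.1 sum rule to the summed long diameters
of **all** segmented lesions (≥ 20 % and ≥ 5 mm increase) or fires on new
lesions; the 5-target/2-per-organ cap of RECIST target selection is not
applied because no organ bookkeeping is modeled. Patients are **PD-HPD**
(progressive with ≥ 1 HPL), **PD-nHPD** (progressive without), or **nPD**.
Scan-schedule windows (pre-baseline 3 ± 2 months before baseline, baseline
within 3 months before treatment, follow-up 3 ± 1.5 months after it,
converted at 30.44 days/month) are validated advisorily: violations are
reported but never block classification.

## Image preprocessing

Volumes and masks use axis-aligned grids with voxel-center coordinates
(world = origin + index · spacing); NIfTI IO is delegated to nibabel.
Preprocessing before feature extraction:

1. **Minimum-volume filter**: lesions < 0.5 cc on the native segmentation
   grid are excluded (inclusive bound: exactly 0.5 cc is kept). The filter
   runs before resampling because it mirrors a segmentation-level exclusion
   criterion.
2. **Resampling** to 2 mm isotropic voxels by trilinear interpolation
   (scipy `map_coordinates`, edge-clamped). The output grid shares the
   input origin and spans its physical extent. Masks are interpolated as a
   0/1 field and re-thresholded at 0.5; a mask that vanishes is an error.
3. **Discretization** with fixed bin widths — 5 HU (CT) and 0.25 SUV (PET)
   — anchored at −1000 HU and 0 SUV respectively, bin i covering
   [anchor + (i−1)w, anchor + iw). Fixed anchors keep bins comparable
   across lesions; values below the anchor clamp to bin 1. Interpolation
   order and anchoring are package choices (declared, configurable), not
   dictated by the growth analysis.

## Radiomic feature catalog

46 features per modality in four families, identical for every lesion and
prefixed `ct_`/`pet_` (shape is computed from each modality's own mask
because CT- and PET-based segmentations differ):

- **Histogram (17)** — computed on resampled in-mask intensities: mean,
  variance, skewness, excess kurtosis, min/max/range, percentiles 10/90,
  median, IQR, mean absolute deviation, coefficient of variation, RMS,
  energy, entropy, uniformity. `hist_energy` is intensity energy Σx² (not
  histogram uniformity). Entropy/uniformity use the discretized bins, log
  base 2. Percentiles interpolate linearly at 1-based position 1 + q(n−1).
  Degenerate constant ROIs define skewness/kurtosis/CV as 0.
- **Shape (9)** — volume (voxel count × voxel volume), mesh surface area,
  sphericity π^{1/3}(6V)^{2/3}/A, compactness 36πV²/A³, surface-to-volume
  ratio, maximum 3-D diameter (center-to-center, convex-hull accelerated),
  major axis length and elongation/flatness from the principal components
  of the voxel-center cloud. The isosurface is extracted by marching cubes
  at level 0.5 after a σ = 0.5-voxel Gaussian smoothing of the padded
  binary field; the smoothing tames the staircase overestimate of the
  surface (a digital ball of radius 10 voxels then yields sphericity
  ≈ 0.96 instead of ≈ 0.91), and tiny masks that would vanish fall back to
  the raw field.
- **GLCM (12)** — symmetric co-occurrence at Chebyshev distance 1 over the
  13 unique 3-D direction classes, merged into a single matrix before
  normalization: joint maximum/average/variance/entropy, contrast,
  dissimilarity, inverse difference (plain and moment), correlation
  (defined as 1 for constant ROIs), cluster tendency/shade, angular second
  moment. A single-voxel ROI has no pairs; features are 0 with a warning.
- **GLRLM (8)** — run-length matrix merged over the same directions: SRE,
  LRE, low/high grey-level run emphasis, run percentage, run-length and
  grey-level non-uniformity, run entropy. Run percentage normalizes by
  (voxels × active directions).

**Degenerate-direction rule.** Texture matrices are computed on the mask
bounding box, and scan directions with a nonzero component along a
singleton box axis are dropped. A 1-voxel-thick ROI is therefore scanned
only along its extent (a 1×1×N row has one direction, so a constant row
yields run percentage 1/N), and a 1×1×1 box counts its voxel as a single
run. Both texture extractors are verified against exhaustive pair/run
enumeration on small ROIs.

The catalog is an explicit package-defined stand-in for the (unpublished)
full feature list of the original extraction software; it covers all
model-relevant named histogram features plus standard members of each
family, and makes no attempt to reproduce an exact 180-feature list.

## Feature redundancy pruning

Kendall tau-b (tie-corrected, via scipy) is computed for every feature
pair. Pairs with tau above 0.90 are visited in descending-tau order (ties
broken by name) and one member of each still-intact pair is removed
uniformly at random from a seeded stream, so no surviving pair exceeds the
threshold and the result is reproducible and idempotent. The threshold
applies to the signed tau as printed (anti-correlated pairs survive);
absolute-value mode is a flag. Constant features have undefined tau,
recorded as 0 with a warning. Inside cross-validation, pruning runs on the
training folds only (leak-safe default); a global pre-pruning mode is
available through the library by pruning the full table up front.

## Predictive modeling

The learner is a two-stage pipeline: standardize → gradient-boosted trees
(xgboost, `hist`, single thread) → rank features by total-gain importance →
keep the top m ≤ 6 per imaging modality (ties broken by column order;
all-zero importances fall back to univariate AUC with a warning) → L2
logistic regression on the retained features. Largest possible models: 6
covariates (single modality), 12 (PET/CT).

Nested cross-validation: the outer loop is a stratified **group** 5-fold
split (sklearn `StratifiedGroupKFold`) keying groups on patient id, so a
patient's lesions never straddle train and test. Per outer fold the
training data are pruned (tau > 0.90), hyperparameters are tuned by random
search — n_estimators ∈ {25, 50, 100}, depth 1–4, learning rate
log-uniform [0.03, 0.3], subsample [0.6, 1.0], features-per-modality 1–6,
logistic C log-uniform [0.01, 100] — scored by mean AUC over a 10×-repeated
stratified 5-fold inner CV (ties keep the first candidate; single-class
inner folds are skipped with a warning). The tuned pipeline is refit on the
full training fold and scored on the held-out lesions; a single-class test
fold is excluded with a warning. Results report per-fold and mean ± SD AUC
(train and test) and a vertically averaged ROC (mean TPR on a 101-point FPR
grid). The search space is a package choice; reproducing any particular
study's exact ranges is a non-goal.

All randomness flows from one config seed through named CRC32-derived
substreams (folds, search, pruning), so stages rerun in isolation
reproduce their in-pipeline behavior.

Default benchmark sizes: the packaged modeling benchmarks and examples run
the random search at 10 candidates with 2 inner repeats on 300-lesion
tables — large enough for the null band (permuted labels: AUC ≈ 0.5) and
the separable benchmark (AUC ≥ 0.95) to be stable, while the full
100-candidate, 10-repeat search remains the configurable default.

## Survival analysis

Overall survival is summarized per patient group with the Kaplan-Meier
estimator (lifelines), group differences with the log-rank test, and effect
sizes as hazard ratios from univariable Cox proportional-hazards fits
(Efron tie handling, Wald 95 % CI) — the estimator behind published HRs is
typically unstated, and a univariable PH fit is the standard choice. The
median is the first time with S(t) ≤ 0.5. A 3-month landmark corrects for
guarantee-time bias: patients with an event or censoring at or before the
landmark are excluded and remaining times are re-origined there (the PH
estimate is invariant to this shift for patients past the landmark).
Cohort comparisons use the two-sided Fisher exact test (summation of tables
with probability ≤ observed; degenerate margins give p = 1) and the
two-sided tie-corrected Mann-Whitney U test (asymptotic, no continuity
correction, so identical samples give p = 1).

## Synthetic data: what it emulates, and what it does not

- **Phantoms** are ellipsoids thresholded on the implicit equation at voxel
  centers (analytic volume/surface references for tests), filled with
  Gaussian noise over a constant background plus optional Gaussian
  hotspots. Class-conditional presets encode the reported imaging signature
  of lesions at risk of hyperprogression — elevated uniform intensity, no
  hot/cold spots — against heterogeneous, dimmer non-HPL lesions. No
  anatomy, scanner noise, attenuation or reconstruction physics.
- **Growth cohorts** draw per-class diameter trajectories from
  D(t) = D₀·exp(g·t/3) with separate pre-/post-treatment rates, so the
  configured g is exactly the TG statistic and jitter-free labels are
  recovered with 100 % accuracy by construction; lognormal measurement
  jitter is optional. The archetype trajectories (20→20→20, 14→20→26,
  19→20→26 mm at −90/0/+90 days) sit far from the 20 %/5 mm and doubling
  boundaries.
- **The worked-example cohort** (`build_figure2_fixture`) is a
  deterministic 56-patient, 330-lesion allocation of those archetypes —
  261 stable, 40 slowly progressing, 29 hyperprogressive lesions over
  42 nPD / 6 PD-nHPD / 8 PD-HPD patients — whose classification reproduces
  the published lesion- and patient-level rates exactly. The per-patient
  lesion mix is one consistent choice; the real study's distribution was
  not published. Its `os_months`/`event` columns are invented,
  deterministic illustration values consistent with the published group
  medians (7 and 12 months from the landmark; non-progressors mostly
  censored with occasional interleaved late deaths so Cox fits remain
  regular); the fitted HRs on this fixture are demonstration output, not
  study estimates.
- **Survival simulation** draws exponential event times per group with
  independent exponential censoring (hazards per month), the standard PH
  data-generating model; recovery benchmarks use n = 500/group where the
  Cox estimate of an 8.5× hazard ratio concentrates within ±~15 %.
- **Feature-table simulation** (`make_feature_table`) produces Gaussian
  lesion×feature tables with a planted mean-shift signal in the first CT
  columns and patient-clustered labels, for modeling benchmarks where the
  truth must be known exactly.

Passing tests on these generators demonstrate correctness of the formulas,
the leak-freedom of the CV design, and statistical calibration of the
estimators — not performance on real PET/CT imaging, which differs in
texture realism, segmentation noise and class balance.

## Numerical and degenerate-input conventions

- Entropies are clamped at 0 (guarding −0.0 / rounding).
- Constant ROIs: skewness = kurtosis = CV = 0; GLCM correlation = 1.
- Diameters and times are validated (> 0, t_pre < t_base ≤ 0 < t_fu).
- Derived seeds use CRC32 of the stream name modulo 2³¹, stable across
  processes and Python versions.
- Resampling beyond the input edge clamps to edge values; bins below the
  discretization anchor clamp to bin 1.

## Known limitations

- No DICOM ingestion, SUV computation, registration, or orientation
  matrices beyond axis-aligned geometry.
- The feature catalog is a documented stand-in, not a reproduction of any
  specific extraction software; wavelet/filtered features and the
  GLSZM/NGTDM families are out of scope.
- Patient-level RECIST uses all lesions rather than target-lesion
  selection.
- Published model AUCs from the motivating clinical study depend on real
  imaging that is not redistributable; the package's modeling claims are
  calibration claims (null ≈ 0.5, separable ≥ 0.95), not clinical
  performance claims.
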