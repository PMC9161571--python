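# Methods

This note documents the models implemented in `evrad`, the assumptions
behind the synthetic-cohort generator, the numerical conventions, and the
design choices made where the underlying clinical methodology left the
design open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## 1. The ΔEV PD-L1 statistic

For each patient, plasma EV western-blot densitometry yields four positive
band intensities: PD-L1 and the loading control CD9, each at baseline (T1)
and at the 9±1-week on-treatment draw (T2). The dynamics statistic is the
ratio of CD9-normalized PD-L1 values,

    Δ = (PD-L1_T2 / CD9_T2) / (PD-L1_T1 / CD9_T1),

with Δ > 1 classified *increase* and Δ < 1 *decrease*. Two properties are
enforced by construction and tested: multiplying all bands of one
timepoint by c > 0 (lane exposure) leaves Δ unchanged, and swapping
timepoints maps Δ → 1/Δ.

**Δ exactly 1.** The clinical definition uses strict inequalities and
never observes Δ = 1. We assign Δ = 1 to the non-increase ("decrease")
class and log a warning: the clinically alarming state is a strict
increase, so the conservative reading places the boundary case outside
it. Any band ≤ 0 raises an error and the patient is excluded, mirroring
the exclusion of low-quality plasma samples.

## 2. Radiomics feature vector (400 features per lesion VOI)

**Normalization.** The volume is z-scored voxelwise to the mean/SD of a
segmented pectoralis-muscle reference VOI ("within-phase normalization").
Together with min–max quantization this makes every feature invariant to
affine intensity maps a·x + b (a > 0) of the scanner output.

**Quantization.** Equal-width bins between the lesion VOI minimum and
maximum; the minimum maps to level 1, the maximum to level G, a constant
VOI maps entirely to level 1. Five gray-level settings are used:
G ∈ {8, 16, 32, 64, 128}. The source methodology states only "five gray
levels" as the multiplier of its 39 rotation-invariant features; reading
that as five *quantization settings* is the standard multi-quantization
design and is the only reading that reproduces 39 × 5 = 195.

**GLCM.** Symmetric, normalized co-occurrence matrices at distance 1
voxel over the 13 unique 3D offsets of the 26-neighborhood (each ± pair
counted once; symmetry makes d and −d equivalent). Pairs with either
voxel outside the lesion mask are excluded; a direction with no valid
pair is skipped and logged. Whether the original analysis computed GLCMs
slice-wise (2D) or volumetrically is unstated; lesions are segmented in
3D, so the 3D convention is used.

**Haralick statistics.** The 13 classical features per GLCM: energy
(angular second moment), contrast, correlation, variance (sum of
squares), inverse difference moment, sum average, sum variance, sum
entropy, entropy, difference variance, difference entropy, and the two
information measures of correlation. Conventions: logs are base 2 with
0·log 0 = 0; sum variance is computed about the *sum average* (the
original text's self-reference to sum entropy is widely treated as an
erratum); for a degenerate single-level GLCM the correlation-type
features are 0 with a warning. A naive double-loop reference
implementation lives in `tests/oracles.py` and the suite requires
agreement to 1e-10 on random VOIs.

**Rotation invariance.** Per direction, features are aggregated into
average, range (max − min) and angular variance (population variance),
13 × 3 = 39 per gray-level setting. Because the offset set is closed
(up to sign) under signed axis permutations, 90° rotations and flips of
volume + masks only permute the per-direction feature multiset, leaving
all aggregated features unchanged; the suite asserts this to float
tolerance.

**Histogram features (10).** Mean, median, SD (population), skewness
(m₃/m₂^1.5), excess kurtosis (m₄/m₂² − 3), minimum, maximum, range, and
energy/entropy of a 64-bin histogram over the VOI range (constant VOI:
energy 1, entropy 0, skewness/kurtosis 0 by convention). The clinical
methodology never enumerates its ten; this fixed set is documented as
ours.

**Volume normalization.** Each of the 195 GLCM features is additionally
divided by the lesion volume (voxel count × voxel volume in mm³), giving
the 195 "volume-dependent" features and the total of 400. Multiple
lesions are extracted per-lesion; a volume-weighted average provides the
whole-body tumor-burden view.

Feature names follow `hist_<stat>`, `glcm_G<G>_<haralick>_<agg>` and
`..._voln`; the order is fixed and exposed by `evrad.feature_names()`.
The exact feature naming of the original pipeline (e.g. "TL_FLV7") is
undocumented and deliberately not imitated.

## 3. Response models

All recipes score the positive class *durable non-responder* (progressive
disease at the 21±3-week evaluation; CR/PR/SD are durable responders).

* `ev_only`: unpenalized logistic model on log Δ.
* `tissue_tps`: logistic model on the ordered TPS groups {<1%, 1–49%,
  ≥50%}; "unknown" merges into the lowest group, following the clinical
  handling of missing TPS ("low or absent").
* `radiomics`: L1-penalized logistic selection (features standardized;
  penalty chosen by 5-fold cross-validated deviance over a 15-point log
  grid, seeded) followed by an XGBoost classifier with fixed
  hyperparameters: depth 2, 100 rounds, learning rate 0.1, logistic
  loss. The original analysis states no boosting hyperparameters; these
  are deliberately shallow/slow to suit n ≲ 60.
* `ev_plus_radiomics`: log Δ appended to the selected radiomics
  features under the same boosted model. If selection returns nothing,
  the recipe degenerates exactly to `ev_only`.

**LOOCV.** Each sample is scored by a model trained on the other n−1,
with feature selection re-run inside every fold by default — the
leakage-free design. Because the original report of a fixed 6-feature
signature suggests selection on the full data, a
`selection_outside=True` mode reproduces that (leaky) workflow for
comparison; the default remains leakage-free. Whether published AUCs are
apparent or cross-validated is ambiguous, so the pipeline reports both
the apparent univariate ROC of Δ and the out-of-fold metrics.

**Metrics at the Youden cut-point.** AUC is computed from the out-of-fold
scores via the rank (Mann–Whitney concordance) identity. Sensitivity,
specificity and accuracy are evaluated at the cut-point maximizing
Youden's J = sens + spec − 1 over the out-of-fold score distribution —
the same convention used for reporting biomarker performance. A fixed
0.5 probability threshold is *not* used: under leave-one-out the held-out
sample's class is always under-represented in its training fold, so any
prevalence-tracking score sits on the wrong side of 0.5 for both classes
(most visibly for near-null models), a known pathology of the
LOOCV/fixed-threshold combination. A related artifact worth knowing:
out-of-fold scores of an *uninformative* model are anti-correlated with
the held-out label, so a null recipe's LOOCV AUC can fall well below
0.5; chance-level behavior shows up in the Youden-threshold accuracy.

**LASSO penalty rule.** Minimum cross-validated deviance (not the 1-SE
rule); the original's choice is unstated.

## 4. Survival analysis

Kaplan–Meier product-limit curves stratified by dynamics class, reported
with at-risk counts every 6 months and landmark survival at 12 and 24
months; two-group log-rank tests; Cox proportional-hazards models by
partial likelihood with Efron tie handling (lifelines defaults). PFS is
time to first radiological or clinical progression, OS time to death;
both are consumed as precomputed columns.

The multivariate model uses backward stepwise selection: starting from
the full model, the covariate with the largest Wald p above
`removal_alpha` is removed and the model refit until all retained
p ≤ `removal_alpha`. The default `removal_alpha = 0.10` matches the
removal default of the classical clinical-statistics packages; entry/
removal thresholds of the original analysis are unstated, so this is a
documented default, not a claim. Default candidate covariates: dynamics
class, TPS group and treatment line (constant columns are dropped).

## 5. The synthetic-cohort generator

The generator emulates the study conditions the analysis assumes; its
defaults are the fixed study design and are not tuned per experiment.

**Cohort.** n = 60 patients (the pooled ICI-treated population scale),
responder fraction 0.5. Latent Δ is lognormal with log-median −0.5 for
responders and +0.4 for non-responders, log-SD 0.6 — medians ≈ 0.61 and
1.49, straddling 1 with substantial overlap, chosen to produce
single-biomarker discrimination in the 0.75–0.9 AUC range typical of the
clinical reports. The distributional form of ΔEV PD-L1 is not published;
lognormal is this module's assumption (positive support, multiplicative
noise), exposed in the configuration.

**Band decomposition.** CD9_T1, CD9_T2, PD-L1_T1 are lognormal around 1
(log-SD 0.3, ordinary blot variability); PD-L1_T2 is set so the
recomputed ratio equals the latent Δ; each band is then multiplied by
lognormal noise with CV `band_noise_cv` (default 0.05, mean-1). With
zero noise the decomposition is exact, which the suite asserts.

**Survival.** PFS is the composite progression-or-death endpoint, so
`pfs ≤ os` must hold per patient while both marginals stay exponential
proportional-hazards. We draw a latent death time
T_death ~ Exp(h_os·HR_os^dec) — OS is exactly exponential PH — and a
latent progression time whose rate is the difference of the configured
PFS and OS rates within each class, so that T_pfs = min(T_prog, T_death)
is exactly Exp(h_pfs·HR_pfs^dec) (minima of independent exponentials add
rates). This requires h_pfs > h_os and h_pfs·HR_pfs > h_os·HR_os, which
the configuration validates. Defaults: baseline hazards 1/6 and 1/12 per
month (median PFS ≈ 4 months, median OS ≈ 8 months in the increase
class), hazard ratios 0.45 (PFS) and 0.35 (OS) for the decrease class —
the multivariate estimates reported for the pooled ICI population.
Censoring is uniform C ~ U(0, c_max), covariate-independent, with c_max
calibrated numerically so the expected censored fraction equals
`censor_fraction` (default 0.15); one shared uniform draw per patient
keeps observed pfs ≤ os.

**Lesion-size change** is a monotone noisy map of log Δ
(30 %-points per log unit, SD 12), reproducing the published positive
correlation between EV dynamics and lesion size; RECIST categories derive
from it (−30 % partial-response threshold; non-responders are PD by the
durable-response definition).

**Phantoms.** An ellipsoidal lesion (semi-axes 2–7 voxels) on a 48³ grid
(0.8 × 0.8 × 1.5 mm spacing) filled with a Gaussian random field:
white noise smoothed at correlation length 2.4 voxels (responders) or
1.4 (non-responders), jittered per patient by lognormal noise (log-SD
0.25) so texture is an informative but imperfect class marker — without
the jitter the radiomics recipe becomes near-perfect (AUC ≈ 0.99),
unlike any real exploratory radiomics cohort. Shorter correlation length
yields higher GLCM contrast (asserted by Monte Carlo). A 6³-voxel
cuboidal "muscle" VOI (mean 50, SD 8) sits in the grid corner, disjoint
from the lesion; background is zero-mean noise. Intensities are
arbitrary units, not calibrated HU.

**What the phantoms do not emulate:** CT anatomy, partial-volume and
beam-hardening effects, contrast-phase variation, segmentation error,
multiple lesions per patient (the interface supports them; the generator
emits one), and scanner/protocol batch effects. Passing tests therefore
demonstrate the *pipeline's* correctness and statistical behavior under
the assumed generative structure — not clinical performance on real CT.

## 6. Statistical kernels and numerical conventions

Mann–Whitney U uses an exact null for groups of ≤ 10 each (full
permutation enumeration when ties are present) and the tie-corrected
normal approximation otherwise; Kruskal–Wallis, chi-square (no
continuity correction) and Spearman (midranks, t-approximation) follow
the standard scipy implementations behind validated wrappers. Two-sided
tests at α = 0.05 are the default throughout. The univariate ROC AUC is
computed by the rank identity AUC = U/(n₁n₀) and the Youden cut-point by
an exhaustive sweep over observed thresholds, ties broken toward the
smaller threshold. GLCM tolerance: symmetric, non-negative, sums to 1
within 1e-12. Angular variance returns exactly 0 when all directions
agree, avoiding float dust in the degenerate case.

## 7. Problem sizes used by the checks

The acceptance checks run at the sizes of the study design: hazard-ratio
recovery on n = 2000 cohorts with 20 % censoring (the log-HR sampling SE
at this size is ≈ 0.05, so recovery/bias is assessed as the mean over 10
replicate seeded cohorts); power and anti-leakage properties at the
default n = 60 and n = 30 over 10–20 seeds; oracle equivalence on 50
random VOIs up to 8³ voxels. Band noise is set to 0 in the recovery runs
so the dynamics class recomputed from the blots coincides with the
latent class driving the hazards — isolating the survival link from blot
measurement error, which is studied separately.

## 8. Known limitations

* The generator encodes the *direction* and approximate magnitude of the
  published effects, not patient-level reality; absolute AUCs/HRs from
  synthetic runs characterize the design, not the clinic.
* Radiomics feature identities (the five gray levels, direction set, 13
  base features, 10 histogram features) reconstruct an incompletely
  specified pipeline; the counts (10 + 195 + 195 = 400) are exact, the
  name-level mapping to the original features is not recoverable.
* Exponential baselines and uniform censoring are the simplest PH-correct
  choices; real survival curves have richer shapes.
* No DICOM ingestion, no segmentation, no competing risks, no
  time-varying covariates, no calibration analysis.
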