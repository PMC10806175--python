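# Methods

This note documents the models, conventions and numerical choices behind
`radcrt`, and what the synthetic phantoms do and do not establish about
real CT data.

## Synthetic cohort

**Design.** The default cohort reproduces the study design the pipeline is
meant for: 27 training and 17 validation cases with 6 responders in each
cohort (prevalences 22.2% and 35.3%). Phantoms live on a 48 × 48 voxel,
36-slice grid with native spacing 0.976 × 0.976 mm in-plane and 2.5 mm
slice thickness — a routine non-contrast chest CT protocol.

**Tumor model.** Each tumor is an ellipsoid (default radii 16 × 11 × 11 mm,
per-axis radius jitter ±15%) whose interior is a stationary correlated
Gaussian random field: white noise smoothed by a Gaussian kernel of scale
`correlation_length` (mm) and rescaled *after* smoothing so the realized
standard deviation equals `sd_hu` exactly. The background is air (−700 HU)
with a 3-voxel soft-tissue shell (+40 HU) around the tumor so the VOI
boundary is radiologically distinct. There is no anatomical realism — no
esophagus, no neighboring organs, no partial-volume blur.

**Class effect.** Nothing quantitative is known about how responder tumors
differ on CT, so the between-class effect is a free parameter. The default
encodes a strong, texture-only difference: responders
(mean 40 HU, sd 20 HU, correlation length 3 mm — smoother, more
homogeneous) versus non-responders (mean 45 HU, sd 45 HU, correlation
length 1 mm — noisier, finer-grained). These values were fixed once, to
represent clearly distinct heterogeneity phenotypes; they drive exactly
the histogram and texture families the pipeline measures while leaving
shape uninformative. With identical parameters for both classes the
per-feature AUC distribution collapses onto chance (tested).

**Outcomes.** Event times are exponential. Non-responder medians default
to 5.9 months (PFS) and 13.4 months (OS); responder hazards are multiplied
by 0.106, putting the responder PFS median at ≈ 55.6 months — the scale of
outcomes reported for this disease setting. OS is generated as
PFS + an independent exponential gap calibrated to the OS−PFS median
difference, which guarantees OS ≥ PFS by construction at the cost of the
OS median being only approximately its nominal value. Administrative
censoring applies at 80 months. Clinical covariates (age, sex, T stage,
N stage, SCC antigen, tumor location) are drawn from class-dependent
categorical/log-normal distributions so the multivariate Cox stage has
non-degenerate, outcome-linked inputs.

**What passing tests show.** That the pipeline's statistics are correct
and that it recovers a texture effect of the simulated kind at the study's
sample size. They do not show that real ESCC responders differ this way,
nor address scanner variation, delineation variability or class overlap in
real cohorts.

## Preprocessing

Arrays are indexed (z, y, x) with spacing aligned to array axes. Cases are
cropped to the VOI bounding box plus an 8-voxel pad (bounds wavelet and
resampling cost without touching in-mask statistics). Resampling to the
2 mm isotropic grid uses trilinear interpolation for images and
nearest-neighbor for masks, with the output grid sized so no voxel center
extrapolates past the input span. Gray levels are requantized with a fixed
25 HU bin width anchored at the in-mask minimum
(`level = floor((I − min)/25) + 1`), making levels invariant to global
intensity shifts; wavelet subbands, which are not in HU, reuse the same
fixed width of 25 on their own scale with the same per-component anchor,
since one rule is applied uniformly to all nine component images.

## Wavelet decomposition

A single-level undecimated (stationary) 3D transform: separable
convolution with the analysis filter pair of a PyWavelets basis along each
axis (2³ = 8 subbands named by their x/y/z filters), symmetric boundary
extension, no downsampling — so every subband stays in register with the
VOI mask, which masked feature extraction requires. Default basis is
Coiflet-1 (the convention of the radiomics toolkits this feature set
follows); Haar is used in tests for hand-checkable coefficients. Whether a
decimated or undecimated transform is "the" reference convention is
genuinely open; the choice is recorded in the extraction config so results
are labeled.

## Feature catalog (476)

8 shape + 9 × (10 histogram + 42 texture) = 476. The published id scheme
pins only twelve names (e.g. `LLLEnergy`, `ROIGCorrelation`, `HLLLRE`,
`HHLZP`); the full 42-texture split — 22 GLCM, 11 GLRLM, 9 GLSZM — is a
declared reconstruction constrained by those names and the printed counts.
GLCM ids carry a `G` marker after the component; the GLSZM gray-level
nonuniformity is named `ZGLN` to avoid colliding with the run-length `GLN`
under the shared component prefix.

Conventions: GLCM and GLRLM are computed per direction over the 13 unique
3D offsets and features are averaged across directions (not matrices);
GLCM matrices are symmetrized and normalized per direction; GLSZM zones
are 26-connected components of equal level. Histogram moments use the raw
continuous intensities (population variance, Pearson non-excess kurtosis);
entropy and uniformity use the fixed-bin probability vector. Shape
features are computed on the 2 mm resampled mask for uniform geometry;
surface area counts exposed voxel faces, so the sphericity of a digitized
ball tops out near 0.66 rather than 1 (a mesh surface would behave
differently — the face-count convention is the package's stated closed
form and is what the tests pin down). Undefined values (correlation and
information-measure features of a single-gray-level region; skewness and
kurtosis at zero variance) are carried as NaN flags per feature, never
propagated across features.

## Selection

Screening keeps features with raw AUC ≥ 0.7 and two-sided tie-corrected
rank-sum p < 0.05; features predictive only in the negative direction
(AUC ≤ 0.3) are excluded by the literal rule, and a `two_sided` switch
screens on max(AUC, 1−AUC) instead. Grouping is greedy in descending-AUC
order (ties broken lexicographically): each feature joins the first group
whose representative it matches at |r| ≥ 0.7 with p < 0.05, else founds a
group. This directly yields "the highest-AUC feature per group" and is
order-deterministic; a connected-components variant is available since
the linkage convention is not uniquely determined. |r| is used because
anti-correlated features are equally redundant. Constant features form
singleton groups with a warning. No multiple-testing correction is
applied at screening (deliberately, matching the workflow being modeled).

## Classifiers and cutoff

RF: 500 trees, √p features per split, fixed seed; its probability score is
the fraction of trees voting responder. Training-cohort RF scores used
downstream are out-of-bag (each case scored only by trees that never saw
it); resubstitution scores are available but flagged. NB is Gaussian naive
Bayes. RR is L2-penalized logistic regression with the penalty picked from
a fixed four-point grid by seeded 3-fold CV AUC. ANN is a single hidden
layer of 8 units (the smallest sensible architecture for ~12 inputs),
early stopping off, fixed seed. SVM is RBF with Platt-scaled decision
values. RR/ANN/SVM inputs are z-scored with training statistics stored in
the model. The Youden cutoff maximizes J over midpoints of consecutive
distinct training scores, ties broken toward higher sensitivity, with
score ≥ threshold ⇒ predicted responder.

## ROC statistics

AUC is the Mann–Whitney c-statistic (ties ½); its p-value is the
two-sided, tie-corrected normal-approximated rank-sum test; the 95% CI
uses the DeLong placement-variance, clipped to [0, 1]. The paired model
comparison is DeLong's test from the 2 × 2 covariance of placement values;
identical rankings (zero variance of the AUC difference) return p = 1 by
convention. Calibration is verified by simulation: type-I error at
α = 0.05 stays within 0.05 ± 0.02 over 500 null cohorts of 44.

## Survival

Kaplan–Meier, log-rank and Cox run through lifelines behind this module's
interface. Cox uses the Efron tie approximation (the standard default with
the best small-sample behavior) and Wald CIs; constant or collinear
covariates are rejected before fitting, non-convergence raises, and
monotone likelihood (perfect separation, common in a 17-case stratum) is
flagged rather than hidden. Covariates are dichotomized as indicators of
the protective category: age < median, female, T 1–2, N 0–1, SCC ≤ 1.5,
mid/lower location, high score. The multivariate model includes exactly
the univariately significant variables (p < 0.05) — the promotion rule the
two-table univariate/multivariate layout implies. A median is "not
reached" (None) when S(t) never drops to 0.5. Simultaneous event/censor
times resolve events-first.

## Problem sizes and tolerances

Test and acceptance workloads were sized to run comfortably on one CPU:
brute-force matrix oracles use exhaustive 6³ volumes with ≤ 4 gray levels;
test calibration uses 500 null simulations (binomial ±2σ ≈ 0.02 at the
nominal 0.05); Cox recovery uses 200 replicates of n = 200 (log-HR bias
bound 10%); the end-to-end check runs 20 full seeds of the 44-case design.
Float comparisons in oracle tests use absolute tolerances of 10⁻⁶–10⁻⁹;
the grid-search Cox oracle resolves β to 10⁻⁴ and is compared at 10⁻³.

## Known limitations

- Phantoms are texture-pure ellipsoids; shape features are present but
  uninformative by construction.
- The exponential outcome model has no frailty or covariate-driven hazard
  beyond response class; covariate effects in Cox tables arise only
  through their class linkage.
- The 42-texture catalog is one defensible reconstruction; other splits
  consistent with the printed counts exist.
- The SVM probability path relies on Platt scaling, which is noisy at
  n ≈ 27; DeLong comparisons against it inherit that noise.
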