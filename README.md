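# radcrt

A CT-radiomics pipeline for predicting chemoradiotherapy (CRT) response and
prognosis in esophageal squamous cell carcinoma (ESCC), implemented as a
tested, reusable Python package and exercised end-to-end on synthetic
textured tumor phantoms (real delineated patient CT cohorts of this kind
are not publicly available).

## What it does

Given a 3D CT volume and a binary volume-of-interest (VOI) mask per case,
the pipeline runs three phases:

1. **Discovery** — extract a 476-feature radiomics vector per case:
   8 shape features from the mask plus, for each of 9 component images
   (the original ROI and the 8 subbands LLL…HHH of a single-level
   undecimated 3D wavelet transform), 10 histogram features and 42 texture
   features (22 GLCM + 11 GLRLM + 9 GLSZM). Components are resampled to a
   2 mm isotropic grid and requantized with a fixed 25 HU bin width before
   texture analysis. Features are screened per-ROC (AUC ≥ 0.7, p < 0.05,
   Mann–Whitney c-statistic), redundant features are grouped by Pearson
   correlation (|r| ≥ 0.7) and the highest-AUC representative of each group
   is kept. Five classifiers — random forest (RF), naive Bayes (NB), ridge
   logistic regression (RR), a small neural network (ANN) and an RBF SVM —
   are trained on the representatives.
2. **Validation** — held-out scores on an independent cohort, per-model ROC
   with DeLong 95% CIs, pairwise DeLong tests between models, and
   accuracy/sensitivity/specificity at the Youden cutoff
   (argmax of J = sensitivity + specificity − 1 on training scores).
3. **Development** — Kaplan–Meier curves and log-rank tests for
   progression-free and overall survival comparing high- vs low-score
   groups, plus univariate and multivariate Cox proportional-hazards
   models over the standard clinical covariates.

Key quantities, in the field's notation: sphericity
π^{1/3}(6V)^{2/3}/A; GLCM contrast Σ p(i,j)(i−j)²; run percentage
RP = N_runs/N_voxels; zone percentage ZP = N_zones/N_voxels; the
c-statistic AUC = P(score⁺ > score⁻) with ties counting ½; Cox hazard
h(t|x) = h₀(t)·exp(βx) with Efron tie handling.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic design (27 training / 17 validation cases, 6 responders each):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_extract_features.py
python analysis/03_discover.py --seed 1
python analysis/04_validate.py --seed 1
python analysis/05_prognosis.py --seed 1
python analysis/06_calibration.py --seed 1
```

With seed 1 this prints (abridged):

```
screened 130 candidate features (AUC >= 0.7) out of 476
collapsed into 14 correlation groups; representatives: HLHGEnergy, ROIGIDMN, ...
  RF: training AUC 1.000 [1.00-1.00]
Youden cutoff 0.348 (sens 1.00, spec 1.00)
  RF: validation AUC 1.000 [1.00-1.00], accuracy 100.0%
all_cases (n=44):
  PFS: median high not reached vs low 4.471 months, log-rank p 4.897e-06
    score group HR 0.11 [0.04-0.32], p 6.793e-05
```

Reading this: of the 476 extracted features, 130 pass the ROC screen and
collapse into 14 non-redundant groups; the classifiers separate the two
synthetic texture classes essentially perfectly (the default phantom
effect is deliberately strong); and stratifying all 44 cases at the Youden
cutoff yields a large survival split (hazard ratio ≈ 0.11 for the
high-score group). `06_calibration.py` additionally verifies that the
DeLong and log-rank tests hold their nominal 5% type-I error
(0.054 / 0.058 over 500 null simulations) and that Cox regression recovers
a simulated hazard ratio of 0.25 without material bias (mean 0.252,
n = 200 per replicate).

The same workflow is available as a CLI (`radcrt simulate | extract |
discover | validate | prognosis | run-all`) and as library calls
(`radcrt.pipeline.run_all`).

## Layout

- `src/radcrt/` — the library: `synthetic` (phantom cohorts), `preprocess`
  (NIfTI I/O, crop, resample, quantize), `wavelet`, `catalog`, `features`,
  `texture`, `extract`, `roc`, `selection`, `models`, `survival`,
  `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `tests/` — unit, property and acceptance tests, with independent
  brute-force oracles in `tests/oracles.py`.
- `docs/methods.md` — modeling assumptions, parameter choices and
  limitations.
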