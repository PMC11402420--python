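# srct-radiomics

Radiomics on slice-reduced versus full-chest lung CT for diagnosing and
staging interstitial lung disease (ILD) in systemic sclerosis (SSc).

Repeated chest HRCT is the standard of care for monitoring SSc-ILD but
carries a radiation burden; a slice-reduced protocol (srCT) acquires only
nine interspaced axial slices, weighted toward the lung base where SSc-ILD
predominates. This package implements, as a tested and reusable pipeline,
the comparison of radiomic models built from srCT slices (2D features)
against models built from full-chest volumes (fcCT, 3D features), for two
binary endpoints derived from visual staging: *diagnosis* (any ILD versus
none) and *staging* (extensive versus limited involvement, using the 20 %
extent threshold).

It is aimed at medical-image-analysis researchers who want a transparent,
fully seeded reference implementation of this design — including a synthetic
cohort generator, so that every stage runs and is verifiable without access
to clinical scans.

## What it computes

* **Preprocessing** — basal slice selection (six positions at 15 mm), SNR
  based duplicate-slice choice (SNR = |μ|/σ inside the lung ROI), tri- and
  bilinear resampling (2 mm isotropic in 3D; 0.72 mm / 2 mm in-plane in 2D),
  fixed-bin-width discretization (50 HU over [−1000, 200] HU → 24 bins).
* **Features** — intensity-histogram statistics (M, SD, skewness, kurtosis,
  …), grey-level co-occurrence (GLCM) and size-zone (GLSZM) texture, on the
  original image and all sub-bands of a single-level wavelet transform, in
  2D (slice-averaged) and 3D.
* **Screening** — per-feature AUC from the Mann-Whitney *U* statistic,
  `AUC = U/(n₁n₀)`, folded below 0.5 as `max(AUC, 1 − AUC)`.
* **Models** — four families under nested cross-validation (stratified
  3×10-fold inner loop, 300-sample random search; 2×5-fold outer loop):
  logistic regressions on preselected intensity moments (`M`, `MSDSK`) and
  data-driven workflows (`LR-LR`, `ET-ET`) with Pearson-correlation pruning,
  Z-score + Yeo-Johnson transform and embedded feature selection.
* **Evaluation** — vertically averaged ROC curves, the operating cutoff at
  the maximum of Youden's *J* = sensitivity + specificity − 1, a metric
  panel (accuracy, sensitivity, specificity, PPV, NPV, DLR+ = sens/(1−spec),
  DLR− = (1−sens)/spec) with 95 % CIs, and precision-recall curves.

See `docs/methods.md` for the model assumptions, parameter defaults and the
scope of the synthetic generator.

## Worked example

```python
from srct_radiomics import (
    CohortConfig, CVConfig, generate_cohort, cohort_labels,
    build_feature_table, clean_features, screen_features,
    make_endpoint, nested_cv, evaluate_predictions,
)

cfg = CohortConfig(n_none=30, n_limited=15, n_extensive=15,
                   volume_shape=(48, 40, 40), voxel_spacing=(3.0, 2.5, 2.5),
                   disease_mean_hu=-800.0, seed=7)
patients = generate_cohort(cfg)
labels = cohort_labels(patients)

table, removed = clean_features(build_feature_table(patients, "2D", 2.0))
ep = make_endpoint(labels, "diagnosis")
report = screen_features(table, ep.y, "diagnosis", condition="2D@2.0")

cv = CVConfig(outer_splits=5, outer_repeats=2, inner_splits=3,
              inner_repeats=1, n_search=30)
res = nested_cv("MSDSK", table, ep, seed=7, cv=cv)
curve, panel, pr = evaluate_predictions(res.predictions)
```

Output for this seed:

```
feature table: 60 patients x 235 features (0 removed by cleaning)
screening: median folded AUC 0.640, max 0.972 (original_GLCM_differenceVariance)
MSDSK nested CV: AUC tuning 0.970 +/- 0.038, AUC testing 0.958 +/- 0.057
Youden cutoff 0.573: sensitivity 0.40 (0.28-0.52), specificity 0.97, accuracy 0.68
DLR+ 12.00, DLR- 0.62, PR AUC 0.91
```

Reading it: the cohort's diseased patients carry a modest attenuation shift
(−800 HU disease vs −850 HU parenchyma) concentrated at the lung base, so
single features already discriminate well (max folded AUC 0.97); the
four-moment logistic model generalizes to a testing AUC of 0.96 ± 0.06 over
the ten outer folds, and the Youden-optimal cutoff on the averaged ROC
trades sensitivity (0.40) for near-perfect specificity (0.97), giving a
positive likelihood ratio of 12 — a score above the cutoff is twelve times
likelier in a diseased patient.

The same analysis runs end to end from the command line, driven by a JSON
or YAML config:

```sh
srct-radiomics all --config run.json --output-dir out --seed 7
```

which writes the cohort (NIfTI + manifest), per-space feature tables (CSV +
descriptor sidecars), screening reports, the model grid (AUC tuning/testing
per space × endpoint × family), metric panels and ROC/PR curves, plus a
manifest with versions, seeds and stage timings sufficient to reproduce the
run.

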