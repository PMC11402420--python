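# Methods

`srct-radiomics` compares radiomic analysis of a slice-reduced chest CT
protocol (srCT: nine interspaced axial slices, basally weighted) against
full-chest CT (fcCT) for detecting and staging interstitial lung disease
(ILD) in systemic sclerosis. Because the clinical scans behind this design
are not publicly deposited, the package ships a synthetic cohort generator
that reproduces the statistical structure the analysis depends on, and every
claim the test suite makes is a property of the method, not a reproduction of
patient-level results.

## The analysis pipeline

1. **Cohort.** Each patient carries a three-class stage label (no ILD /
   limited / extensive, mirroring the 20 % extent threshold of visual
   staging), a full-chest volume with a lung mask, and a nine-slice reduced
   stack: three upper positions and six basal positions spaced exactly
   15 mm, each position acquired twice with independent noise.
2. **Preprocessing.** Only the six basal positions are retained (the upper
   sub-scan is discarded unconditionally, even when it overlaps the lower
   one). Of the two duplicates per position, the slice with the higher
   signal-to-noise ratio is kept; SNR is defined as |in-ROI mean| / in-ROI
   standard deviation, which needs no background segmentation and ranks
   duplicates identically to background-based variants when only the noise
   differs. Volumes are resampled trilinearly to 2 mm isotropic voxels;
   reduced slices bilinearly in-plane to 0.72 mm or 2 mm. Masks are
   interpolated linearly and thresholded at 0.5 (partial-volume consistent;
   nearest-neighbour biases thin basal regions). Grey levels are discretized
   with a fixed 50 HU bin width over [−1000, 200] HU (24 bins); out-of-range
   values are clipped, not dropped, so the ROI voxel count is invariant.
3. **Features.** Intensity-histogram statistics on continuous HU values
   (population moments; kurtosis is non-excess, so a Gaussian scores 3),
   GLCM statistics (symmetric accumulation, counts merged over 4 in-plane /
   13 spatial directions before normalization) and GLSZM statistics
   (8-/26-connectivity) on the discretized image, all repeated on every
   sub-band of a single-level decimated `coif1` wavelet transform with
   symmetric padding. Sub-band images are re-discretized to a fixed 24-bin
   count over their in-ROI range, since HU bin edges are meaningless after
   filtering; sub-band masks are obtained by linear resampling of the ROI to
   the half-resolution grid. 2D features are computed per slice and averaged
   over slices containing ROI pixels. The exact feature inventory of the
   original software is not public; this package implements the intensity,
   GLCM and GLSZM families in full (235 2D / 423 3D columns), which is a
   subset by design — feature *counts* are not a comparison target.
4. **Screening.** Features with any missing value or fewer than five unique
   values are dropped (no imputation; uniqueness counted on exact float
   equality). Univariate AUC per feature comes from the Mann-Whitney U
   statistic with midrank ties; AUCs below 0.5 are folded to 1 − AUC before
   summarizing, so predictive strength is compared independently of effect
   direction. Folding is applied before computing medians.
5. **Models.** Two endpoints: diagnosis (any ILD vs none, full cohort) and
   staging (extensive vs limited, diseased subset). Four families: logistic
   regression on the intensity mean (M) or on mean + sd + skewness +
   kurtosis (MSDSK); and two data-driven workflows — logistic regression
   with embedded LR-based selection (LR-LR) and extra-trees with embedded
   ET-based selection (ET-ET) — preceded by greedy Pearson-correlation
   pruning in rank order (rank by extraction order, F-score, or
   Kruskal-Wallis H; all tunable) and by Z-scoring followed by the
   Yeo-Johnson power transform (in that order). Selection keeps features
   whose embedded-model importance clears a tunable quantile, never fewer
   than one.
6. **Nested CV.** Hyperparameters are tuned by random search scored with
   mean ROC AUC on a 3×-repeated 10-fold inner loop (300 samples);
   generalization is measured on a 2×-repeated 5-fold outer loop. Folds are
   stratified — required for a 23-positive staging class under 5 folds.
   "AUC tuning" reports the winning configuration's inner score (mean over
   outer folds; sd pooled over the winners' inner-fold scores), "AUC
   testing" the mean ± sd of the outer test-fold AUCs. One global seed
   streams per-fold sub-seeds, so results are bit-reproducible.
7. **Operating point.** Per-fold ROC curves are averaged vertically (TPR and
   threshold interpolated on a fixed 101-point FPR grid). The cutoff sits at
   the maximum of Youden's J on the averaged curve, ties resolved toward the
   more specific point. The metric panel (accuracy, sensitivity,
   specificity, PPV, NPV, DLR±) is computed on pooled out-of-fold
   predictions with 95 % CIs — Wald with a continuity guard at the boundary
   by default, exact Clopper-Pearson by configuration; likelihood-ratio CIs
   use the standard log-transform formula. Precision-recall curves with
   step-interpolated area accompany every panel because the classes are
   imbalanced.

## The synthetic cohort generator

The generator emulates the features of the clinical data the analysis is
sensitive to, and nothing else:

* **Geometry.** Two half-ellipsoid lungs with a flattened base inside a
  64×64×64-voxel volume at 3.0×2.5×2.5 mm (z, y, x). Airways, vessels and
  mediastinum are absent: masks are pipeline *inputs* in the real workflow,
  so anatomical realism buys nothing for testing it.
* **Disease.** A Gaussian random field smoothed to a 6 mm correlation
  length, multiplied by a logistic ramp in z (strength 6 by default; 0
  disables the gradient), thresholded at the quantile producing the target
  extent fraction: below 20 % of lung volume for "limited", above for
  "extensive". Diseased tissue raises mean attenuation from −850 HU toward
  −400 HU through a soft (1-voxel blurred) edge and carries a second,
  stronger texture field (sd 90 HU vs 35 HU in healthy parenchyma), which
  is what makes the disease visible to co-occurrence and size-zone
  statistics and not only to the histogram mean.
* **Reduced protocol.** Six basal positions at exactly 15 mm starting one
  slice above the lung base, plus three upper positions; every position is
  an exact plane of the generated volume plus independent white Gaussian
  noise, one duplicate at sd 20 HU and one at 60 HU in randomized order, so
  SNR-based duplicate selection is genuinely exercised.
* **What it does not model.** Scanner kernels, dose, beam hardening,
  respiratory motion, inter-scanner variation, lobar anatomy, and real
  fibrosis morphology. Passing tests therefore show the *pipeline* behaves
  correctly and that its comparative claims hold under the stated
  statistical structure — not that the same effect sizes would be observed
  in patients.

HU anchors, noise levels and the correlation length are plausible values
fixed once (the source material reports no per-class HU statistics); all are
configurable.

## Numerical choices

* Discretization maps the upper range limit into the top bin; bins are
  1..24 inside the ROI and 0 outside.
* Resampling uses tri/bilinear interpolation (monotone, no ringing at the
  −1000 HU air boundary); a constant field resamples to itself exactly.
* GLCM correlation of a zero-variance (single-bin) image is defined as 1.
* The Yeo-Johnson lambda is fit per feature by maximum likelihood on a
  vectorized 81-point grid over [−3, 5] with parabolic sharpening; this
  matches a scalar-optimizer reference to ±0.02 in lambda and is an order
  of magnitude faster, which matters because the transform is refit inside
  every inner CV fold. A closed-form transform for a given lambda is
  exposed separately.
* Duplicate-slice SNR ties go to the first-listed duplicate; Youden ties go
  to the smaller FPR; both tie-breaks are exact and deterministic, with a
  1e-9 tolerance absorbing float noise in the Youden comparison.
* Degenerate folds (a class absent from an inner split, possible only on
  very small cohorts) are skipped when averaging inner scores; constant
  score vectors make the operating cutoff undefined and raise.

## Problem sizes used in tests and the acceptance script

The full protocol (166 patients, 300-sample random search, 3×10-fold inner
loop) is the package default. The verification runs are scaled down, chosen
once as study conditions for a single-CPU run: cohorts of 120 (null
calibration, 60/35/25) and 60 (power and directionality, 30/15/15) patients
on 48×40×40 phantoms, five generator seeds per experiment, a 1×3-fold inner
loop with 10 search samples (30 for the quantitative-CT models, matching the
reduced-budget convention of the power checks), the full 2×5-fold outer
loop, and an extra-trees budget of 50-150 trees. Null-calibration bounds
were fixed before measurement: family-mean testing AUC within 0.5 ± 0.1 and
|mean Youden J| < 0.25 (≈2 sigma of the null J estimator at these class
sizes). The optimism check (tuning ≥ testing AUC) runs on label-permuted
cohorts because diseased cohorts saturate both estimates at 1.0, making the
inequality trivially tight.

## Known limitations

* The feature inventory is intentionally smaller than the original
  software's (no GLRLM/NGTDM families, no shape features, single-level
  wavelets only), so absolute feature counts differ.
* The 2D aggregation averages per-slice feature values (one of the standard
  aggregation schemes); other schemes (merging matrices across slices)
  would give systematically different texture values.
* Wald proportion intervals can degenerate near 0/1; the exact method is
  available per configuration but both are approximations at the small
  staging denominators.
* Patient-level results of the motivating clinical study are not
  reproducible here by construction; all acceptance evidence is
  property-based.
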