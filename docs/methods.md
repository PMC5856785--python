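# Methods

## Problem and model

The pipeline scores a segmented lung nodule on thin-section CT for the
probability of visceral pleural invasion. The working object is the VOI: a
3D grid of Hounsfield-unit intensities, an aligned binary mask and the
voxel spacing in mm, indexed `(slice, row, column)` with axis 0 axial.
The final model is a soft-margin SVM with the radial basis kernel
k(x, x′) = exp(−γ‖x − x′‖²) on a small set of selected, standardized
features; its raw decision value x is mapped to the signature probability
Pi = 1/(1 + e^(−x)). No Platt-style recalibration is applied: the sigmoid
is a fixed monotone transform, so Pi preserves the ranking (and therefore
the AUC) of the decision values exactly, and the probability scale should
be read as a convention rather than a calibrated risk.

## Feature catalog (308)

* **Shape (8).** Longest 3D diameter = maximal centre-to-centre distance
  between surface-voxel centres in mm (computed on convex-hull vertices
  when the surface is large); volume = voxel count × voxel volume; surface
  area from a marching-cubes mesh of the 0.5 iso-surface on the
  zero-padded mask; sphericity π^(1/3)(6V)^(2/3)/A and compactness
  36πV²/A³ (both 1 for an ideal sphere; the mesh convention makes a
  digital ball come out near 0.97); elongation √(λ2/λ1) and flatness
  √(λ3/λ1) from the voxel-coordinate covariance eigenvalues; surface/volume
  ratio. A single-voxel mask has diameter 0 and NaN for the ratios that
  need an extended region.
* **Histogram (9).** Population moments of the in-mask HU values;
  kurtosis is the Fisher (excess) convention; percentiles are lower
  percentiles with linear interpolation between order statistics (the 10th
  percentile is the point with 10% of voxel values to its left).
  Skewness/kurtosis of a constant region are NaN.
* **Texture (271).** Intensities are first quantized to 64 equal-width
  levels over the in-mask min–max range (level 1..64; a constant region is
  all level 1). Co-occurrence and run-length statistics are computed per
  axial slice in 2D and aggregated by summing the count matrices over
  slices before normalizing — this matches the `S(d1,d2)` / `45dgr` naming
  convention of the feature labels. GLCM: offsets (0,d), (d,0), (d,d),
  (d,−d) for d = 1..5; only pairs with both voxels in-mask count; the
  matrix is symmetrized and normalized to sum 1; 12 statistics (angular
  second moment, contrast, correlation, sum of squares, inverse difference
  moment, sum average, sum variance, sum entropy, entropy, difference
  variance, difference entropy, dissimilarity), entropies in nats. The
  correlation of a constant region is NaN. GLRLM: maximal equal-level
  in-mask runs along 0°/45°/90°/135° within each slice (mask gaps break
  runs); 7 statistics per direction (short/long-run emphasis, gray-level
  and run-length non-uniformity, run percentage, low/high gray-level run
  emphasis) plus gray-level non-uniformity, run-length non-uniformity and
  run percentage on the runs pooled over the four directions. The
  240 + 31 split is this package's reconstruction of the printed
  271-feature total; the catalog module is the single source of truth for
  names and ordering.
* **Wavelet (20).** Per-slice 2D coiflet-1 transform of the mask bounding
  box, outside-mask voxels filled with the in-mask mean and the box padded
  (same fill) to ≥ 32 px per in-plane axis so five scales always exist.
  Periodized boundary handling is used instead of symmetric extension:
  coif1 is orthogonal, so with periodization the four subbands partition
  the input energy exactly at every level, which makes the energies
  well-defined and testable; symmetric extension would break that
  identity at the boundary. Subband energy = mean squared coefficient over
  coefficients whose support touches the mask (the mask is cascaded
  through the same transform to locate them), averaged over slices with
  mask content. LL/LH/HL/HH map to the approximation, horizontal,
  vertical and diagonal detail bands.

## Feature reduction

1. **Reproducibility.** For each feature, the concordance correlation
   coefficient between two replicate extractions, evaluated with
   population (divide-by-n) moments. Conventions for degenerate input:
   both replicates constant and equal → 1; constant with unequal means or
   only one constant → 0. Keep features with CCC ≥ 0.9, ranked by CCC
   (ties by catalog order), capped at 100.
2. **Redundancy.** Distance 1 − |Pearson r| on standardized columns;
   while any pair is closer than 0.05, drop the member with the lower CCC
   (tie: later catalog position). The "nearest neighbor distance" of the
   original description is not defined there; correlation distance is this
   package's choice. Constant columns are dropped with a warning.
3. **SVM-RFE.** A linear maximum-margin classifier is refit after every
   single-feature elimination (no chunking); the eliminated feature's
   squared weight becomes its raw contribution, normalized into ω summing
   to 1 over all features; ranking = reverse elimination order. Selection
   keeps the shortest prefix with Σω ≥ 0.80 (a fixed-k mode exists because
   the 80% stop and the published per-feature weight figures are in
   tension). The linear SVM used only for ranking defaults to C = 0.01:
   with nearly separable cohorts and weak regularization the margin is
   carried by a few dominant features and the ranking of moderate-effect
   features degenerates to noise, whereas a strongly regularized margin
   spreads weight over all informative features and gives a stable
   elimination order. The classifier proper remains the RBF-SVM above.
   The ranking stage is intentionally linear even though the final kernel
   is RBF — an RBF margin has no per-feature weight to rank by.

## Cross-validation and operating point

"Repeated leave-one-out ten-fold" validation is implemented as 10-repeat
stratified 10-fold CV: per repeat every case appears in exactly one
validation fold. Inside each training split, standardization, SVM-RFE
selection and a stratified 3-fold grid search over C ∈ {0.1, 1, 10, 100},
γ ∈ {0.001, 0.01, 0.1, 1} (AUC-scored) are re-fit from scratch; the
validation fold contributes nothing to any fitted quantity, which the test
suite asserts by flipping validation labels under a fixed fold assignment.
The per-case signature is the mean Pi over repeats (repeat-averaging
demonstrably reduces prediction variance on null data). The operating
point maximizes the Youden index J = sensitivity + specificity − 1 over
midpoints between adjacent distinct Pi values; among ties the
higher-specificity (then higher) cut-off wins; the same point is reported
on the decision scale as logit(Pi). An all-equal score vector yields a
flagged non-informative cut-off.

## Evaluation statistics

DeLong's method provides the AUC (midrank Mann–Whitney statistic, ties ½),
its standard error from the positive/negative structural components, a
normal 95% CI clipped to [0, 1], and the paired-curve z-test. The
concordance index is computed by direct pair counting and equals the AUC
for binary outcomes. Confusion metrics are the standard 2×2 quantities in
percent with likelihood ratios on the ratio scale. Odds ratios come from a
statsmodels logistic fit (for a binary predictor this equals ad/bc; AIC =
2k − 2logL); complete separation is flagged with an optional
Haldane–Anscombe +0.5 correction. Mann–Whitney uses the exact null for
groups ≤ 8 without ties, else the tie-corrected normal approximation;
Wilcoxon signed-rank drops zero differences, exact for ≤ 12, else the
continuity-corrected approximation. Cohort contingency tables get row and
column percentages (rounded to 0.1, the printed convention) and a 1-df
Pearson χ² per category against the pooled rest, without continuity
correction. AIC is reported as a plain information criterion; it is not a
percentage and no normalized variant is invented for it.

## Synthetic cohorts

The study's 327-patient CT cohort (192 VPI−, 135 VPI+) is not public, so
the generators reproduce its published summary statistics rather than its
images:

* **Feature cohorts** draw the five top-ranked signature features
  (`Perc.10%`, `WavEnLL_s-2`, `S(0,1)SumAverage`, `45dgr_GLevNonU`,
  `S(3,3)Contrast`) as per-class independent Gaussians with the published
  class means and SDs, defaults n = 192/135, plus 15 class-independent
  noise features; an optional equicorrelation models shared variance.
  Independence is the simplest model consistent with the printed
  mean ± SD table — real radiomics features are strongly cross-correlated
  and non-Gaussian, so cross-validated performance here (AUC ≈ 1) is
  easier than on real CT and should be read as a pipeline check, not a
  clinical estimate.
* **Image cohorts** place a jittered ellipsoidal nodule (radius 6–10 mm)
  on a −800 HU background at −150 HU, with a class intensity shift and a
  class-specific texture correlation length realized as Gaussian-smoothed
  white noise (SD 80 HU) — enough to move histogram, GLCM/GLRLM and
  wavelet statistics between classes without simulating lung anatomy,
  pleural geometry or CT reconstruction physics.
* **Replicate pairs** for the CCC stage come from perturbing a
  segmentation (±1 voxel dilation/erosion plus HU noise) or, for feature
  tables, adding per-feature Gaussian measurement noise at 5% of the
  column SD; inter-reader variability of the original study was never
  quantified, so these magnitudes are package choices.

All generators are bit-reproducible under a fixed seed; the pipeline
derives per-stage seeds as (base seed + CRC32(stage name)) mod 2³¹ so each
stage can be replayed independently.

## Numerical conventions and problem sizes

Equal-width quantization (64 levels) and all matrix conventions above are
frozen defaults, exposed in configuration. The ω normalization guards the
zero-total corner case by falling back to uniform weights. The acceptance
script runs the full nested CV at 160+110 cases (10×10 folds), the null
control at 50/class (3×10), and 20 recovery replicates of the 100-feature
ranking — sizes at which the whole recomputation finishes in well under a
minute on a single CPU while keeping Monte-Carlo noise small.

## Known limitations

Texture is 2D-per-slice by design (matching the label conventions); a
13-direction 3D mode is deliberately not implemented. The wavelet support
mask is located by transforming the mask itself, which slightly smears
support at subband boundaries. The synthetic feature model cannot probe
feature-extraction ↔ selection interactions (its features are drawn, not
extracted); the image generator covers that path at small n. Survival
endpoints are out of scope.
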