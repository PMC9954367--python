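# Methods

## Problem and model

The pipeline estimates, per tumor pixel, whether the tissue belongs to the
highly cellular compartment of an ovarian tumor. Ground truth is defined
physiologically: dense cellularity restricts water diffusion, so a pixel is
"high cellularity" when its apparent diffusion coefficient is below
0.85 × 10⁻³ mm²/s. The classifier never sees the ADC map at prediction
time — it works from T2-weighted radiomics — so the system is a learned
mapping from T2 appearance to diffusion-defined cellularity class.

The forward physics used throughout (and by the phantom) is the
monoexponential diffusion decay

```
S(b) = S0 · exp(−b · ADC(x)),      b in s/mm², ADC in mm²/s
```

with additive Gaussian noise. The fallback ADC fit inverts this model by
ordinary least squares of ln S against b (intercept included, slope
negated, clipped at zero); it is exact on noiseless data.

## Synthetic phantom

The generator emulates the statistical structure the pipeline relies on,
not anatomy:

* a body ellipsoid (anisotropic in-plane so that rotations are
  identifiable by registration) surrounded by air, containing two
  bone-like low-ADC anchor structures that give the interior stable
  landmarks;
* a tumor ellipsoid split into spatially structured subregions by
  thresholding a smooth random field at the volume-fraction quantiles.
  Defaults: a highly cellular part (ADC 0.7 × 10⁻³ mm²/s, 40 % of the
  volume) and a low-cellularity part (1.1 × 10⁻³ mm²/s) — both sides of
  the labeling cut-off, with jitter across cohort cases;
* DWI subseries at b = {0, 600, 1200} s/mm² from the decay law (the
  b-value set beyond 1200 is a package choice; only b = 1200 is
  structurally required). S0 is tissue-dependent (tumor 260, body 150,
  air 5) so the tumor is the single hyperintense structure at high b;
* a T2 volume whose subregion means differ moderately (175 vs 140) and
  whose texture differs in amplitude and correlation length (26 @ 0.9 mm
  vs 12 @ 2.5 mm), so T2 radiomics carry cellularity information without
  copying the ADC map;
* a known misalignment of the DWI/ADC frame: rigid rotation + translation
  plus a Gaussian-smoothed random elastic field (amplitude ≈ 1 mm RMS,
  smoothness 8 mm), recorded for registration tests.

Default grid: 14 slices of 56×56 voxels at 2.6 × 1.0 × 1.0 mm, noise
σ = 3 (tumor contrast-to-noise ≫ 5). Compartment boundaries are crisp;
partial-volume softening enters only through the interpolation of the
misalignment/alignment resampling. What passing tests on these phantoms
show is that the machinery is correct and that the pipeline recovers a
planted T2↔cellularity association; they cannot show that real T2 texture
carries such a signal, which is a property of the data, not the code.
Rician noise, bias fields, fat/water effects and multifocal tumors are
deliberately not modelled.

## Registration

Transforms map fixed (T2) world coordinates to moving coordinates; the
moving volume is resampled onto the T2 grid by linear interpolation, and
the affine and elastic stages are composed into a single resampling.

* **Metric**: mutual information (nats) of a 32-bin joint histogram over a
  seeded 20 % voxel sample, linearly interpolated in the moving volume.
* **Optimizer**: Nelder–Mead downhill simplex, run coarse-to-fine over
  translation (initialized at the intensity centre-of-mass offset), then
  rigid, then full affine (rotation, translation, scale, shear; scale and
  shear enter the parameter vector ×50 so all simplex steps are
  comparable). Up to 500 simplex iterations per stage, `xatol` 0.01 —
  fewer iterations routinely stop short of the 1 mm / 1° recovery the
  package aims for.
* **Demons**: classic intensity-driven updates. With the warp convention
  `m_w(x) = m(x + u(x))`, the first-order step is
  `(f − m_w)·∇f / (|∇f|² + (f − m_w)²)`; the accumulated field is
  Gaussian-smoothed (σ = 2 mm by default, matched to the centimetre-scale
  smoothness of inter-sequence warps; narrower deformations warrant a
  smaller σ) each iteration, and a step is accepted only
  if the RMS difference does not increase, so the RMS trace is
  non-increasing by construction and a cross-modality mismatch can at
  worst leave the field at zero. At most 50 iterations, stopping when the
  relative RMS improvement falls below 10⁻⁴. Because T2 and DWI are
  different modalities, Demons runs on histogram-matched intensities.
* **Which subseries drives the registration**: b = 0, because it carries
  the most anatomical signal and the DWI subseries share one frame; the
  estimated transform is applied identically to every b-value and to the
  ADC map. The final resampling of the aligned volumes uses cubic
  interpolation (linear resampling visibly blunts tissue edges and puts a
  floor under the achievable RMS); the metric's interpolation stays
  linear, and the resampled ADC map is clipped at zero.
* The RMS difference doubles as the alignment-quality report
  (histogram-matched across modalities). In the registration-recovery
  experiment the post/pre RMS ratio is measured by applying the recovered
  transform to a noise-free twin of the same phantom: with noisy volumes
  the decorrelation of independent noise puts a floor under the ratio that
  has nothing to do with alignment quality.

## Segmentation and labeling

K-means (k = 2, k-means++ seeding, 10 restarts) on the b = 1200 voxel
intensities; the brightest cluster, reduced to its largest 3D connected
component, is the tumor. The radiologist validation used in clinical
practice is replaced by phantom ground truth (Dice). Labels inside the
mask: ADC < 0.85 × 10⁻³ mm²/s → high; ADC within [0.85, 1.0] × 10⁻³ →
"uncertain" (overlay display only); else low. The binary training target
collapses uncertain into low. Label maps are exported with integer codes
{0 background, 1 high, 2 low, 3 uncertain}.

## Per-pixel features

Feature extraction is slice-wise on the ROI crop of the T2 volume
(bounding box of the mask, background zeroed, offset recorded so
predictions map back to the original grid). The reconciliation between
slice-level texture statistics and pixel-level classification is a sliding
window: each tumor pixel's texture features are computed in the 9×9 window
centred on it, intersected with the tumor mask. Its feature vector is

* the value of each filter-bank image at the pixel (14 images: original,
  stationary-wavelet LL/LH/HL/HH (coiflet-1, level 1), LoG at σ = 1, 2,
  3 mm, square, square root, logarithm, exponential, gradient magnitude,
  uniform 8-neighbour LBP). The four intensity remappings are linearly
  rescaled back to the original intensity range; logarithm uses
  log(1+|x|) and exponential e^(|x|/max|x|), so zero images never produce
  NaN;
* 19 first-order statistics of the raw window intensities (entropy and
  uniformity on a 32-bin equal-width histogram; kurtosis is not
  excess-corrected; skewness/kurtosis of a constant window are defined as
  0);
* texture-matrix features of the discretized window: GLCM (24 features;
  distance 1, four angles, symmetric, angle-averaged; log2 entropies;
  correlation of a flat matrix defined as 1; the MCC eigenvalue is floored
  at 10⁻¹² before the square root because round-off-scale eigenvalues are
  genuine zeros), GLRLM (16; four directions, mask gaps break runs),
  GLSZM (16; 8-connected zones), GLDM (14; δ = 1, α = 0, dependence =
  1 + dependent neighbours so it is never zero), NGTDM (5; δ = 1,
  coarseness = 1/(10⁻⁶ + Σ pᵢsᵢ), so a constant region scores 10⁶);
* nine 2D shape descriptors of the slice's tumor outline (area, perimeter,
  their ratio, circularity, axis lengths, elongation, eccentricity,
  maximum Feret diameter), identical for all pixels of a slice.

Discretization (32 equal-width bins over the masked slice intensities) is
done once per slice, so window features are comparable within a slice and
invariant to intensity shifts that preserve bin assignment. Pixels whose
window supports no texture matrix (fewer than 2 masked pixels or no
co-occurring pair) are dropped with a logged count. Rows are ordered
(slice, row-major) and chunked into blocks of 400 pixels — the unit used
at prediction time. Constant columns are removed on the training side
only.

## Selection and classification

RFE-CV removes 10 % of the remaining features per round (a linear
estimator's smallest |weights|), scoring every subset size by balanced
accuracy under case-grouped K-fold CV (10 folds, or the number of cases if
smaller — pixels of one case never straddle train/validation). The chosen
size maximizes the mean CV score, ties toward the smaller subset. The
elimination loop is implemented in the package because the installed
sklearn RFECV cannot combine group-aware folds with this tie-break; sklearn
remains the estimator engine, and sklearn's own RFE serves as an
independent cross-check in the tests.

Estimators (both with inverse-frequency class weights, features
standardized with training statistics only):

* **svm** — `LinearSVC` (squared-hinge, C = 1, dual=False); an RBF kernel
  is available but then the model cannot drive RFE.
* **sgd** — hinge-loss linear model trained by mini-batch SGD (batch 32,
  100 epochs, inverse-scaling learning rate, η₀ = 0.01) via repeated
  `partial_fit`. Inside the elimination loop the per-sample sklearn
  `SGDClassifier` (same loss, schedule and weighting, 100 epochs) stands
  in, because the mini-batch loop is ~100× slower per fit and the loop
  fits hundreds of models.

Prediction is block-wise (400 rows at a time), one label per pixel.
Evaluation: accuracy, balanced accuracy (mean of the two class recalls),
sensitivity TP/(TP+FN), specificity TN/(TN+FP); a zero-denominator metric
is reported as missing and excluded from cohort averages with a note,
never as NaN.

## Problem sizes used in the shipped experiments

The validation experiments run at deliberately small scale: 8-case LOPO
cohorts (~700 tumor pixels per case, ~5 000 pixel rows overall), 10
phantoms for registration recovery, 600×55 matrices for selection
recovery, and texture-oracle batteries up to 8×8 images with ≤ 4 gray
levels. These sizes were chosen so a complete validation runs in minutes
on one CPU while every stage still operates in its intended regime.

## Known limitations

* Gaussian rather than Rician noise; no bias field; no anatomy.
* The Demons stage is cross-modality only through histogram matching; its
  accept/reject rule makes it conservative (it can stop at a zero field).
* 2D texture only (per-slice), as implied by slice-wise extraction.
* The filter inventory is a reasonable default, not a certified (IBSI)
  configuration; absolute feature values depend on the discretization and
  window choices documented above.
* With fewer than 10 cases the "10-fold" CV degrades gracefully to
  case-count folds; results on very small cohorts are accordingly noisy.
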