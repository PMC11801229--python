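# Methods

`coronalign` registers 2D coronal mouse-brain section images to an oblique
slice of a 3D reference atlas, warps the atlas region annotations onto the
tissue, detects cell-body-like signals by tiled blob detection, and
quantifies signals per anatomical region.  This note records the models,
conventions, numerical choices and limitations; every number quoted here is
computed by the test suite or by `scripts/acceptance.py`, not asserted from
memory.

## Atlas model and slice geometry

The reference atlas is a 3D intensity volume (e.g. the Allen CCF 10 µm Nissl
average) paired with a same-shaped integer annotation volume, axis order
anterior→posterior (AP), dorsal→ventral (DV), left→right (LR), isotropic
voxel size (default 10 µm).  A section is located by a `SlicePose`: the x
and y cut angles (rotations of the slicing plane in the x–z and y–z planes,
each restricted to [−10°, 10°], the plausible range of microtome error) and
an anterior–posterior position expressed as a fractional voxel index in
[0, ap_max] (0–1324 for the 10 µm volume).  Poses normalize affinely onto
[0, 1]³ for pose predictors; the round-trip is exact to floating point.

Conventions fixed here because the plane names alone do not determine them:

* a positive x angle tilts the plane normal from +AP toward +LR, a positive
  y angle toward +DV, x applied first;
* the rotation pivot is the section's centre point on the AP axis;
* out-of-volume samples are background (0), matching the zero-padded
  registration margins;
* intensity is sampled with linear interpolation, labels with nearest
  neighbour, so label slicing can never invent region ids;
* fractional AP indices are allowed (linear interpolation between planes) so
  fine-tuning can move in sub-index steps.

`generate_training_samples` reproduces the random-slicing scheme used to
train pose-regression networks: angles uniform in [−10, 10]², AP uniform in
[0, ap_max], a 50:50 choice of full section versus a single hemisphere
(left/right half of the LR axis, equiprobable), resized to 256×256.  The
stored pose is that of the full, pre-crop section.  Training such a network
is out of scope here; the pipeline instead accepts any `PosePredictor`
callable (256×256 image → normalized pose triple) and ships two: a constant
stub and a weights-free nearest-template matcher (Pearson correlation
against evenly spaced zero-angle atlas slices, angles predicted as 0°).
Predicted x/y angles are averaged across an experiment's sections (serial
sections share the physical cut plane) and users fine-tune per section by
editing the poses JSON.

## Registration

The atlas slice (moving) is registered onto the tissue section (fixed) in a
working frame: both images are resized to 360×360 (area averaging when
downscaling, linear when upscaling; aspect is not preserved), converted to
Sobel gradient-magnitude images min–max normalized to [0, 1] — the atlas
template and arbitrarily stained tissue share edge structure even when their
intensity statistics differ — zero-padded by 50 px to mitigate boundary
effects, cast to float32, and the moving gradient image is histogram-matched
onto the fixed one (1024 histogram levels, 10 match points).  With the
mean-intensity threshold on, pixels at or below the moving image's mean are
explicitly restored after matching, preserving the background range; note
the underlying ITK filter alone restricts only the histogram computation to
above-mean pixels, so the restore step is what realizes the documented
contract.  Because the protected set depends on the post-match mean, the
mean-thresholded variant is only approximately idempotent near the mean; the
distributional idempotence property holds with the threshold off.

Whether histogram matching should operate on raw intensities or on gradient
images is genuinely open; we match gradient images, since those are what the
similarity metrics compare.

Stage 1 is an affine fit T(x) = A·(x−c) + c + b initialized by aligning
intensity centroids (geometric centres for empty images), optimized under
Mattes mutual information with 32 bins over a 3-level pyramid (shrink
factors [4, 2, 1], smoothing sigmas [2, 1, 0]).  Stage 2 resamples the
moving image through the fitted affine and fits a cubic B-spline
displacement field on a 4×4 control mesh under a neighbourhood-correlation
metric (radius 3 px; a config switch selects MI instead), at full resolution
only.  Optimization is gradient descent with full (non-stochastic) metric
sampling — the procedure is therefore deterministic — run for up to 300
iterations per level with convergence declared when the metric changes less
than 1e−8 over a 20-iteration window, parameter scales set from physical
shifts.  The descent step is re-estimated every iteration against a cap of
`max_step_px` = 0.25 px of physical shift per iteration.  This cap is the
one numerically load-bearing choice in the optimizer: a fixed learning rate
of 0.01 with these scales does not move the parameters measurably, and a
once-per-level estimated rate is unstable when the initialization is already
near the optimum (the estimate is made where the gradient is vanishing).
The capped per-iteration estimate recovers identity to sub-pixel accuracy
and still traverses tens of pixels of misalignment within the iteration
budget.  There is no accept/reject step, so descent is monitored as
final-versus-initial objective per level rather than per-iteration
monotonicity.

All transforms are resampling maps (fixed-frame point → moving-frame point,
coordinates (x, y) = (column, row)), the convention SimpleITK's resampler
uses; for a moving image displaced by +d the fitted translation is +d.  The
composite applies the affine resample first, then the B-spline on the
affine-resampled image; as a single point map that is x → T_affine
(T_bspline(x)), and single-resample application agrees with the sequential
two-stage application to within interpolation error.  The composite is
applied to the atlas intensity with linear interpolation and to the labels
with nearest neighbour, padding is cropped, and outputs are resized back to
the fixed section's native resolution (nearest neighbour for labels).  The
transform serializes to JSON (affine matrix/translation/centre, B-spline
mesh, grid geometry and control-point displacements) and round-trips
exactly.

Damage masks are fixed-frame exclusion maps: masked pixels contribute to
neither metric, and the corresponding warped-atlas intensity pixels are
zeroed in the output (labels are left intact so region tables remain
complete; downstream analyses should exclude masked areas themselves).

B-spline stage notes: the stage runs at full resolution only (the pyramid is
specified for the affine stage; a coarse 4×4 mesh needs no pyramid), and the
literature this routine derives from is ambiguous about whether the second
stage resamples the fixed or the moving image — resampling the fixed image
would invert the roles mid-pipeline, so we resample the moving (atlas)
image.

## Synthetic phantoms

Closed-loop testing needs inputs with known ground truth, so the `synthetic`
module generates all three levels of data:

* **Phantom volume** — a smooth ellipsoidal "brain" (slight DV asymmetry so
  sections are not up/down symmetric) with n_regions labels: concentric
  shells emulating cortical layers plus one bilateral deep nucleus placed
  dorsally off-centre; intensity is a smoothed region-dependent value plus
  seeded Gaussian noise, background strictly darker than tissue.  Default
  shape 96×96×112 voxels keeps every downstream stage fast while leaving
  room for oblique cuts.
* **Deformed sections** — a phantom slice warped by an exactly known affine
  (rotation/scale/shear/translation about the section centre) plus a seeded
  random B-spline displacement on the same mesh family the registration
  fits, then gamma distortion and additive Gaussian noise on intensity only.
  The ground truth is returned in the same `CompositeTransform`
  representation the registration emits; since B-spline parameterizations
  are not unique, recovery is judged primarily by label Dice rather than by
  parameter distance.
* **Synthetic cells** — isotropic Gaussian blobs (σ drawn from 3–6 px, peak
  amplitude 0.5–1.0 over background noise σ = 0.05, so SNR ≥ 10) scattered
  inside a mask with a minimum-spacing rule, each with a ground-truth box of
  centre ± 2σ.  Centres keep a margin so every box lies fully on the
  canvas — a border-clipped cell has no well-defined box.

What the phantoms do **not** emulate: real staining variability, uneven
illumination, tears and folds, anisotropic section thickness, overlapping
cells, and the intensity statistics of real counterstains.  Passing the
closed loops therefore demonstrates that the machinery is self-consistent
and recovers known deformations of atlas-like images, not that accuracy on
real histology matches these numbers.

All generators take one explicit seed; nothing reads global RNG state.

## Detection

High-resolution signal images are tiled into 640×640 tiles with 50 %
overlap (the last tile on each axis is anchored to the image border; images
smaller than one tile become a single zero-padded tile).  Any detector
callable (tile → local detections) can be plugged in — the intended slot
for a trained object-detection model.  Aggregation: per-tile detections
whose box touches an interior tile edge are discarded (they are clipped
partial views; the overlapping neighbour tile sees the object fully),
survivors are shifted to global coordinates, clipped, filtered by a
confidence threshold (default 0.25, deliberately exposed per experiment),
and de-duplicated by greedy non-maximum suppression at IoU 0.5.

The shipped default detector is a classical multiscale difference-of-
Gaussians blob detector: scale-normalized DoG responses over σ ∈ [2, 8] px
(6 scales), 3D local maxima above an absolute response threshold of 0.08
(images are assumed scaled to ≈[0, 1]), cross-scale pruning of concentric
responses by centre distance, boxes of centre ± 2σ at the detected scale,
confidence = response/0.2 clipped to [0, 1].  The response threshold was
calibrated on the synthetic-cell generator's conditions so that SNR ≥ 5
blobs are detected and pure background noise stays silent.

## Quantification

Warped labels assign a region id to every pixel.  ISH-style signal images
are inverted, quantized to 8 bit (round-half-even; constant images map to
255), and thresholded strictly above 125 to form binary signal masks; per
region the table reports total pixels, signal pixels and their proportion.
Detections are assigned to the region under their box centre (cheap,
deterministic, and matching counting semantics; swappable for
majority-overlap if ever needed).  Centres on background are reported under
a reserved "unassigned" row, never dropped, so signal pixels and cell
counts are conserved exactly.  A CSV ontology (id, acronym, name,
parent_id; compatible with flattened Allen structure-ontology exports)
supports rolling tables up to any target acronym set: each region
contributes to its nearest target ancestor, integer columns sum exactly.

## Evaluation metrics

Dice is computed over whole-tissue foregrounds by default (Otsu threshold
for intensity images, label > 0 for annotations); per-region Dice is
available by masking single labels.  Contours are boundary-pixel sets
(foreground pixels 4-adjacent to background or on the border) — a
reproducible, oracle-checkable choice in place of subpixel polygons — and
the directed Hausdorff distance is taken between contour point sets.
Centroid distance is the Euclidean distance between foreground-pixel means.
Count agreement uses Pearson's product-moment correlation (n ≥ 3,
zero-variance input rejected).  Two empty masks have Dice 1.0 by
definition.

## Pipeline

`run_pipeline` chains predict → align → detect → quantify → evaluate from a
single JSON/TOML config; all stages are also available as separate CLI
subcommands.  Fine-tuning is file-based (edit poses.json between `predict`
and `align`) to keep the tool headless and testable.  Each section is
processed independently; failures are recorded per section in the manifest
and skipped.  The manifest stores the package version, a SHA-256 hash of the
canonical config, the seed and per-section status, so a run is reproducible
from its manifest; re-runs skip sections whose outputs exist unless forced.

## Problem sizes and reproduction

The acceptance script and test suite run everything on the 96×96×112
phantom: registrations use the full default working frame (360×360 + 50 px
padding), the deformable-recovery study uses ten seeded deformations
(≤5° rotation, ≤10 px translation, 3–6 px elastic amplitude, noise σ = 5 on
a ≈240-unit intensity scale), the detection loop uses 200 cells on a
1280×1280 canvas, and the training-sample statistics use n = 2000 draws.
`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes all headline numbers from scratch.

## Known limitations

* Only coronal sections of mouse-brain-shaped volumes; no sagittal or
  horizontal slicing, no non-mouse atlases.
* The affine stage can absorb some elastic deformation and vice versa;
  recovered parameters are therefore not unique even when the warped-label
  Dice is high.
* The template-matching pose predictor ignores cut angles (predicts 0°);
  it is an initializer, not a replacement for a trained regressor.
* The DoG detector assumes bright, roughly isotropic blobs on a darker
  background; densely packed or elongated cells need a trained detector
  plugged into the tiling interface.
* Working-frame resizing forces squares, so strongly non-square sections
  are anisotropically stretched during fitting (and un-stretched on
  output); extreme aspect ratios will degrade the metrics.
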