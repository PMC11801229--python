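# coronalign

Semiautomated alignment of coronal mouse-brain section images to a 3D
reference atlas, with tiled cell detection and per-region quantification.

Experimental neurohistology routinely asks "how much signal, in which brain
region?"  Answering it requires warping a reference atlas — a 3D template
volume with voxel-wise integer region annotations, such as the Allen CCF —
onto each imaged tissue section, despite cut-angle errors introduced at the
microtome and the mounting/staining deformations of real tissue.
`coronalign` implements that workflow for anyone doing standard 2D
epifluorescence or brightfield imaging of serial coronal sections:
neuroanatomists tracing projections, labs quantifying ISH or reporter
expression per region, and method developers who need a headless, scriptable
alternative to GUI alignment tools.

## Method

The pipeline has four steps per experiment:

1. **Predict** — estimate each section's pose in the atlas: x and y cut
   angles (plane rotations in the x–z and y–z planes, each in [−10°, 10°])
   and anterior–posterior position z (a fractional index in [0, 1324] for
   the 10 µm volume).  Any predictor callable can be plugged in; a
   weights-free template matcher is shipped.  Predicted angles are averaged
   across the experiment's serial sections, and the resulting `poses.json`
   is hand-editable (fine-tuning).
2. **Align** — slice the atlas at the pose (intensity linear, labels
   nearest-neighbour) and register the atlas slice *M* onto the tissue
   section *F* with a composite transform: an affine stage
   T_affine(x) = A·x + b fitted by minimizing negated Mattes mutual
   information (32 bins) under 3-level multiresolution gradient descent,
   then a cubic B-spline stage T_bspline(x) = Σᵢ Pᵢ Bᵢ(x) on a 4×4 control
   mesh fitted with a neighbourhood-correlation metric on the
   affine-resampled image.  Both stages compare Sobel gradient-magnitude
   images at a 360×360 working size with a 50 px zero-padded margin, after
   histogram-matching M's gradients onto F's.  Binary damage masks exclude
   artifact areas from both metrics.  The composite warps the atlas
   annotation onto the tissue.
3. **Detect** — tile the high-resolution signal channel into 640×640 tiles
   with 50 % overlap, run a pluggable detector per tile (default: a
   multiscale difference-of-Gaussians blob detector), and merge by greedy
   non-maximum suppression at IoU 0.5.
4. **Quantify** — threshold ISH-style signal (invert, 8-bit, strict > 125)
   and tally per region id: total pixels, signal pixels and their
   proportion, plus cell counts assigned by detection-box centre; roll
   results up a region ontology without losing a single pixel or cell.

Alignment quality is scored with the Dice similarity coefficient
2|A∩B|/(|A|+|B|), the directed Hausdorff distance between boundary
contours, and centroid distance.  A synthetic-phantom module generates
brain-like volumes, deformed sections with exactly known ground-truth
transforms, and scattered Gaussian "cells" with ground-truth boxes, so
every stage is tested closed-loop without external data.

## Worked example

Generate a phantom "experiment" and run the full pipeline:

```bash
coronalign synth phantom --shape 96,96,112 --regions 5 --seed 3 --out vol.nrrd
coronalign synth section --volume vol.nrrd --ap 48 --rotation 3 \
    --translation 5,-4 --elastic 4 --noise 5 --seed 1 --out images/s0.tif
coronalign slice --volume vol.nrrd --ap 48 --out atlas_s0.tif
```

In Python, register the deformed section back to the atlas slice and score
the recovered annotation against the known ground truth:

```python
from coronalign.atlas import SlicePose, slice_volume
from coronalign.evaluate import dice
from coronalign.register import register_composite
from coronalign.synthetic import (DeformationSpec, PhantomSpec,
                                  make_deformed_section, make_phantom_volume)

vol = make_phantom_volume(PhantomSpec(shape=(96, 96, 112), n_regions=5, seed=3))
pose = SlicePose(ap_index=48.0)
atlas_slice = slice_volume(vol, pose)
section, truth = make_deformed_section(
    vol, pose, DeformationSpec(rotation_deg=3.0, translation_px=(5, -4),
                               bspline_amplitude_px=4.0, noise_sigma=5.0, seed=1))

result = register_composite(section, atlas_slice)
print(f"composite Dice   {dice(result.warped_labels > 0, section.labels > 0):.4f}")
print(f"affine-only Dice {dice(result.warped_labels_affine > 0, section.labels > 0):.4f}")
```

```
composite Dice   0.9932
affine-only Dice 0.9838
```

The composite (affine + B-spline) annotation overlaps the ground-truth
tissue labels almost perfectly, and the elastic stage measurably improves
on the affine fit — on real tissue this is the difference between region
boundaries that hug the cortex and ones that cut across it.

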