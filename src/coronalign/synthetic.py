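"""Synthetic phantoms with known ground truth for closed-loop testing.

Three generators: a brain-like 3D phantom volume (smooth ellipsoidal
foreground with nested "cortical layer" shells and a bilateral deep
nucleus), synthetically deformed "experimental" sections whose exact
affine + B-spline deformation is returned alongside the image, and
scattered Gaussian "cell bodies" with ground-truth bounding boxes.  Every
generator takes an explicit seed and is bit-reproducible; there is no
global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .atlas import AtlasVolume, Section, SlicePose, slice_volume
from .register import (
    AffineTransform,
    BSplineTransform,
    CompositeTransform,
    apply_transform,
)


@dataclass
class PhantomSpec:
    """Parameters of the phantom atlas volume."""

    shape: tuple[int, int, int] = (96, 96, 112)
    n_regions: int = 5
    smoothness_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(v) for v in self.shape)
        if len(self.shape) != 3 or min(self.shape) < 32:
            raise ValueError("phantom shape must be 3D with every extent >= 32")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")


@dataclass
class DeformationSpec:
    """An exactly-known affine + elastic deformation of a section.

    Models the mounting/sectioning distortions of real tissue: a global
    rotation/scale/shear/shift plus a smooth random B-spline displacement,
    with optional gamma distortion and additive noise on the intensity only.
    """

    rotation_deg: float = 0.0
    scale: float = 1.0
    shear: float = 0.0
    translation_px: tuple[float, float] = (0.0, 0.0)
    bspline_amplitude_px: float = 0.0
    bspline_mesh: tuple[int, int] = (4, 4)
    noise_sigma: float = 0.0
    intensity_gamma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.bspline_amplitude_px < 0:
            raise ValueError("bspline_amplitude_px must be non-negative")


def make_phantom_volume(spec: PhantomSpec) -> AtlasVolume:
    """Brain-like phantom: ellipsoid with nested shells and a bilateral nucleus.

    Labels 1..n_regions−1 are concentric shells (1 outermost); label
    n_regions is a bilateral deep nucleus placed dorsally off-centre so
    sections carry enough asymmetric structure for registration.  Intensity
    is a smoothed region-dependent value plus seeded Gaussian noise, with
    background strictly darker than tissue.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    zz, yy, xx = np.meshgrid(
        np.linspace(-1, 1, nz), np.linspace(-1, 1, ny), np.linspace(-1, 1, nx),
        indexing="ij",
    )
    # Normalized ellipsoidal radius; slight DV asymmetry breaks up/down symmetry.
    r = np.sqrt((zz / 0.85) ** 2 + ((yy + 0.08 * yy * yy) / 0.75) ** 2 + (xx / 0.85) ** 2)
    labels = np.zeros(spec.shape, dtype=np.int32)
    n_shells = spec.n_regions - 1
    edges = np.linspace(1.0, 0.0, n_shells + 1)
    for i in range(n_shells):
        shell = (r < edges[i]) & (r >= edges[i + 1])
        labels[shell] = i + 1
    labels[r < edges[-1]] = n_shells  # innermost core belongs to last shell
    # Bilateral nucleus: two ellipsoids mirrored across the midline, dorsal.
    nucleus = np.zeros(spec.shape, dtype=bool)
    for sx in (-1, 1):
        d = np.sqrt(
            (zz / 0.25) ** 2
            + ((yy + 0.35) / 0.22) ** 2
            + ((xx - sx * 0.4) / 0.2) ** 2
        )
        nucleus |= d < 1.0
    nucleus &= r < 1.0
    labels[nucleus] = spec.n_regions

    base = np.zeros(spec.shape, dtype=np.float64)
    # Distinct, bright region intensities over a dark background.
    values = 60.0 + 180.0 * (1 + np.arange(spec.n_regions)) / spec.n_regions
    rng.shuffle(values)
    for rid in range(1, spec.n_regions + 1):
        base[labels == rid] = values[rid - 1]
    base = ndimage.gaussian_filter(base, spec.smoothness_sigma)
    base += rng.normal(0.0, 4.0, size=spec.shape)
    base = np.clip(base, 0, None)
    return AtlasVolume(intensity=base.astype(np.float32), labels=labels)


def _affine_about_center(shape: tuple[int, int], d: DeformationSpec) -> AffineTransform:
    h, w = shape
    th = np.deg2rad(d.rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    shear = np.array([[1.0, d.shear], [0.0, 1.0]])
    a = d.scale * rot @ shear
    return AffineTransform(
        matrix=a,
        translation=np.asarray(d.translation_px, dtype=float),
        center=np.array([(w - 1) / 2.0, (h - 1) / 2.0]),
    )


def _random_bspline(shape: tuple[int, int], d: DeformationSpec,
                    rng: np.random.Generator) -> BSplineTransform:
    h, w = shape
    init = sitk.BSplineTransformInitializer(
        sitk.Image(int(w), int(h), sitk.sitkFloat32),
        transformDomainMeshSize=list(d.bspline_mesh),
    )
    params = rng.uniform(-d.bspline_amplitude_px, d.bspline_amplitude_px,
                         size=len(init.GetParameters()))
    return BSplineTransform(
        mesh_size=d.bspline_mesh,
        fixed_parameters=tuple(init.GetFixedParameters()),
        parameters=params,
    )


def make_deformed_section(
    volume: AtlasVolume, pose: SlicePose, d: DeformationSpec
) -> tuple[Section, CompositeTransform]:
    """Slice the volume, then apply a known affine + B-spline deformation.

    Returns the deformed section (image warped with linear interpolation and
    gamma/noise applied to intensity only; labels warped with nearest
    neighbour — these are the ground-truth region labels of the synthetic
    tissue) and the exact deformation as a :class:`CompositeTransform` in the
    same resampling convention the registration emits.
    """
    rng = np.random.default_rng(d.seed)
    clean = slice_volume(volume, pose)
    shape = clean.image.shape
    affine = _affine_about_center(shape, d)
    if d.bspline_amplitude_px > 0:
        bspline = _random_bspline(shape, d, rng)
    else:
        bspline = None
    truth = CompositeTransform(affine, bspline, working_size=shape[0], pad_px=0)

    image = apply_transform(clean.image, truth, "linear")
    labels = apply_transform(clean.labels, truth, "nearest")

    if d.intensity_gamma != 1.0:
        lo, hi = image.min(), image.max()
        if hi > lo:
            image = lo + (hi - lo) * ((image - lo) / (hi - lo)) ** d.intensity_gamma
    if d.noise_sigma > 0:
        image = image + rng.normal(0.0, d.noise_sigma, size=image.shape)
        image = np.clip(image, 0, None)
    section = Section(
        image=image.astype(np.float32),
        labels=labels,
        pose=pose,
        pixel_size_um=clean.pixel_size_um,
        channel="counterstain",
    )
    return section, truth


def scatter_synthetic_cells(
    canvas_shape: tuple[int, int],
    region_mask: np.ndarray | None,
    n: int,
    radius_range_px: tuple[float, float] = (3.0, 6.0),
    intensity_range: tuple[float, float] = (0.5, 1.0),
    seed: int = 0,
    noise_sigma: float = 0.05,
    min_spacing_px: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Scatter n Gaussian "cell bodies" inside a mask, with ground-truth boxes.

    Each cell is an isotropic Gaussian of σ drawn from ``radius_range_px``
    and peak amplitude from ``intensity_range`` on a noisy background; its
    ground-truth box is centre ± 2σ.  Centres are rejection-sampled to keep a
    minimum spacing (default 2·max radius + 2 px).  Returns the float image
    and an (n, 5) array of (x_min, y_min, x_max, y_max, confidence=1.0).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    h, w = canvas_shape
    if region_mask is None:
        region_mask = np.ones((h, w), dtype=bool)
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != (h, w):
        raise ValueError("region_mask shape must match canvas_shape")
    if n > 0 and not region_mask.any():
        raise ValueError("cannot place cells in an empty region mask")
    rng = np.random.default_rng(seed)
    image = rng.normal(0.0, noise_sigma, size=(h, w))
    if n == 0:
        return image.astype(np.float32), np.empty((0, 5))

    if min_spacing_px is None:
        min_spacing_px = 2.0 * radius_range_px[1] + 2.0
    # Keep every ground-truth box fully on the canvas: a cell clipped by the
    # image border has no well-defined box.
    margin = int(np.ceil(2.0 * radius_range_px[1]))
    interior = np.zeros_like(region_mask)
    interior[margin:h - margin, margin:w - margin] = True
    candidates = np.argwhere(region_mask & interior)
    if len(candidates) == 0:
        raise ValueError("region mask has no interior room for cells")
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > 10000 * n:
            raise ValueError(
                "could not place all cells with the requested minimum spacing"
            )
        c = candidates[rng.integers(len(candidates))]
        if all(np.hypot(*(c - o)) >= min_spacing_px for o in centers):
            centers.append(c)

    yy, xx = np.mgrid[0:h, 0:w]
    boxes = np.zeros((n, 5))
    for i, (cy, cx) in enumerate(centers):
        sigma = rng.uniform(*radius_range_px)
        amp = rng.uniform(*intensity_range)
        image += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        boxes[i] = (cx - 2 * sigma, cy - 2 * sigma, cx + 2 * sigma, cy + 2 * sigma, 1.0)
    return image.astype(np.float32), boxes
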