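"""Two-stage composite registration of atlas slices onto tissue sections.

The atlas slice (moving image) is registered onto the experimental tissue
section (fixed image) by an affine transform T_affine(x) = A·x + b fitted
with the Mattes mutual-information metric, followed by a cubic B-spline
transform T_bspline(x) = Σ_i P_i·B_i(x) on a coarse control-point mesh fitted
with a neighbourhood-correlation metric on the affine-resampled moving image.
Both stages are optimized with gradient descent through SimpleITK's
registration framework using full (non-stochastic) metric sampling, so
results are deterministic.  The composite is applied to the atlas intensity
image (linear interpolation) and to its annotation labels (nearest
neighbour), warping the atlas region boundaries onto the tissue.

Coordinate/sign convention: all transforms here are *resampling* maps — they
take a point in the fixed-image frame to the corresponding point in the
moving-image frame, exactly as SimpleITK's ``Resample`` expects.  For a
moving image whose content is displaced by +d relative to the fixed image,
the fitted translation is therefore +d.  Point coordinates are (x, y) =
(column, row) with unit spacing.

Metric sign convention: both metric functions return values to be
*minimized* (negated MI / negated mean local correlation); lower is better.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .atlas import Section
from .preprocess import (
    PreprocessConfig,
    match_histogram,
    pad_pair,
    resize_working,
    to_gradient,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Transform containers
# ---------------------------------------------------------------------------

@dataclass
class AffineTransform:
    """Affine resampling map p_moving = A·(p_fixed − c) + c + b, in (x, y) order."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(2)
        self.center = np.asarray(self.center, dtype=np.float64).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine matrix must be non-singular")

    def to_sitk(self) -> sitk.AffineTransform:
        t = sitk.AffineTransform(2)
        t.SetMatrix(self.matrix.ravel().tolist())
        t.SetCenter(self.center.tolist())
        t.SetTranslation(self.translation.tolist())
        return t

    @classmethod
    def from_sitk(cls, t: sitk.AffineTransform) -> "AffineTransform":
        return cls(
            matrix=np.array(t.GetMatrix()).reshape(2, 2),
            translation=np.array(t.GetTranslation()),
            center=np.array(t.GetCenter()),
        )

    def to_dict(self) -> dict:
        return {
            "A": self.matrix.tolist(),
            "b": self.translation.tolist(),
            "center": self.center.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(matrix=np.array(d["A"]), translation=np.array(d["b"]),
                   center=np.array(d["center"]))


@dataclass
class BSplineTransform:
    """Cubic B-spline displacement field on a coarse control-point mesh.

    ``mesh_size`` counts mesh cells per axis (default 4×4); with cubic
    support the control grid is (mesh+3)² points.  ``fixed_parameters`` carry
    the grid geometry (size, origin, spacing, direction) in SimpleITK's
    layout; ``parameters`` are the control-point displacements (all x, then
    all y), in pixels.
    """

    mesh_size: tuple[int, int]
    fixed_parameters: tuple[float, ...]
    parameters: np.ndarray

    def __post_init__(self) -> None:
        self.mesh_size = tuple(int(v) for v in self.mesh_size)
        if min(self.mesh_size) < 2:
            raise ValueError("mesh_size must be at least 2×2")
        self.fixed_parameters = tuple(float(v) for v in self.fixed_parameters)
        self.parameters = np.asarray(self.parameters, dtype=np.float64).ravel()

    @property
    def control_points(self) -> np.ndarray:
        """Control-point displacement vectors, shape (n_points, 2) in (x, y)."""
        return self.parameters.reshape(2, -1).T

    def to_sitk(self) -> sitk.BSplineTransform:
        t = sitk.BSplineTransform(2, 3)
        t.SetFixedParameters(self.fixed_parameters)
        t.SetParameters(self.parameters.tolist())
        return t

    @classmethod
    def from_sitk(cls, t: sitk.BSplineTransform,
                  mesh_size: tuple[int, int]) -> "BSplineTransform":
        return cls(
            mesh_size=mesh_size,
            fixed_parameters=tuple(t.GetFixedParameters()),
            parameters=np.array(t.GetParameters()),
        )

    def to_dict(self) -> dict:
        return {
            "mesh": list(self.mesh_size),
            "fixed_parameters": list(self.fixed_parameters),
            "control_points": self.parameters.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BSplineTransform":
        return cls(mesh_size=tuple(d["mesh"]),
                   fixed_parameters=tuple(d["fixed_parameters"]),
                   parameters=np.array(d["control_points"]))


@dataclass
class CompositeTransform:
    """Affine stage chained with an optional B-spline stage.

    Application order follows the registration: the affine resample happens
    first, then the B-spline acts on the affine-resampled image.  As a single
    point map this is p → T_affine(T_bspline(p)).  The transform is defined
    in the padded working frame (``working_size`` + 2·``pad_px`` square).
    """

    affine: AffineTransform
    bspline: BSplineTransform | None = None
    working_size: int = 360
    pad_px: int = 50

    def to_sitk(self) -> sitk.Transform:
        if self.bspline is None:
            return self.affine.to_sitk()
        ct = sitk.CompositeTransform(2)
        ct.AddTransform(self.affine.to_sitk())
        ct.AddTransform(self.bspline.to_sitk())  # applied first to the point
        return ct

    def affine_only(self) -> "CompositeTransform":
        return CompositeTransform(self.affine, None, self.working_size, self.pad_px)

    def to_dict(self) -> dict:
        return {
            "affine": self.affine.to_dict(),
            "bspline": None if self.bspline is None else self.bspline.to_dict(),
            "working_size": self.working_size,
            "pad_px": self.pad_px,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompositeTransform":
        return cls(
            affine=AffineTransform.from_dict(d["affine"]),
            bspline=None if d["bspline"] is None else BSplineTransform.from_dict(d["bspline"]),
            working_size=int(d["working_size"]),
            pad_px=int(d["pad_px"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "CompositeTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class OptimizerConfig:
    """Gradient-descent and metric settings for both registration stages."""

    learning_rate: float = 0.01
    max_iterations: int = 300
    convergence_min_value: float = 1e-8
    convergence_window: int = 20
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0)
    mi_bins: int = 32
    bspline_mesh: tuple[int, int] = (4, 4)
    bspline_metric: str = "ncc"  # "ncc" (neighbourhood correlation) or "mi"
    ncc_radius: int = 3
    #: Per-iteration cap on the largest physical displacement (pixels) any
    #: image point may move; the learning rate is re-estimated each iteration
    #: against this cap, which keeps the descent stable both far from and at
    #: the optimum.
    max_step_px: float = 0.25

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.max_iterations <= 0:
            raise ValueError("learning_rate and max_iterations must be positive")
        if len(self.shrink_factors) != len(self.smoothing_sigmas):
            raise ValueError("shrink and smoothing schedules must have equal length")
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")
        if self.bspline_metric not in ("ncc", "mi"):
            raise ValueError("bspline_metric must be 'ncc' or 'mi'")


# ---------------------------------------------------------------------------
# Similarity metrics (standalone, numpy implementations)
# ---------------------------------------------------------------------------

def mattes_mi(
    fixed: np.ndarray,
    moving: np.ndarray,
    bins: int = 32,
    fixed_mask: np.ndarray | None = None,
) -> float:
    """Negated mutual information from a joint intensity histogram (nats).

    Intensities of each image are linearly binned over their own range into
    ``bins`` bins; MI is computed from the joint distribution and negated so
    that lower values mean better agreement.  A constant image on either side
    carries no information and yields 0.  Masked-out pixels contribute
    nothing.
    """
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must have equal shapes")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if fixed_mask is not None:
        fixed_mask = np.asarray(fixed_mask, dtype=bool)
        if fixed_mask.shape != fixed.shape:
            raise ValueError("mask shape must match image shape")
        f, m = fixed[fixed_mask], moving[fixed_mask]
    else:
        f, m = fixed.ravel(), moving.ravel()
    if f.size == 0 or f.max() == f.min() or m.max() == m.min():
        return 0.0
    joint, _, _ = np.histogram2d(f, m, bins=bins,
                                 range=[[f.min(), f.max()], [m.min(), m.max()]])
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))
    return -mi


def neighborhood_correlation(
    fixed: np.ndarray, moving: np.ndarray, radius: int = 3
) -> float:
    """Negated mean local normalized cross-correlation over (2r+1)² windows.

    Windows are the full interior windows (centres at least ``radius`` from
    every border); windows with zero variance in either image are excluded.
    Returns −1 for a perfect local match.
    """
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must have equal shapes")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    w = 2 * radius + 1
    if min(fixed.shape) < w:
        raise ValueError(f"image smaller than the {w}×{w} correlation window")
    size = w * w

    def _win_sums(a: np.ndarray) -> np.ndarray:
        return ndimage.uniform_filter(a, size=w, mode="constant")[radius:-radius, radius:-radius]

    mf = _win_sums(fixed)
    mm = _win_sums(moving)
    cov = _win_sums(fixed * moving) - mf * mm
    vf = _win_sums(fixed * fixed) - mf * mf
    vm = _win_sums(moving * moving) - mm * mm
    # uniform_filter is mean-based already; sums above are window means.
    scale = np.sqrt(np.clip(vf, 0, None) * np.clip(vm, 0, None))
    valid = (vf > 1e-12) & (vm > 1e-12)
    if not valid.any():
        return 0.0
    corr = cov[valid] / scale[valid]
    return -float(np.mean(corr))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _to_sitk_image(a: np.ndarray) -> sitk.Image:
    return sitk.GetImageFromArray(np.ascontiguousarray(a, dtype=np.float32))


def _mask_image(mask: np.ndarray) -> sitk.Image:
    return sitk.GetImageFromArray(np.ascontiguousarray(mask, dtype=np.uint8))


def init_centered_affine(fixed: np.ndarray, moving: np.ndarray) -> AffineTransform:
    """Identity-matrix affine translating the moving intensity centroid onto the fixed one.

    For an all-zero (empty) image the geometric centre is used instead and a
    warning is logged.  The rotation centre is the fixed-image centre.
    """

    def _centroid(img: np.ndarray) -> np.ndarray:
        img = np.asarray(img, dtype=np.float64)
        total = img.sum()
        if total <= 0:
            logger.warning("empty image in init_centered_affine; using geometric centre")
            return np.array([(img.shape[1] - 1) / 2.0, (img.shape[0] - 1) / 2.0])
        rr, cc = np.indices(img.shape)
        cy = float((rr * img).sum() / total)
        cx = float((cc * img).sum() / total)
        return np.array([cx, cy])

    c_fix = _centroid(fixed)
    c_mov = _centroid(moving)
    fixed = np.asarray(fixed)
    centre = np.array([(fixed.shape[1] - 1) / 2.0, (fixed.shape[0] - 1) / 2.0])
    return AffineTransform(matrix=np.eye(2), translation=c_mov - c_fix, center=centre)


def _run_registration(
    reg: sitk.ImageRegistrationMethod,
    fixed: np.ndarray,
    moving: np.ndarray,
    log: list | None,
    stage: str,
) -> None:
    if log is not None:
        def _record():
            log.append((reg.GetCurrentLevel(), reg.GetOptimizerIteration(),
                        reg.GetMetricValue()))
        reg.AddCommand(sitk.sitkIterationEvent, _record)
    try:
        reg.Execute(_to_sitk_image(fixed), _to_sitk_image(moving))
    except RuntimeError as exc:
        where = f" (last: level {log[-1][0]}, iteration {log[-1][1]})" if log else ""
        raise RuntimeError(f"{stage} registration failed{where}: {exc}") from exc
    final = reg.GetMetricValue()
    if not np.isfinite(final):
        raise RuntimeError(
            f"{stage} registration produced a non-finite metric at level "
            f"{reg.GetCurrentLevel()}, iteration {reg.GetOptimizerIteration()}"
        )


def _configure_optimizer(reg: sitk.ImageRegistrationMethod, cfg: OptimizerConfig,
                         shrink: tuple[int, ...], sigmas: tuple[float, ...]) -> None:
    reg.SetOptimizerAsGradientDescent(
        learningRate=cfg.learning_rate,
        numberOfIterations=cfg.max_iterations,
        convergenceMinimumValue=cfg.convergence_min_value,
        convergenceWindowSize=cfg.convergence_window,
        estimateLearningRate=reg.EachIteration,
        maximumStepSizeInPhysicalUnits=cfg.max_step_px,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(shrink))
    reg.SetSmoothingSigmasPerLevel(list(sigmas))
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetMetricSamplingStrategy(reg.NONE)  # full sampling: deterministic


def fit_affine(
    fixed: np.ndarray,
    moving: np.ndarray,
    cfg: OptimizerConfig | None = None,
    fixed_mask: np.ndarray | None = None,
    init: AffineTransform | None = None,
    log: list | None = None,
) -> AffineTransform:
    """Fit the affine stage by minimizing Mattes MI over a multiresolution pyramid."""
    cfg = cfg or OptimizerConfig()
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(cfg.mi_bins)
    _configure_optimizer(reg, cfg, cfg.shrink_factors, cfg.smoothing_sigmas)
    if fixed_mask is not None:
        reg.SetMetricFixedMask(_mask_image(fixed_mask))
    tx = (init or init_centered_affine(fixed, moving)).to_sitk()
    reg.SetInitialTransform(tx, inPlace=True)
    _run_registration(reg, fixed, moving, log, "affine")
    return AffineTransform.from_sitk(tx)


def fit_bspline(
    fixed: np.ndarray,
    moving: np.ndarray,
    cfg: OptimizerConfig | None = None,
    fixed_mask: np.ndarray | None = None,
    log: list | None = None,
) -> BSplineTransform:
    """Fit the B-spline refinement on the affine-resampled moving image.

    Runs at full resolution (single level) with the neighbourhood-correlation
    metric by default (``cfg.bspline_metric`` switches to MI).
    """
    cfg = cfg or OptimizerConfig()
    reg = sitk.ImageRegistrationMethod()
    if cfg.bspline_metric == "ncc":
        reg.SetMetricAsANTSNeighborhoodCorrelation(cfg.ncc_radius)
    else:
        reg.SetMetricAsMattesMutualInformation(cfg.mi_bins)
    _configure_optimizer(reg, cfg, (1,), (0.0,))
    if fixed_mask is not None:
        reg.SetMetricFixedMask(_mask_image(fixed_mask))
    tx = sitk.BSplineTransformInitializer(
        _to_sitk_image(fixed), transformDomainMeshSize=list(cfg.bspline_mesh)
    )
    reg.SetInitialTransform(tx, inPlace=True)
    _run_registration(reg, fixed, moving, log, "B-spline")
    return BSplineTransform.from_sitk(tx, cfg.bspline_mesh)


def apply_transform(
    image: np.ndarray,
    transform: CompositeTransform | AffineTransform | BSplineTransform,
    interpolation: str = "linear",
    output_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Resample an image through a transform; out-of-domain pixels become 0.

    ``interpolation`` is "linear" or "nearest"; nearest is mandatory for
    label images so no label ids are invented.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError("interpolation must be 'linear' or 'nearest'")
    image = np.asarray(image)
    is_int = np.issubdtype(image.dtype, np.integer)
    shape = output_shape or image.shape
    t = transform.to_sitk()
    interp = sitk.sitkLinear if interpolation == "linear" else sitk.sitkNearestNeighbor
    if is_int:
        img = sitk.GetImageFromArray(np.ascontiguousarray(image, dtype=np.int32))
    else:
        img = _to_sitk_image(image)
    ref = sitk.Image(int(shape[1]), int(shape[0]), img.GetPixelID())
    out = sitk.GetArrayFromImage(sitk.Resample(img, ref, t, interp, 0.0))
    return out.astype(image.dtype) if is_int else out


@dataclass
class RegistrationResult:
    """Everything register_composite produces for one section."""

    transform: CompositeTransform
    warped_atlas: np.ndarray
    warped_labels: np.ndarray | None
    warped_labels_affine: np.ndarray | None
    affine_log: list
    bspline_log: list


def register_composite(
    fixed_section: Section,
    atlas_section: Section,
    mask: np.ndarray | None = None,
    pre_cfg: PreprocessConfig | None = None,
    opt_cfg: OptimizerConfig | None = None,
) -> RegistrationResult:
    """Register an atlas slice onto a tissue section and warp its annotations.

    Runs the full conditioning chain (working-size resize → Sobel gradient →
    pad → histogram match), fits the affine then the B-spline stage, composes
    them, applies the composite to the atlas intensity (linear) and labels
    (nearest), crops the padding, and resizes outputs back to the fixed
    section's native resolution.  ``mask`` flags damaged fixed-image pixels:
    they are excluded from both metrics and the corresponding warped-atlas
    intensity pixels are zeroed in the output.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    opt_cfg = opt_cfg or OptimizerConfig()
    ws, pad = pre_cfg.working_size, pre_cfg.pad_px

    include = None
    mask_native = None
    fixed_image = fixed_section.image
    if mask is not None:
        mask_native = np.asarray(mask, dtype=bool)
        if mask_native.shape != fixed_section.image.shape:
            raise ValueError("mask shape must match the fixed section image")
        # Remove the damaged content entirely: it must influence neither the
        # gradients nor the histogram-matching reference.
        fixed_image = fixed_image.copy()
        fixed_image[mask_native] = 0

    fx_g = to_gradient(resize_working(fixed_image, ws))
    mv_g = to_gradient(resize_working(atlas_section.image, ws))
    fx_p, mv_p = pad_pair(fx_g, mv_g, pad)

    if mask_native is not None:
        damage_w = resize_working(mask_native.astype(np.uint8), ws, is_label=True) > 0
        # Widen by the Sobel support so boundary gradients of the zeroed
        # region are excluded from the metric as well.
        damage_w = ndimage.binary_dilation(damage_w, iterations=2)
        include = np.pad(~damage_w, pad, mode="constant", constant_values=True)
    mv_p = match_histogram(mv_p, fx_p, pre_cfg)

    affine_log: list = []
    bspline_log: list = []
    affine = fit_affine(fx_p, mv_p, opt_cfg, fixed_mask=include, log=affine_log)
    mv_aff = apply_transform(mv_p, affine, "linear")
    bspline = fit_bspline(fx_p, mv_aff, opt_cfg, fixed_mask=include, log=bspline_log)
    composite = CompositeTransform(affine, bspline, ws, pad)

    from skimage.transform import resize as _resize

    def _warp_native(arr: np.ndarray, is_label: bool, t) -> np.ndarray:
        a = resize_working(np.asarray(arr), ws, is_label=is_label)
        a = np.pad(a, pad, mode="constant", constant_values=0)
        warped = apply_transform(a, t, "nearest" if is_label else "linear")
        warped = warped[pad:-pad, pad:-pad] if pad else warped
        h, w = fixed_section.image.shape
        if warped.shape == (h, w):
            return warped
        if is_label:
            return _resize(warped, (h, w), order=0, anti_aliasing=False,
                           preserve_range=True).astype(warped.dtype)
        return _resize(warped.astype(np.float32), (h, w), order=1,
                       anti_aliasing=False, preserve_range=True).astype(np.float32)

    warped_atlas = _warp_native(atlas_section.image, False, composite)
    if mask_native is not None:
        warped_atlas = warped_atlas.copy()
        warped_atlas[mask_native] = 0.0
    warped_labels = None
    warped_labels_affine = None
    if atlas_section.labels is not None:
        warped_labels = _warp_native(atlas_section.labels, True, composite)
        warped_labels_affine = _warp_native(
            atlas_section.labels, True, composite.affine_only()
        )
    return RegistrationResult(
        transform=composite,
        warped_atlas=warped_atlas,
        warped_labels=warped_labels,
        warped_labels_affine=warped_labels_affine,
        affine_log=affine_log,
        bspline_log=bspline_log,
    )
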