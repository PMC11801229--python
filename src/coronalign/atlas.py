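"""Reference-atlas volumes, slice poses and oblique coronal slicing.

The reference atlas is a 3D intensity volume (e.g. the Allen CCF 10 µm Nissl
average) paired with an integer annotation volume of the same shape.  A tissue
section corresponds to an oblique plane through that volume, described by a
:class:`SlicePose`: two small cut angles (the deviation of the knife plane from
a perfect coronal plane, introduced during sectioning) and an anterior–
posterior (AP) position expressed as a fractional voxel index.

Axis convention: volume axis 0 runs anterior→posterior (AP), axis 1
dorsal→ventral (DV), axis 2 left→right (LR).  A section image has DV as rows
and LR as columns.

Rotation convention (fixed here; the planes are conventionally called x–z and
y–z): a positive ``x_angle_deg`` tilts the slicing-plane normal from +AP
toward +LR; a positive ``y_angle_deg`` tilts it toward +DV; the x rotation is
applied first.  The rotation pivot is the section's centre point on the AP
axis.  Samples falling outside the volume are filled with 0 (background).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize

logger = logging.getLogger(__name__)

#: AP index bounds of the 10 µm full-resolution coronal atlas (0 .. 1324).
DEFAULT_AP_MAX = 1324

ANGLE_MIN_DEG = -10.0
ANGLE_MAX_DEG = 10.0


@dataclass
class AtlasVolume:
    """Paired 3D intensity and integer-label arrays with voxel-size metadata."""

    intensity: np.ndarray
    labels: np.ndarray
    voxel_size_um: float = 10.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        self.labels = np.asarray(self.labels)
        if self.intensity.ndim != 3 or self.labels.ndim != 3:
            raise ValueError("intensity and labels must be 3D arrays")
        if self.intensity.shape != self.labels.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} != labels shape {self.labels.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    @property
    def ap_max(self) -> int:
        """Largest valid AP index (number of coronal planes minus one)."""
        return self.shape[0] - 1


@dataclass
class SlicePose:
    """Cut angles (degrees, in [-10, 10]) and AP position of one section."""

    x_angle_deg: float = 0.0
    y_angle_deg: float = 0.0
    ap_index: float = 0.0

    def normalized(self, ap_max: int = DEFAULT_AP_MAX) -> tuple[float, float, float]:
        return normalize_pose(self, ap_max)


@dataclass
class Section:
    """A single 2D section: intensity image, optional labels, pose, channel tag."""

    image: np.ndarray
    labels: np.ndarray | None = None
    pose: SlicePose = field(default_factory=SlicePose)
    pixel_size_um: float = 10.0
    channel: str = "counterstain"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValueError("section image must be 2D")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.image.shape:
                raise ValueError("labels shape must match image shape")


def _check_angle(value: float, name: str) -> None:
    if not (ANGLE_MIN_DEG <= value <= ANGLE_MAX_DEG):
        raise ValueError(
            f"{name}={value} outside the supported cut-angle range "
            f"[{ANGLE_MIN_DEG}, {ANGLE_MAX_DEG}] degrees"
        )


def normalize_pose(pose: SlicePose, ap_max: int = DEFAULT_AP_MAX) -> tuple[float, float, float]:
    """Map a physical pose onto the unit cube used by pose predictors.

    Angles map affinely from [-10, 10] deg to [0, 1]; the AP index maps from
    [0, ap_max] to [0, 1].
    """
    _check_angle(pose.x_angle_deg, "x_angle_deg")
    _check_angle(pose.y_angle_deg, "y_angle_deg")
    if not (0 <= pose.ap_index <= ap_max):
        raise ValueError(f"ap_index={pose.ap_index} outside [0, {ap_max}]")
    span = ANGLE_MAX_DEG - ANGLE_MIN_DEG
    return (
        (pose.x_angle_deg - ANGLE_MIN_DEG) / span,
        (pose.y_angle_deg - ANGLE_MIN_DEG) / span,
        pose.ap_index / ap_max,
    )


def denormalize_pose(
    triple: tuple[float, float, float], ap_max: int = DEFAULT_AP_MAX
) -> SlicePose:
    """Inverse of :func:`normalize_pose`."""
    nx, ny, nz = triple
    for name, v in (("x", nx), ("y", ny), ("z", nz)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"normalized component {name}={v} outside [0, 1]")
    span = ANGLE_MAX_DEG - ANGLE_MIN_DEG
    return SlicePose(
        x_angle_deg=nx * span + ANGLE_MIN_DEG,
        y_angle_deg=ny * span + ANGLE_MIN_DEG,
        ap_index=nz * ap_max,
    )


def slicing_basis(pose: SlicePose) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotated (normal, row, col) unit vectors of the slicing plane.

    Row direction starts as +DV, column direction as +LR, normal as +AP; the
    x-angle rotation (AP–LR plane) is applied first, then the y-angle rotation
    (AP–DV plane).
    """
    ax = np.deg2rad(pose.x_angle_deg)
    ay = np.deg2rad(pose.y_angle_deg)
    # Rotation in the (AP, LR) plane, i.e. around the DV axis.
    rx = np.array(
        [
            [np.cos(ax), 0.0, np.sin(ax)],
            [0.0, 1.0, 0.0],
            [-np.sin(ax), 0.0, np.cos(ax)],
        ]
    )
    # Rotation in the (AP, DV) plane, i.e. around the LR axis.
    ry = np.array(
        [
            [np.cos(ay), np.sin(ay), 0.0],
            [-np.sin(ay), np.cos(ay), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    rot = ry @ rx
    normal = rot @ np.array([1.0, 0.0, 0.0])
    e_row = rot @ np.array([0.0, 1.0, 0.0])
    e_col = rot @ np.array([0.0, 0.0, 1.0])
    return normal, e_row, e_col


def _plane_coordinates(volume_shape: tuple[int, int, int], pose: SlicePose) -> np.ndarray:
    """(3, H, W) volume-index coordinates of every pixel of the oblique section."""
    _, n_rows, n_cols = volume_shape
    _, e_row, e_col = slicing_basis(pose)
    centre = np.array(
        [pose.ap_index, (n_rows - 1) / 2.0, (n_cols - 1) / 2.0]
    )
    rr = np.arange(n_rows) - (n_rows - 1) / 2.0
    cc = np.arange(n_cols) - (n_cols - 1) / 2.0
    coords = (
        centre[:, None, None]
        + e_row[:, None, None] * rr[None, :, None]
        + e_col[:, None, None] * cc[None, None, :]
    )
    return coords


def slice_volume(volume: AtlasVolume, pose: SlicePose) -> Section:
    """Extract the oblique coronal section located by ``pose``.

    Intensity is sampled with linear interpolation, labels with nearest
    neighbour; out-of-volume samples are 0.  The section pixel grid spacing
    equals the voxel size, so the section shape is (DV extent, LR extent).
    """
    _check_angle(pose.x_angle_deg, "x_angle_deg")
    _check_angle(pose.y_angle_deg, "y_angle_deg")
    if not (0 <= pose.ap_index <= volume.ap_max):
        raise ValueError(
            f"ap_index={pose.ap_index} outside the volume AP range [0, {volume.ap_max}]"
        )
    coords = _plane_coordinates(volume.shape, pose)
    image = ndimage.map_coordinates(
        volume.intensity.astype(np.float32), coords, order=1, mode="constant", cval=0.0
    )
    labels = ndimage.map_coordinates(
        volume.labels, coords, order=0, mode="constant", cval=0
    )
    return Section(
        image=image,
        labels=labels,
        pose=replace(pose),
        pixel_size_um=volume.voxel_size_um,
        channel="counterstain",
    )


def average_pose_angles(poses: list[SlicePose]) -> tuple[float, float]:
    """Arithmetic mean of the x and y cut angles over an experiment's sections.

    Serial sections from one brain share the physical cut plane, so the
    per-section angle estimates are averaged and re-applied to every section
    (the caller keeps each section's own AP index).
    """
    if not poses:
        raise ValueError("average_pose_angles requires a non-empty pose list")
    return (
        float(np.mean([p.x_angle_deg for p in poses])),
        float(np.mean([p.y_angle_deg for p in poses])),
    )


def apply_average_angles(poses: list[SlicePose]) -> list[SlicePose]:
    """Return poses with angles replaced by the experiment-wide averages."""
    mx, my = average_pose_angles(poses)
    return [replace(p, x_angle_deg=mx, y_angle_deg=my) for p in poses]


def generate_training_samples(
    volume: AtlasVolume,
    n: int,
    seed: int,
    image_size: int = 256,
) -> list[tuple[np.ndarray, tuple[float, float, float]]]:
    """Pose-labelled training samples produced by random oblique slicing.

    Angles are drawn uniformly in [-10, 10]² degrees and the AP index
    uniformly in [0, ap_max].  With probability 0.5 the section is cropped to
    a single hemisphere (left or right half of the LR axis, equiprobable)
    before resizing, emulating single-hemisphere mounts; the stored pose is
    that of the full (pre-crop) section.  Images are resized to
    ``image_size``² float32 and paired with the normalized pose triple.
    Deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[tuple[np.ndarray, tuple[float, float, float]]] = []
    ap_max = volume.ap_max
    for _ in range(n):
        pose = SlicePose(
            x_angle_deg=float(rng.uniform(ANGLE_MIN_DEG, ANGLE_MAX_DEG)),
            y_angle_deg=float(rng.uniform(ANGLE_MIN_DEG, ANGLE_MAX_DEG)),
            ap_index=float(rng.uniform(0, ap_max)),
        )
        section = slice_volume(volume, pose)
        image = section.image
        if rng.random() < 0.5:
            half = image.shape[1] // 2
            if rng.random() < 0.5:
                image = image[:, :half]
            else:
                image = image[:, half:]
        image = resize(
            image.astype(np.float32),
            (image_size, image_size),
            order=1,
            anti_aliasing=True,
            preserve_range=True,
        ).astype(np.float32)
        out.append((image, normalize_pose(pose, ap_max)))
    return out


class ConstantPosePredictor:
    """Pose predictor returning one fixed normalized triple (testing stub)."""

    def __init__(self, triple: tuple[float, float, float] = (0.5, 0.5, 0.5)):
        self.triple = tuple(float(v) for v in triple)

    def __call__(self, image: np.ndarray) -> tuple[float, float, float]:
        return self.triple


class TemplateMatchPosePredictor:
    """Weights-free pose predictor: nearest-template correlation.

    Precomputes evenly spaced zero-angle coronal slices of the atlas, resized
    to the predictor input size, and predicts the AP position of the template
    with the highest Pearson correlation against the query image (angles are
    predicted as 0°, i.e. normalized 0.5 — the average-angle step and user
    fine-tuning refine them).  This stands in for a learned pose-regression
    network: the pipeline only requires *some* initial estimate that the user
    then fine-tunes.
    """

    def __init__(self, volume: AtlasVolume, n_templates: int = 32, image_size: int = 256):
        if n_templates < 2:
            raise ValueError("n_templates must be >= 2")
        self.ap_max = volume.ap_max
        self.image_size = image_size
        self.ap_positions = np.linspace(0, self.ap_max, n_templates)
        self.templates = np.stack(
            [
                self._standardize(
                    resize(
                        slice_volume(volume, SlicePose(ap_index=float(ap))).image,
                        (image_size, image_size),
                        order=1,
                        anti_aliasing=True,
                        preserve_range=True,
                    )
                )
                for ap in self.ap_positions
            ]
        )

    @staticmethod
    def _standardize(image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=np.float64).ravel()
        x = x - x.mean()
        norm = np.linalg.norm(x)
        return x / norm if norm > 0 else x

    def __call__(self, image: np.ndarray) -> tuple[float, float, float]:
        if image.shape != (self.image_size, self.image_size):
            image = resize(
                np.asarray(image, dtype=np.float64),
                (self.image_size, self.image_size),
                order=1,
                anti_aliasing=True,
                preserve_range=True,
            )
        q = self._standardize(image)
        scores = self.templates @ q
        best = int(np.argmax(scores))
        return (0.5, 0.5, float(self.ap_positions[best] / self.ap_max))
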