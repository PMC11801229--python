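"""Alignment-quality metrics: Dice, directed Hausdorff, centroid distance.

These are the benchmark metrics for judging how well warped atlas
annotations fit the experimental tissue: the Dice similarity coefficient
2|A∩B|/(|A|+|B|) over foreground masks, the directed Hausdorff distance
between boundary-pixel contours (max over one contour of the distance to
the nearest point of the other), and the Euclidean distance between
foreground centroids.  Count agreement between two counting methods is
summarized by Pearson's product-moment correlation.

Foreground conventions: for an experimental image, tissue = intensity above
the Otsu threshold; for a warped annotation, tissue = label > 0.  Contours
are boundary-pixel sets: a foreground pixel 4-adjacent to background or on
the image border.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import directed_hausdorff as _scipy_dh
from scipy.stats import pearsonr
from skimage.filters import threshold_otsu


def tissue_mask(image: np.ndarray) -> np.ndarray:
    """Foreground (tissue) mask by Otsu thresholding; empty for constant images."""
    image = np.asarray(image)
    if image.max() == image.min():
        return np.zeros(image.shape, dtype=bool)
    return image > threshold_otsu(image)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient of two binary masks; two empty masks → 1.0."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def contour_points(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of a mask: foreground 4-adjacent to background or at the border.

    Returns an (n, 2) array of (row, col) coordinates; empty for an empty mask.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.empty((0, 2), dtype=int)
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = mask & ~interior
    return np.argwhere(boundary)


def directed_hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Directed Hausdorff distance from point set a to point set b (pixels)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("directed_hausdorff requires non-empty point sets")
    return float(_scipy_dh(a, b)[0])


def mask_directed_hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Directed Hausdorff between the contours of two masks."""
    return directed_hausdorff(contour_points(a), contour_points(b))


def centroid(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("centroid of an empty mask is undefined")
    return np.argwhere(mask).mean(axis=0)


def centroid_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between the foreground centroids of two masks (pixels)."""
    return float(np.linalg.norm(centroid(a) - centroid(b)))


def count_correlation(counts_a, counts_b) -> tuple[float, float]:
    """Pearson r and two-sided p-value between two count vectors (n ≥ 3)."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("count vectors must be 1D and equal length")
    if len(a) < 3:
        raise ValueError("correlation requires at least 3 pairs")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = pearsonr(a, b)
    return float(r), float(p)


def section_metrics(pred_labels: np.ndarray, truth_labels: np.ndarray) -> dict:
    """Dice / directed Hausdorff / centroid distance between two label images,
    computed on the whole-tissue (label > 0) foreground."""
    pm = np.asarray(pred_labels) > 0
    tm = np.asarray(truth_labels) > 0
    return {
        "dice": dice(pm, tm),
        "hausdorff": mask_directed_hausdorff(pm, tm),
        "centroid_distance": centroid_distance(pm, tm),
    }
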