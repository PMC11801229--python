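"""Tiled (slicing-aided) cell detection with overlap suppression.

High-resolution microscopy images are tiled into small overlapping tiles
(640×640, 50 % overlap by default) so cell bodies are seen at a useful
scale; a pluggable detector runs on each tile, detections are remapped to
global coordinates, confidence-filtered, and duplicates from overlapping
tiles are removed by greedy non-maximum suppression (NMS).

The detector plug-in contract is a callable ``tile -> list[Detection]`` in
tile-local coordinates, so a trained object-detection model can be dropped
in without code changes.  The shipped default is a classical
difference-of-Gaussians (DoG) blob detector whose normalized blob response
serves as the detection confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

logger = logging.getLogger(__name__)


@dataclass
class Detection:
    """One detected cell body: global-coordinate box plus confidence."""

    box: tuple[float, float, float, float]  # (x_min, y_min, x_max, y_max)
    confidence: float
    class_id: int = 0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate box {self.box}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must be in [0, 1]")

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.box
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


@dataclass
class TilingConfig:
    tile_size: int = 640
    overlap_fraction: float = 0.5
    nms_iou: float = 0.5
    confidence_threshold: float = 0.25

    def __post_init__(self) -> None:
        if self.tile_size < 64:
            raise ValueError("tile_size must be >= 64")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")


def _axis_offsets(extent: int, tile: int, stride: int) -> list[int]:
    if extent <= tile:
        return [0]
    offsets = list(range(0, extent - tile + 1, stride))
    if offsets[-1] + tile < extent:
        offsets.append(extent - tile)
    return offsets


def tile_image(
    image: np.ndarray, cfg: TilingConfig | None = None
) -> list[tuple[np.ndarray, tuple[int, int]]]:
    """Split an image into overlapping tiles covering every pixel.

    Stride is ``tile_size·(1−overlap_fraction)``; the last tile along each
    axis is anchored to end exactly at the image border.  Images smaller than
    one tile yield a single zero-padded full-size tile at offset (0, 0).
    Offsets are (x, y) in global pixel coordinates.
    """
    cfg = cfg or TilingConfig()
    image = np.asarray(image)
    h, w = image.shape[:2]
    t = cfg.tile_size
    stride = max(1, int(round(t * (1.0 - cfg.overlap_fraction))))
    tiles = []
    for oy in _axis_offsets(h, t, stride):
        for ox in _axis_offsets(w, t, stride):
            tile = image[oy:oy + t, ox:ox + t]
            if tile.shape[:2] != (t, t):
                padded = np.zeros((t, t) + tile.shape[2:], dtype=image.dtype)
                padded[: tile.shape[0], : tile.shape[1]] = tile
                tile = padded
            tiles.append((tile, (ox, oy)))
    return tiles


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two (x_min, y_min, x_max, y_max) boxes."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    ix = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    iy = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = ix * iy
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union if union > 0 else 0.0


def nms(detections: list[Detection], iou_threshold: float = 0.5) -> list[Detection]:
    """Greedy non-maximum suppression.

    Detections are visited in descending confidence (ties broken by earlier
    original index); each kept detection suppresses every remaining one whose
    IoU with it exceeds the threshold.  Output is in descending confidence.
    """
    order = sorted(range(len(detections)), key=lambda i: (-detections[i].confidence, i))
    kept: list[Detection] = []
    suppressed = np.zeros(len(detections), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        kept.append(detections[i])
        for j in order:
            if j != i and not suppressed[j]:
                if iou(detections[i].box, detections[j].box) > iou_threshold:
                    suppressed[j] = True
        suppressed[i] = True
    return kept


def tiled_detect(
    image: np.ndarray,
    detector,
    cfg: TilingConfig | None = None,
) -> list[Detection]:
    """Run a detector over overlapping tiles and merge the results.

    Per-tile detections are shifted by the tile offset, clipped to the image
    bounds, filtered by ``cfg.confidence_threshold``, and de-duplicated by
    global NMS.  A detector exception skips that tile (logged); the summary
    count of failed tiles is logged at warning level.
    """
    cfg = cfg or TilingConfig()
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h == 0 or w == 0:
        return []
    merged: list[Detection] = []
    failed = 0
    for tile, (ox, oy) in tile_image(image, cfg):
        try:
            local = detector(tile)
        except Exception:
            failed += 1
            logger.exception("detector failed on tile at offset (%d, %d)", ox, oy)
            continue
        for det in local:
            x0, y0, x1, y1 = det.box
            # A box touching an interior tile edge is a clipped partial view;
            # the overlapping neighbour tile sees the object fully.
            tol = 1.0
            t = cfg.tile_size
            if (x0 < tol and ox > 0) or (x1 > t - tol and ox + t < w):
                continue
            if (y0 < tol and oy > 0) or (y1 > t - tol and oy + t < h):
                continue
            x0 = min(max(x0 + ox, 0.0), w)
            x1 = min(max(x1 + ox, 0.0), w)
            y0 = min(max(y0 + oy, 0.0), h)
            y1 = min(max(y1 + oy, 0.0), h)
            if x1 - x0 <= 0 or y1 - y0 <= 0:
                continue
            if det.confidence < cfg.confidence_threshold:
                continue
            merged.append(Detection((x0, y0, x1, y1), det.confidence, det.class_id))
    if failed:
        logger.warning("detector failed on %d tile(s)", failed)
    return nms(merged, cfg.nms_iou)


@dataclass
class BlobDetectorParams:
    """Difference-of-Gaussians detector settings.

    ``min_sigma``/``max_sigma`` bound the cell-body scale (σ in pixels; the
    reported box half-width is 2σ at the detected scale); ``threshold`` is
    the absolute scale-normalized DoG response a peak must exceed;
    ``response_scale`` maps responses onto [0, 1] confidences
    (confidence = min(1, response/response_scale)).
    """

    min_sigma: float = 2.0
    max_sigma: float = 8.0
    num_scales: int = 6
    threshold: float = 0.08
    response_scale: float = 0.2
    min_distance_px: int = 3


class DoGBlobDetector:
    """Classical multiscale DoG blob detector (tile → detections).

    A weights-free default detector for bright, roughly Gaussian cell bodies
    on a darker background; the tiling/NMS aggregation accepts any
    detector with the same call signature in its place.
    """

    def __init__(self, params: BlobDetectorParams | None = None):
        self.params = params or BlobDetectorParams()

    def __call__(self, tile: np.ndarray) -> list[Detection]:
        p = self.params
        img = np.asarray(tile, dtype=np.float64)
        if img.ndim != 2:
            raise ValueError("blob detector expects a grayscale tile")
        sigmas = np.geomspace(p.min_sigma, p.max_sigma, p.num_scales)
        smoothed = [ndimage.gaussian_filter(img, s) for s in sigmas]
        # Scale-normalized DoG approximates the Laplacian-of-Gaussian response.
        stack = np.stack(
            [
                (smoothed[i] - smoothed[i + 1]) / (sigmas[i + 1] / sigmas[i] - 1.0)
                for i in range(len(sigmas) - 1)
            ]
        )
        peaks = peak_local_max(
            stack,
            threshold_abs=p.threshold,
            min_distance=p.min_distance_px,
            exclude_border=False,
        )
        blobs = []
        for k, cy, cx in peaks:
            sigma = float(np.sqrt(sigmas[k] * sigmas[k + 1]))
            response = float(stack[k, cy, cx])
            blobs.append((response, float(cx), float(cy), sigma))
        # Cross-scale pruning: a blob is dropped when a stronger blob's centre
        # lies within half the sum of their radii (concentric multi-scale
        # responses to one cell have low box IoU, so plain NMS misses them).
        blobs.sort(key=lambda b: -b[0])
        kept: list[tuple[float, float, float, float]] = []
        for resp, cx, cy, sigma in blobs:
            if any(
                np.hypot(cx - kx, cy - ky) < (sigma + ks)
                for _, kx, ky, ks in kept
            ):
                continue
            kept.append((resp, cx, cy, sigma))
        detections = []
        for resp, cx, cy, sigma in kept:
            conf = min(1.0, resp / p.response_scale)
            r = 2.0 * sigma
            detections.append(Detection((cx - r, cy - r, cx + r, cy + r), conf))
        return detections


def default_blob_detector(
    tile: np.ndarray, params: BlobDetectorParams | None = None
) -> list[Detection]:
    """Functional wrapper over :class:`DoGBlobDetector`."""
    return DoGBlobDetector(params)(tile)


def match_detections(
    detections: list[Detection],
    truth_boxes: np.ndarray,
    iou_threshold: float = 0.3,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detections against ground-truth boxes.

    Returns (true positives, false positives, false negatives) at the given
    IoU threshold; each truth box may be claimed by at most one detection,
    in descending confidence order.
    """
    truth_boxes = np.asarray(truth_boxes)
    used = np.zeros(len(truth_boxes), dtype=bool)
    tp = 0
    for det in sorted(detections, key=lambda d: -d.confidence):
        best, best_iou = -1, iou_threshold
        for t in range(len(truth_boxes)):
            if used[t]:
                continue
            v = iou(det.box, truth_boxes[t, :4])
            if v >= best_iou:
                best, best_iou = t, v
        if best >= 0:
            used[best] = True
            tp += 1
    fp = len(detections) - tp
    fn = len(truth_boxes) - tp
    return tp, fp, fn
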