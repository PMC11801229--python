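"""Image conditioning applied before and during registration.

Sections and atlas slices are brought into a common "working frame" before
any metric is evaluated: both are resized to a square working size (360×360
by default), converted to Sobel gradient-magnitude images so that the atlas
template and arbitrarily stained tissue are compared on shared edge features,
min–max normalized, zero-padded by a uniform 50 px margin to mitigate
boundary effects, and cast to float32.  The atlas (moving) gradient image is
then histogram-matched onto the tissue (fixed) gradient image.

The in-situ-hybridization (ISH) signal chain is separate: signal images are
inverted, quantized to 8 bit, and thresholded at a constant value (125) to
produce binary signal masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.transform import resize, resize_local_mean


@dataclass
class PreprocessConfig:
    """Conditioning parameters; defaults follow the registration recipe."""

    pad_px: int = 50
    working_size: int = 360
    hist_levels: int = 1024
    hist_match_points: int = 10
    threshold_at_mean: bool = True
    ish_threshold: int = 125

    def __post_init__(self) -> None:
        for name in ("pad_px", "working_size", "hist_levels", "hist_match_points"):
            if getattr(self, name) < 0 or (name != "pad_px" and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.ish_threshold <= 255):
            raise ValueError("ish_threshold must be an 8-bit value")


def resize_working(image: np.ndarray, size: int, is_label: bool = False) -> np.ndarray:
    """Resize to the square working size.

    Downscaling uses local-mean (area) averaging, upscaling linear
    interpolation; aspect ratio is not preserved (both axes are forced to
    ``size``).  Label images always use nearest neighbour.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    if image.shape == (size, size):
        return image.copy()
    if is_label:
        out = resize(image, (size, size), order=0, anti_aliasing=False, preserve_range=True)
        return out.astype(image.dtype)
    if size < min(image.shape):
        out = resize_local_mean(image.astype(np.float32), (size, size))
    else:
        out = resize(
            image.astype(np.float32), (size, size), order=1,
            anti_aliasing=False, preserve_range=True,
        )
    return out.astype(np.float32)


def pad_pair(
    fixed: np.ndarray, moving: np.ndarray, pad_px: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-pad both images by a uniform margin and cast to float32."""
    out = []
    for img in (fixed, moving):
        img = np.asarray(img)
        if img.ndim != 2:
            raise ValueError("pad_pair expects 2D images")
        out.append(np.pad(img.astype(np.float32), pad_px, mode="constant", constant_values=0.0))
    return out[0], out[1]


def to_gradient(image: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude, min–max normalized to [0, 1].

    A constant image yields an all-zero output (defined, not an error).
    Border handling is reflective, matching the separable 3×3 Sobel kernels.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    gx = ndimage.sobel(image, axis=1, mode="reflect")
    gy = ndimage.sobel(image, axis=0, mode="reflect")
    mag = np.sqrt(gx * gx + gy * gy)
    lo, hi = mag.min(), mag.max()
    if hi > lo:
        mag = (mag - lo) / (hi - lo)
    else:
        mag = np.zeros_like(mag)
    return mag.astype(np.float32)


def match_histogram(
    moving: np.ndarray, fixed: np.ndarray, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Remap the moving image's intensities so its histogram matches the fixed.

    Piecewise-linear quantile correspondence built from ``hist_match_points``
    match points over ``hist_levels`` histogram bins.  With
    ``threshold_at_mean`` on, the histograms are computed from above-mean
    pixels and pixels at or below the moving image's mean are left unchanged,
    preserving the lower (background) intensity range.
    """
    cfg = cfg or PreprocessConfig()
    moving = np.asarray(moving, dtype=np.float32)
    fixed = np.asarray(fixed, dtype=np.float32)
    if moving.size == 0 or fixed.size == 0:
        raise ValueError("match_histogram requires non-empty images")
    f = sitk.HistogramMatchingImageFilter()
    f.SetNumberOfHistogramLevels(cfg.hist_levels)
    f.SetNumberOfMatchPoints(cfg.hist_match_points)
    f.SetThresholdAtMeanIntensity(cfg.threshold_at_mean)
    matched = sitk.GetArrayFromImage(
        f.Execute(sitk.GetImageFromArray(moving), sitk.GetImageFromArray(fixed))
    )
    if cfg.threshold_at_mean:
        keep = moving <= moving.mean()
        matched[keep] = moving[keep]
    return matched.astype(np.float32)


def invert_quantize(image: np.ndarray) -> np.ndarray:
    """Invert and quantize to 8 bit: round(255·(1 − (x−min)/(max−min))).

    A constant image maps to all 255.  Rounding is numpy's round-half-even.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.full(image.shape, 255, dtype=np.uint8)
    inv = 1.0 - (image - lo) / (hi - lo)
    return np.round(255.0 * inv).astype(np.uint8)


def threshold_signal(image8: np.ndarray, threshold: int = 125) -> np.ndarray:
    """Binary signal mask from an 8-bit image: pixel value strictly > threshold."""
    image8 = np.asarray(image8)
    return image8 > threshold
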