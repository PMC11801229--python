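"""File I/O: volumes (NRRD / npy+JSON sidecar), sections, poses, detections.

Volumes are stored either as NRRD (read and written through SimpleITK) or as
a raw ``.npy`` array with a JSON sidecar ``{"voxel_size_um": ..,
"axis_order": "ap,dv,lr"}``; the paired annotation volume uses the same
format with a ``_labels`` suffix.  Section intensities are written as
float32/16-bit TIFF or 8-bit PNG previews; label images as 32-bit integer
TIFF.  Poses for an experiment live in one JSON file, which is also the
fine-tuning override format users edit between the predict and align steps.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import SimpleITK as sitk
import tifffile

from .atlas import AtlasVolume, SlicePose


# -- volumes ----------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_volume(volume: AtlasVolume, path) -> None:
    """Write intensity + labels; format chosen by extension (.nrrd or .npy)."""
    path = Path(path)
    labels_path = path.with_name(path.stem + "_labels" + path.suffix)
    if path.suffix == ".nrrd":
        for arr, p in ((volume.intensity, path), (volume.labels, labels_path)):
            img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
            img.SetSpacing([volume.voxel_size_um] * 3)
            sitk.WriteImage(img, str(p), useCompression=True)
    elif path.suffix == ".npy":
        np.save(path, volume.intensity)
        np.save(labels_path, volume.labels)
        _sidecar(path).write_text(json.dumps(
            {"voxel_size_um": volume.voxel_size_um, "axis_order": "ap,dv,lr"}
        ))
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r}")


def load_volume(path, labels_path=None) -> AtlasVolume:
    """Read a volume written by :func:`save_volume` (NRRD or npy + sidecar)."""
    path = Path(path)
    labels_path = Path(labels_path) if labels_path else path.with_name(
        path.stem + "_labels" + path.suffix
    )
    if path.suffix == ".nrrd":
        img = sitk.ReadImage(str(path))
        lab = sitk.ReadImage(str(labels_path))
        return AtlasVolume(
            intensity=sitk.GetArrayFromImage(img),
            labels=sitk.GetArrayFromImage(lab).astype(np.int32),
            voxel_size_um=float(img.GetSpacing()[0]),
        )
    if path.suffix == ".npy":
        meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
        return AtlasVolume(
            intensity=np.load(path),
            labels=np.load(labels_path).astype(np.int32),
            voxel_size_um=float(meta.get("voxel_size_um", 10.0)),
        )
    raise ValueError(f"unsupported volume format {path.suffix!r}")


# -- section images ---------------------------------------------------------

def save_image(image: np.ndarray, path) -> None:
    """Write an intensity image: TIFF keeps float32/uint16; PNG is an 8-bit preview."""
    path = Path(path)
    image = np.asarray(image)
    if path.suffix in (".tif", ".tiff"):
        if np.issubdtype(image.dtype, np.floating):
            image = image.astype(np.float32)
        tifffile.imwrite(path, image)
    elif path.suffix == ".png":
        lo, hi = image.min(), image.max()
        u8 = np.zeros(image.shape, dtype=np.uint8) if hi == lo else (
            255 * (image.astype(np.float64) - lo) / (hi - lo)
        ).round().astype(np.uint8)
        iio.imwrite(path, u8)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")


def load_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        return tifffile.imread(path)
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse RGB(A) previews to grayscale
        arr = arr[..., :3].mean(axis=2)
    return arr


def save_labels(labels: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), np.asarray(labels).astype(np.int32))


def load_labels(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


# -- poses ------------------------------------------------------------------

def save_poses(poses: dict[str, SlicePose], ap_max: int, path) -> None:
    """One JSON per experiment: {ap_max, sections: [{file, angles, ap_index}]}."""
    payload = {
        "ap_max": int(ap_max),
        "sections": [
            {"file": name, **asdict(pose)} for name, pose in poses.items()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_poses(path) -> tuple[dict[str, SlicePose], int]:
    data = json.loads(Path(path).read_text())
    poses = {
        s["file"]: SlicePose(
            x_angle_deg=float(s["x_angle_deg"]),
            y_angle_deg=float(s["y_angle_deg"]),
            ap_index=float(s["ap_index"]),
        )
        for s in data["sections"]
    }
    return poses, int(data["ap_max"])


# -- detections -------------------------------------------------------------

def save_detections(detections, path, section: str = "") -> None:
    """CSV with columns section,x_min,y_min,x_max,y_max,confidence."""
    import pandas as pd

    rows = [
        {"section": section, "x_min": d.box[0], "y_min": d.box[1],
         "x_max": d.box[2], "y_max": d.box[3], "confidence": d.confidence}
        for d in detections
    ]
    pd.DataFrame(
        rows, columns=["section", "x_min", "y_min", "x_max", "y_max", "confidence"]
    ).to_csv(Path(path), index=False)


def load_detections(path):
    import pandas as pd

    from .detect import Detection

    df = pd.read_csv(Path(path))
    return [
        Detection((r.x_min, r.y_min, r.x_max, r.y_max), float(r.confidence))
        for r in df.itertuples()
    ]
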