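"""End-to-end orchestration: predict → fine-tune → align → detect → quantify.

The pipeline is file-based and headless.  ``predict`` writes an editable
poses JSON (the fine-tuning step is the user editing that file), ``align``
registers an atlas slice to every section and writes transforms plus warped
label images, ``detect`` runs tiled detection on the signal channel, and
``quantify`` integrates labels, signal masks and detections into per-region
CSV tables.  A machine-readable manifest records the config hash, seed,
package version and per-section status; re-runs skip completed sections
unless forced, and a failed section is recorded and skipped rather than
aborting the experiment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .atlas import (
    SlicePose,
    TemplateMatchPosePredictor,
    apply_average_angles,
    slice_volume,
)
from .detect import DoGBlobDetector, TilingConfig, tiled_detect
from .evaluate import section_metrics
from .io import (
    load_image,
    load_labels,
    load_poses,
    load_volume,
    save_detections,
    save_image,
    save_labels,
    save_poses,
)
from .preprocess import PreprocessConfig, invert_quantize, threshold_signal
from .quantify import (
    Ontology,
    assign_detections_to_regions,
    count_pixels_by_region,
    merge_region_tables,
)
from .register import OptimizerConfig, register_composite

logger = logging.getLogger(__name__)

IMAGE_PATTERNS = ("*.tif", "*.tiff", "*.png")


@dataclass
class ExperimentConfig:
    """All paths and stage settings for one experiment."""

    volume: str
    images: str
    output: str
    signal: str | None = None
    masks: str | None = None
    ontology: str | None = None
    poses: str | None = None
    truth_labels: str | None = None
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    tiling: TilingConfig = field(default_factory=TilingConfig)

    def validate(self) -> None:
        for name in ("volume", "images"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config field {name!r}: path {p} does not exist")
        for name in ("signal", "masks", "ontology", "poses", "truth_labels"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config field {name!r}: path {p} does not exist")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key, sub in (("preprocess", PreprocessConfig),
                         ("optimizer", OptimizerConfig),
                         ("tiling", TilingConfig)):
            if key in d and isinstance(d[key], dict):
                sub_d = dict(d[key])
                for k, v in sub_d.items():
                    if isinstance(v, list):
                        sub_d[k] = tuple(v)
                d[key] = sub(**sub_d)
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        return cls.from_dict(data)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _find_sections(images_dir: str) -> list[Path]:
    files: list[Path] = []
    for pat in IMAGE_PATTERNS:
        files.extend(Path(images_dir).glob(pat))
    return sorted(files)


def predict_poses(config: ExperimentConfig, n_templates: int = 32) -> dict[str, SlicePose]:
    """Initial pose estimates for every section image, with averaged angles."""
    from .atlas import denormalize_pose

    volume = load_volume(config.volume)
    predictor = TemplateMatchPosePredictor(volume, n_templates=n_templates)
    files = _find_sections(config.images)
    poses = {
        f.name: denormalize_pose(predictor(load_image(f)), volume.ap_max)
        for f in files
    }
    averaged = apply_average_angles(list(poses.values()))
    return dict(zip(poses.keys(), averaged))


def run_pipeline(config: ExperimentConfig, force: bool = False) -> dict:
    """Run the full workflow; returns the manifest dict (also written to disk).

    Exit contract: raises on invalid config; individual section failures are
    recorded in the manifest with status "error" and skipped.  The run is
    reproducible from its manifest (config hash + seed).
    """
    config.validate()
    out = Path(config.output)
    dirs = {name: out / name for name in
            ("transforms", "labels", "warped", "detections", "region_tables", "metrics")}
    for d in dirs.values():
        d.mkdir(parents=True, exist_ok=True)

    volume = load_volume(config.volume)
    files = _find_sections(config.images)
    if not files:
        raise FileNotFoundError(f"no section images found in {config.images}")

    if config.poses:
        poses, _ = load_poses(config.poses)
    else:
        poses = predict_poses(config)
        save_poses(poses, volume.ap_max, out / "poses.json")

    ontology = Ontology.from_csv(config.ontology) if config.ontology else None
    detector = DoGBlobDetector()
    manifest_sections: dict[str, dict] = {}
    aggregated = []

    for f in files:
        status: dict = {"status": "ok", "stages": []}
        stem = f.stem
        t0 = time.time()
        try:
            if f.name not in poses:
                raise KeyError(f"no pose for section {f.name}")
            pose = poses[f.name]
            tpath = dirs["transforms"] / f"{stem}.json"
            lpath = dirs["labels"] / f"{stem}_labels.tif"
            wpath = dirs["warped"] / f"{stem}_atlas.tif"
            if force or not (tpath.exists() and lpath.exists() and wpath.exists()):
                fixed_img = load_image(f).astype(np.float32)
                from .atlas import Section

                fixed = Section(image=fixed_img, pose=pose)
                atlas_sec = slice_volume(volume, pose)
                mask = None
                if config.masks:
                    mpath = Path(config.masks) / f.name
                    if mpath.exists():
                        mask = load_image(mpath) > 0
                result = register_composite(
                    fixed, atlas_sec, mask=mask,
                    pre_cfg=config.preprocess, opt_cfg=config.optimizer,
                )
                result.transform.to_json(tpath)
                save_labels(result.warped_labels, lpath)
                save_image(result.warped_atlas, wpath)
                for level, it, metric in result.affine_log[-1:] + result.bspline_log[-1:]:
                    logger.info("section=%s stage=align level=%d iteration=%d metric=%.6f",
                                stem, level, it, metric)
                status["stages"].append("align")
            else:
                status["stages"].append("align:cached")

            warped_labels = load_labels(lpath)

            detections = []
            dpath = dirs["detections"] / f"{stem}.csv"
            signal_img = None
            if config.signal:
                spath = Path(config.signal) / f.name
                if spath.exists():
                    signal_img = load_image(spath)
                    if force or not dpath.exists():
                        sig = signal_img.astype(np.float64)
                        if sig.max() > sig.min():  # detector expects ~[0, 1]
                            sig = (sig - sig.min()) / (sig.max() - sig.min())
                        detections = tiled_detect(sig, detector, config.tiling)
                        save_detections(detections, dpath, section=stem)
                        status["stages"].append("detect")
                    else:
                        from .io import load_detections

                        detections = load_detections(dpath)
                        status["stages"].append("detect:cached")

            qpath = dirs["region_tables"] / f"{stem}.csv"
            if force or not qpath.exists():
                if signal_img is not None:
                    sig_mask = threshold_signal(
                        invert_quantize(signal_img), config.preprocess.ish_threshold
                    )
                else:
                    sig_mask = np.zeros(warped_labels.shape, dtype=bool)
                if sig_mask.shape != warped_labels.shape:
                    raise ValueError(
                        f"signal shape {sig_mask.shape} != labels shape {warped_labels.shape}"
                    )
                table = count_pixels_by_region(sig_mask, warped_labels, ontology)
                cells = assign_detections_to_regions(detections, warped_labels, ontology)
                table = merge_region_tables(table, cells)
                table.insert(0, "section", stem)
                table.to_csv(qpath, index=False)
                status["stages"].append("quantify")
            else:
                status["stages"].append("quantify:cached")
            import pandas as pd

            aggregated.append(pd.read_csv(qpath))

            if config.truth_labels:
                truth_path = Path(config.truth_labels) / f"{stem}_labels.tif"
                if truth_path.exists():
                    m = section_metrics(warped_labels, load_labels(truth_path))
                    m["section"] = stem
                    pd.DataFrame([m]).to_csv(
                        dirs["metrics"] / f"{stem}.csv", index=False
                    )
                    status["stages"].append("evaluate")
        except Exception as exc:  # per-section failure: record and continue
            logger.exception("section %s failed", stem)
            status = {"status": "error", "error": str(exc), "stages": status["stages"]}
        status["elapsed_s"] = round(time.time() - t0, 3)
        manifest_sections[stem] = status

    if aggregated:
        import pandas as pd

        pd.concat(aggregated, ignore_index=True).to_csv(
            out / "region_tables_all.csv", index=False
        )

    n_ok = sum(1 for s in manifest_sections.values() if s["status"] == "ok")
    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
        "sections": manifest_sections,
        "n_sections": len(files),
        "n_ok": n_ok,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    if n_ok == 0:
        raise RuntimeError("all sections failed; see manifest for per-section errors")
    return manifest
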