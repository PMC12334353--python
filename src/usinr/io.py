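"""Dataset manifests, file formats, run configuration and the pipeline.

On disk a dataset is a JSON manifest next to two multi-page TIFFs:
16-bit intensity frames and 8-bit masks.  Volumes are written as
NIfTI-1 with the voxel spacing in the header; meshes as ASCII PLY (or
any format trimesh infers from the extension).  World units are mm
everywhere on disk; normalized coordinates exist only inside the model.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .geometry import ScanGeometry
from .phantom import FrameSet, SpherePhantom

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_volume_nifti",
    "write_labels_nifti",
    "write_mesh",
    "load_run_config",
    "run_pipeline",
]

SCHEMA_VERSION = 1
_UINT16_MAX = 65535


def write_dataset(frames: FrameSet, outdir: str | Path,
                  phantom: SpherePhantom | None = None,
                  seeds: dict | None = None) -> Path:
    """Write frames + masks + manifest; returns the manifest path."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames_path = outdir / "frames.tif"
    masks_path = outdir / "masks.tif"
    tifffile.imwrite(frames_path,
                     (frames.intensity * _UINT16_MAX + 0.5).astype(np.uint16))
    tifffile.imwrite(masks_path, (frames.mask * 255).astype(np.uint8))
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "geometry": frames.geom.to_dict(),
        "frames_file": frames_path.name,
        "masks_file": masks_path.name,
        "angles_deg": [float(a) for a in frames.angles_deg],
        "seeds": seeds or {},
        "phantom": phantom.to_dict() if phantom is not None else None,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_dataset(manifest_path: str | Path) -> tuple:
    """Load a dataset back as ``(FrameSet, ScanGeometry)``.

    Intensities are rescaled from the integer TIFF range to [0, 1];
    masks binarize at > 0.  Validation errors name the offending field.
    """
    import tifffile

    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported manifest schema_version {manifest.get('schema_version')}"
        )
    geom = ScanGeometry.from_dict(manifest["geometry"])
    root = manifest_path.parent
    for key in ("frames_file", "masks_file"):
        if not (root / manifest[key]).exists():
            raise FileNotFoundError(f"{key} {manifest[key]!r} missing next to manifest")
    inten = tifffile.imread(root / manifest["frames_file"])
    masks = tifffile.imread(root / manifest["masks_file"])
    if inten.ndim == 2:
        inten = inten[None]
    if masks.ndim == 2:
        masks = masks[None]
    angles = np.asarray(manifest["angles_deg"], dtype=np.float64)
    if len(angles) != len(inten):
        raise ValueError(
            f"manifest lists {len(angles)} angles but {len(inten)} frames are stored"
        )
    if len(masks) != len(inten):
        raise ValueError(
            f"{len(inten)} intensity frames but {len(masks)} mask frames"
        )
    if np.any(np.diff(angles) <= 0):
        raise ValueError("angles_deg must be strictly increasing")
    return (
        FrameSet(
            angles_deg=angles,
            intensity=inten.astype(np.float32) / _UINT16_MAX,
            mask=(masks > 0).astype(np.uint8),
            geom=geom,
        ),
        geom,
    )


def write_volume_nifti(volume, path: str | Path) -> Path:
    """Write a VoxelVolume's intensity (float32) as NIfTI-1 with mm spacing."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag(list(volume.grid.spacing_mm) + [1.0])
    affine[:3, 3] = volume.grid.origin_mm
    nib.save(nib.Nifti1Image(volume.intensity.astype(np.float32), affine), path)
    return path


def write_labels_nifti(labels: np.ndarray, spacing_mm, path: str | Path,
                       origin_mm=(0.0, 0.0, 0.0)) -> Path:
    import nibabel as nib

    path = Path(path)
    affine = np.diag(list(spacing_mm) + [1.0])
    affine[:3, 3] = origin_mm
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine), path)
    return path


def write_mesh(mesh, path: str | Path) -> Path:
    path = Path(path)
    mesh.export(path)
    return path


_CONFIG_KEYS = {
    "seed", "phantom", "geometry", "inr", "loss", "train",
    "sample_grid_n", "threshold", "outputs",
}
_PHANTOM_KEYS = {
    "n_spheres", "radius_range_mm", "contrast_range_db", "anechoic",
    "sizes_are_diameters", "background_level", "speckle_scale",
    "axial_extent_mm", "lateral_extent_mm", "min_gap_mm",
}


def load_run_config(path: str | Path) -> dict:
    """Load a YAML/JSON run config, rejecting unknown top-level keys."""
    import yaml

    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a mapping")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys are "
            f"{sorted(_CONFIG_KEYS)}"
        )
    bad = set(cfg.get("phantom", {})) - _PHANTOM_KEYS
    if bad:
        raise ValueError(
            f"unknown phantom keys {sorted(bad)}; valid keys are "
            f"{sorted(_PHANTOM_KEYS)}"
        )
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Execute simulate -> train -> sample -> extract -> evaluate.

    Every artifact directory carries a run log with the config hash and
    all seeds; a re-run with the same config reproduces the metrics CSV
    bit for bit.  Any stage failure is re-raised naming the stage.
    Returns a dict of artifact paths and headline metrics.
    """
    from .fit import TrainConfig, fit_inr
    from .geometry import GridSpec
    from .losses import LossConfig
    from .network import InrConfig, save_checkpoint
    from .phantom import make_phantom, rasterize_ground_truth, render_sweep
    from .reslice import sample_volume
    from .volumetry import volume_metrics

    if not isinstance(config, dict):
        config = load_run_config(config)
    else:
        unknown = set(config) - _CONFIG_KEYS
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; valid keys are "
                f"{sorted(_CONFIG_KEYS)}"
            )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stage = "simulate"
    try:
        phantom = make_phantom(seed=seed, **config.get("phantom", {}))
        geom = ScanGeometry(**config["geometry"])
        frames = render_sweep(phantom, geom, seed=seed + 1)
        manifest = write_dataset(frames, outdir / "dataset", phantom,
                                 seeds={"master": seed})

        stage = "train"
        inr_cfg = InrConfig(**config.get("inr", {}))
        loss_cfg = LossConfig(**config.get("loss", {}))
        train_cfg = TrainConfig(**{**config.get("train", {}), "seed": seed + 2})
        model, log = fit_inr(frames, geom, inr_cfg, loss_cfg, train_cfg)
        ckpt_meta = save_checkpoint(model, outdir / "model.npz")
        log.to_csv(outdir / "training_log.csv", index=False)

        stage = "sample"
        n = int(config.get("sample_grid_n", 96))
        grid = GridSpec.for_cylinder(geom.axial_extent_mm,
                                     geom.lateral_extent_mm, n)
        vol = sample_volume(model, grid,
                            threshold=float(config.get("threshold", 0.5)))
        write_volume_nifti(vol, outdir / "volume.nii.gz")

        stage = "extract"
        truth_labels, analytic = rasterize_ground_truth(phantom, grid)
        write_labels_nifti(truth_labels, grid.spacing_mm,
                           outdir / "truth_labels.nii.gz", grid.origin_mm)

        stage = "evaluate"
        metrics = volume_metrics(truth_labels, analytic, vol.mask,
                                 grid.spacing_mm)
        metrics.to_csv(outdir / "metrics.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    run_log = {
        "config_hash": _config_hash(config),
        "config": config,
        "seed": seed,
        "n_parameters": ckpt_meta["n_parameters"],
        "mean_dice": float(metrics["dice"].mean()),
        "mean_voxel_count_error_pct": float(metrics["voxel_count_error_pct"].mean()),
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    return {
        "manifest": manifest,
        "checkpoint": outdir / "model.npz",
        "metrics": outdir / "metrics.csv",
        "run_log": outdir / "run_log.json",
        **{k: run_log[k] for k in ("mean_dice", "mean_voxel_count_error_pct",
                                   "config_hash")},
    }
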