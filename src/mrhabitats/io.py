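"""NIfTI / JSON / YAML input-output and the run manifest.

Volumes are written as NIfTI-1 (``.nii.gz``) with identity affines unless an
affine is supplied; acquisition metadata (frame timing, event frame, flip
angle, TR) travels in a JSON sidecar next to each dynamic series.  Every
file a pipeline run writes is recorded in a manifest with its SHA-256 hash,
the global seed, and the package version.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .containers import DynamicSeries, VfaSet

__all__ = [
    "save_volume",
    "load_volume",
    "save_series",
    "load_series",
    "save_vfa",
    "load_vfa",
    "Manifest",
    "load_config",
]


def save_volume(path, data: np.ndarray, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data), np.eye(4) if affine is None else affine)
    nib.save(img, str(path))
    return path


def load_volume(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def _sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_series(path, series: DynamicSeries, affine=None) -> list[Path]:
    """Dynamic series as 4D NIfTI plus JSON sidecar with timing metadata."""
    path = Path(path)
    save_volume(path, series.data, affine)
    meta = {
        "modality": series.modality,
        "frame_times_s": series.frame_times.tolist(),
        "event_frame": int(series.event_frame),
        "flip_angle_deg": float(series.flip_angle_deg),
        "tr_ms": float(series.tr_ms),
    }
    sc = _sidecar(path)
    sc.write_text(json.dumps(meta, indent=1))
    return [path, sc]


def load_series(path) -> DynamicSeries:
    path = Path(path)
    data, _ = load_volume(path)
    meta = json.loads(_sidecar(path).read_text())
    return DynamicSeries(
        data=data,
        frame_times=np.asarray(meta["frame_times_s"]),
        event_frame=meta["event_frame"],
        modality=meta["modality"],
        flip_angle_deg=meta["flip_angle_deg"],
        tr_ms=meta["tr_ms"],
    )


def save_vfa(path, vfa: VfaSet, affine=None) -> list[Path]:
    path = Path(path)
    save_volume(path, vfa.signals, affine)
    meta = {
        "angles_deg": vfa.angles_deg.tolist(),
        "tr_ms": float(vfa.tr_ms),
        "te_ms": None if vfa.te_ms is None else float(vfa.te_ms),
    }
    sc = _sidecar(path)
    sc.write_text(json.dumps(meta, indent=1))
    return [path, sc]


def load_vfa(path) -> VfaSet:
    path = Path(path)
    data, _ = load_volume(path)
    meta = json.loads(_sidecar(path).read_text())
    return VfaSet(
        signals=data,
        angles_deg=np.asarray(meta["angles_deg"]),
        tr_ms=meta["tr_ms"],
        te_ms=meta["te_ms"],
    )


class Manifest:
    """Content-hash record of every artifact a run writes."""

    def __init__(self, out_dir, seed=None):
        self.out_dir = Path(out_dir)
        self.seed = seed
        self.entries: dict[str, str] = {}

    def record(self, path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.entries[str(path.relative_to(self.out_dir))] = digest

    def write(self) -> Path:
        from . import __version__

        payload = {
            "version": __version__,
            "seed": self.seed,
            "files": self.entries,
        }
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


def load_config(path) -> dict:
    """YAML pipeline configuration; unknown keys are rejected downstream."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg
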