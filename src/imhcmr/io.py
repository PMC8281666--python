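"""NIfTI / YAML interfaces for simulated subjects and configurations."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .phantom import SimulatedImage
from .presets import TissueClass

__all__ = ["save_subject", "load_volume", "load_study_config", "dump_study_config"]


def _affine(pixel_spacing: float, slice_thickness: float = 8.0) -> np.ndarray:
    return np.diag([pixel_spacing, pixel_spacing, slice_thickness, 1.0])


def save_subject(sim: dict, out_dir: str | Path, subject_id: str) -> list[Path]:
    """Write one simulated subject as NIfTI volumes (one file per modality,
    uint8 files for the truth masks).  Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spacing = sim["geometry"].pixel_spacing
    aff = _affine(spacing)
    written = []
    for name in ("bright", "dark", "lge"):
        img: SimulatedImage = sim[name]
        vol = np.transpose(img.intensity, (1, 2, 0)).astype(np.float32)
        path = out / f"{subject_id}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(vol, aff), path)
        written.append(path)
    masks = dict(sim["truth"].masks)
    named = {cls.name.lower(): masks[cls]
             for cls in (TissueClass.MI, TissueClass.IMH, TissueClass.REMOTE_MYO)}
    named["myocardium"] = (
        masks[TissueClass.REMOTE_MYO] | masks[TissueClass.MI] | masks[TissueClass.IMH]
    )
    for name, mask in named.items():
        vol = np.transpose(mask, (1, 2, 0)).astype(np.uint8)
        path = out / f"{subject_id}_mask_{name}.nii.gz"
        nib.save(nib.Nifti1Image(vol, aff), path)
        written.append(path)
    return written


def load_volume(path: str | Path) -> np.ndarray:
    """Read a NIfTI volume back into (slice, row, col) order."""
    vol = np.asarray(nib.load(str(path)).dataobj)
    return np.transpose(vol, (2, 0, 1))


def load_study_config(path: str | Path):
    """Build a StudyConfig from a YAML document (missing keys use defaults)."""
    from .study import GeometryRanges, ReaderModel, StudyConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "geometry_ranges" in raw:
        raw["geometry_ranges"] = GeometryRanges(
            **{k: tuple(v) for k, v in raw["geometry_ranges"].items()}
        )
    if "reader" in raw:
        raw["reader"] = ReaderModel(**raw["reader"])
    for key in ("fields", "phases"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "exclusions" in raw:
        raw["exclusions"] = tuple(tuple(x) for x in raw["exclusions"])
    return StudyConfig(**raw)


def dump_study_config(config, path: str | Path) -> None:
    import json

    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(dataclasses.asdict(config))), fh)
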