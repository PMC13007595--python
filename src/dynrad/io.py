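"""NIfTI and table I/O for the pipeline.

Cine sequences are stored as 3D NIfTI volumes with time as the last axis
(``H x W x T``) and an identically shaped binary mask volume.  All tables
are CSV with a leading ``# config_hash=...`` comment line so mixed-
provenance inputs can be detected.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import GeometryError, MaskError, PipelineError
from .phantom import CineSequence

__all__ = [
    "write_cine_nifti",
    "read_cine_nifti",
    "write_table",
    "read_table",
    "write_json",
]


def write_cine_nifti(
    seq: CineSequence, image_path: str | Path, mask_path: str | Path
) -> tuple[Path, Path]:
    """Write a sequence and its masks as NIfTI files; returns the paths."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    image_path.parent.mkdir(parents=True, exist_ok=True)
    mask_path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([seq.pixel_spacing, seq.pixel_spacing, 1.0, 1.0])
    # (T, H, W) -> (H, W, T): time last, per the storage convention
    img_data = np.transpose(seq.frames, (1, 2, 0))
    mask_data = np.transpose(seq.masks, (1, 2, 0)).astype(np.uint8)
    nib.save(nib.Nifti1Image(img_data, affine), str(image_path))
    nib.save(nib.Nifti1Image(mask_data, affine), str(mask_path))
    return image_path, mask_path


def read_cine_nifti(
    image_path: str | Path, mask_path: str | Path, subject_id: str | None = None
) -> CineSequence:
    """Read an image/mask NIfTI pair back into a :class:`CineSequence`."""
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    if img.shape != msk.shape:
        raise GeometryError(
            f"image shape {img.shape} != mask shape {msk.shape} "
            f"({image_path} / {mask_path})"
        )
    zi = tuple(np.round(img.header.get_zooms()[:2], 6))
    zm = tuple(np.round(msk.header.get_zooms()[:2], 6))
    if zi != zm:
        raise GeometryError(f"pixel spacings differ: {zi} vs {zm}")
    frames = np.transpose(np.asarray(img.dataobj, dtype=np.float64), (2, 0, 1))
    mask_data = np.transpose(np.asarray(msk.dataobj), (2, 0, 1))
    vals = np.unique(mask_data)
    if not np.all(np.isin(vals, [0, 1])):
        raise MaskError(f"mask {mask_path} contains non-binary values {vals}")
    if subject_id is None:
        subject_id = Path(image_path).parent.name or Path(image_path).stem
    return CineSequence(
        subject_id=subject_id,
        frames=frames,
        masks=mask_data.astype(np.uint8),
        pixel_spacing=float(zi[0]),
        intensity_range=(float(frames.min()), float(frames.max())),
    )


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str) -> Path:
    """CSV with a config-hash header comment; byte-deterministic."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path, expect_hash: str | None = None) -> pd.DataFrame:
    """Read a hash-stamped CSV, optionally enforcing provenance."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("# config_hash="):
        raise PipelineError("io", f"{path} lacks a config-hash header")
    found = header.split("=", 1)[1]
    if expect_hash is not None and found != expect_hash:
        raise PipelineError(
            "io", f"{path}: config hash {found} != expected {expect_hash}"
        )
    return pd.read_csv(path, comment="#")


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
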