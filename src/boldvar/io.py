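"""NIfTI and TSV input/output with schema validation.

Runs are stored as NIfTI-1 images with the TR carried in the header's
time-axis zoom; masks are uint8 volumes; phenotypes are TSV files with a
fixed column schema.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import PHENO_COLUMNS, BoldRun

__all__ = [
    "write_nifti",
    "read_nifti",
    "write_bold",
    "read_bold",
    "write_mask",
    "read_mask",
    "write_pheno_tsv",
    "read_pheno_tsv",
    "FormatError",
]


class FormatError(ValueError):
    """Raised for malformed on-disk inputs."""


def write_nifti(
    path, data: np.ndarray, voxel_mm=(3.0, 3.0, 3.0), tr_s: float | None = None
) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data), affine=np.diag(list(voxel_mm) + [1.0]))
    zooms = list(voxel_mm)
    if data.ndim == 4:
        zooms.append(tr_s if tr_s is not None else 0.0)
        img.header.set_xyzt_units("mm", "sec")
    img.header.set_zooms(zooms)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_nifti(path):
    """Load a NIfTI file; returns ``(data, voxel_mm, tr_s_or_None)``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()
    voxel_mm = tuple(float(z) for z in zooms[:3])
    tr = float(zooms[3]) if data.ndim == 4 and len(zooms) > 3 else None
    return data, voxel_mm, tr


def write_bold(path, run: BoldRun) -> Path:
    return write_nifti(path, run.data, run.voxel_mm, run.tr_s)


def read_bold(path, mask_path=None, brain_mask=None, tr_s: float | None = None) -> BoldRun:
    """Load a 4D run (plus its brain mask) into a :class:`BoldRun`.

    A zero TR in the header triggers a warning and requires an explicit
    ``tr_s`` override.
    """
    data, voxel_mm, tr = read_nifti(path)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4D image, got shape {data.shape}")
    if tr is None or tr <= 0:
        warnings.warn(f"{path}: header TR is missing or zero", stacklevel=2)
        if tr_s is None:
            raise FormatError(f"{path}: TR not stored in header; pass tr_s explicitly")
        tr = tr_s
    elif tr_s is not None:
        tr = tr_s
    if brain_mask is None:
        if mask_path is None:
            raise FormatError("either mask_path or brain_mask is required")
        brain_mask = read_mask(mask_path)
    return BoldRun(
        data=np.asarray(data, dtype=float),
        tr_s=float(tr),
        brain_mask=brain_mask,
        provenance=[f"read({Path(path).name})"],
        voxel_mm=voxel_mm,
    )


def write_mask(path, mask: np.ndarray, voxel_mm=(3.0, 3.0, 3.0)) -> Path:
    return write_nifti(path, mask.astype(np.uint8), voxel_mm)


def read_mask(path) -> np.ndarray:
    data, _, _ = read_nifti(path)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D mask, got shape {data.shape}")
    return data.astype(bool)


def write_pheno_tsv(records: pd.DataFrame, path) -> Path:
    path = Path(path)
    missing = [c for c in PHENO_COLUMNS if c not in records.columns]
    if missing:
        raise FormatError(f"phenotype table missing columns: {missing}")
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def read_pheno_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such phenotype file: {path}")
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df
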