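"""File formats: NIfTI volumes, FSL bvec/bval text, ROI YAML, cohort CSV."""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .alps import AlpsRois
from .gradients import GradientTable

__all__ = [
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "read_dwi",
    "write_dwi",
    "read_nifti",
    "write_nifti",
    "load_rois",
    "save_rois",
    "read_cohort",
    "write_cohort",
]

logger = logging.getLogger(__name__)


def read_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """FSL-style b-value / b-vector text files.

    Accepts bvecs as either 3 rows x N columns (FSL convention) or
    N rows x 3 columns; slightly off-unit vectors are renormalised with
    a warning.
    """
    bval_path, bvec_path = Path(bval_path), Path(bvec_path)
    for p in (bval_path, bvec_path):
        if not p.exists():
            raise FileNotFoundError(f"no such file: {p}")
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.atleast_2d(np.loadtxt(bvec_path))
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] == 3 and bvecs.shape[0] != 3:
        pass
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # assume FSL 3xN layout when ambiguous
    else:
        raise ValueError(f"bvec file has shape {bvecs.shape}; expected 3xN or Nx3")
    if len(bvals) != len(bvecs):
        raise ValueError(f"{len(bvals)} b-values but {len(bvecs)} b-vectors")
    dw = bvals > 0
    norms = np.linalg.norm(bvecs[dw], axis=1)
    off = np.abs(norms - 1.0) > 1e-8
    if off.any():
        if np.any(norms[off] == 0):
            raise ValueError("zero-length b-vector on a diffusion-weighted volume")
        if np.any(np.abs(norms[off] - 1.0) > 1e-3):
            logger.warning("renormalising %d b-vectors off unit norm by > 1e-3", int(off.sum()))
        bvecs = bvecs.copy()
        bvecs[dw] = bvecs[dw] / norms[:, None]
    return bvals, bvecs


def write_bvals_bvecs(bvals, bvecs, bval_path, bvec_path) -> None:
    """Write the FSL 1xN bval / 3xN bvec text pair."""
    np.savetxt(bval_path, np.asarray(bvals).reshape(1, -1), fmt="%.6g")
    np.savetxt(bvec_path, np.asarray(bvecs).T, fmt="%.10g")


def read_dwi(nifti_path, bval_path, bvec_path):
    """4-D DWI volume + gradient table; returns (data, affine, GradientTable)."""
    nifti_path = Path(nifti_path)
    if not nifti_path.exists():
        raise FileNotFoundError(f"no such file: {nifti_path}")
    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata())
    bvals, bvecs = read_bvals_bvecs(bval_path, bvec_path)
    if data.shape[-1] != len(bvals):
        raise ValueError(f"DWI has {data.shape[-1]} volumes but gradient table has {len(bvals)} entries")
    return data, img.affine, GradientTable(bvals, bvecs)


def write_dwi(nifti_path, data, gtab: GradientTable, bval_path, bvec_path, affine=None, voxel_size=None) -> None:
    if affine is None:
        affine = np.diag([voxel_size or 1.0] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(nifti_path))
    write_bvals_bvecs(gtab.bvals, gtab.bvecs, bval_path, bvec_path)


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_nifti(path, data, affine=None, voxel_size=None) -> None:
    if affine is None:
        affine = np.diag([voxel_size or 1.0] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_rois(path) -> AlpsRois:
    """ROI spec YAML: per ROI a {center: [i,j,k], radius: r} mapping."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    return AlpsRois.from_dict(spec)


def save_rois(rois_dict: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {k: {"center": list(map(int, v["center"])), "radius": float(v.get("radius", 2.0))} for k, v in rois_dict.items()},
            fh,
        )


def read_cohort(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return pd.read_csv(path)


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
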