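"""Diffusion tensor estimation.

Log-linear least-squares fit of the single-tensor model
ln S = ln S0 - b g^T D g, followed by one weighted re-fit with weights
equal to the squared predicted signal (standard WLLS).  Axis-diffusivity
maps (Dxx, Dyy, Dzz) are the raw tensor diagonal elements in the
scanner frame -- not eigenvalues -- as the ALPS index requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gradients import GradientTable

__all__ = ["DiffusionTensorField", "DiffusivityMaps", "fit_tensor", "axis_diffusivities", "design_matrix"]

# column order of the 6 unique tensor elements
_ELEMENTS = ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")


@dataclass
class DiffusionTensorField:
    """Per-voxel symmetric tensor (6 unique elements) plus estimated S0."""

    elements: np.ndarray  # (..., 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz (mm^2/s)
    s0: np.ndarray
    mask: np.ndarray
    not_psd: np.ndarray  # voxels where positive-definiteness fails (flagged, not altered)

    def tensor(self, index) -> np.ndarray:
        dxx, dyy, dzz, dxy, dxz, dyz = self.elements[index]
        return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


@dataclass
class DiffusivityMaps:
    """Scanner-frame axis diffusivities on the acquisition grid."""

    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray


def design_matrix(gtab: GradientTable) -> np.ndarray:
    """Rows [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]."""
    b = gtab.bvals
    gx, gy, gz = gtab.bvecs.T
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx**2,
            -b * gy**2,
            -b * gz**2,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
        ]
    )


def fit_tensor(
    signal: np.ndarray,
    gtab: GradientTable,
    mask: np.ndarray | None = None,
    max_b: float = 1000.0,
) -> DiffusionTensorField:
    """Fit the diffusion tensor voxel-wise.

    Only volumes with b <= ``max_b`` enter the fit (the Gaussian tensor
    model breaks down at high b; the default keeps the b=50/300/1000
    shells of the study scheme).  Deterministic; voxels outside the mask
    are NaN.
    """
    signal = np.asarray(signal, dtype=float)
    shape = signal.shape[:-1]
    if signal.shape[-1] != len(gtab):
        raise ValueError(f"{signal.shape[-1]} volumes but {len(gtab)} gradient entries")
    keep = gtab.bvals <= max_b
    sub = GradientTable(gtab.bvals[keep], gtab.bvecs[keep])
    if keep.sum() < 7:
        raise ValueError("need at least 7 volumes (>=6 DW + 1 b=0) at b <= max_b")
    X = design_matrix(sub)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("rank-deficient gradient design: fewer than 6 independent directions")
    mask = np.ones(shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)

    y_all = signal[..., keep].reshape(-1, keep.sum())
    flat_mask = mask.ravel()
    elements = np.full((y_all.shape[0], 6), np.nan)
    s0 = np.full(y_all.shape[0], np.nan)
    not_psd = np.zeros(y_all.shape[0], dtype=bool)

    y = y_all[flat_mask]
    floor = 1e-6 * np.maximum(y.max(axis=1, keepdims=True), 1e-300)
    logy = np.log(np.maximum(y, floor))
    # ordinary log-linear fit
    beta = np.linalg.lstsq(X, logy.T, rcond=None)[0].T  # (n_vox, 7)
    # one weighted re-fit: weights = squared predicted signal
    pred = beta @ X.T
    w = np.exp(2.0 * np.clip(pred, -700, 700))
    for i in range(beta.shape[0]):
        sw = np.sqrt(w[i])
        beta[i] = np.linalg.lstsq(X * sw[:, None], logy[i] * sw, rcond=None)[0]
    elements[flat_mask] = beta[:, 1:]
    s0[flat_mask] = np.exp(beta[:, 0])
    # flag non-positive-definite voxels (ALPS uses raw diagonals; no projection)
    dxx, dyy, dzz, dxy, dxz, dyz = beta[:, 1:].T
    m1 = dxx
    m2 = dxx * dyy - dxy**2
    m3 = (
        dxx * (dyy * dzz - dyz**2)
        - dxy * (dxy * dzz - dyz * dxz)
        + dxz * (dxy * dyz - dyy * dxz)
    )
    not_psd[flat_mask] = (m1 <= 0) | (m2 <= 0) | (m3 <= 0)
    return DiffusionTensorField(
        elements.reshape(shape + (6,)),
        s0.reshape(shape),
        mask,
        not_psd.reshape(shape),
    )


def axis_diffusivities(field: DiffusionTensorField) -> DiffusivityMaps:
    """Dxx/Dyy/Dzz maps: the tensor diagonal in the scanner frame."""
    e = field.elements
    return DiffusivityMaps(e[..., 0].copy(), e[..., 1].copy(), e[..., 2].copy())
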