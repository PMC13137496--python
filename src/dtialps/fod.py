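"""Fibre orientation distributions, fixel segmentation and complexity.

Constrained spherical deconvolution (CSD) recovers a fibre orientation
distribution (FOD) per voxel from a single shell, using a zonal
single-fibre response; FOD lobes are segmented into fixels (discrete
fibre populations) by a watershed on a dense antipodally-symmetric
sphere grid; and the per-voxel complexity metric

    complexity = 0                      if N <= 1 fixels
               = N/(N-1) * (1 - f1/sum) otherwise

(f1 the largest fibre density) quantifies how much of the voxel's fibre
content lies outside the dominant bundle.  It is 0 when all fibres share
one orientation and 1 when N >= 2 bundles have equal density.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize

from .gradients import GradientTable, fibonacci_sphere
from .sh import n_coefficients, real_sh_basis, sh_convolution_weights, zonal_indices

__all__ = [
    "ResponseFunction",
    "FodField",
    "Fixel",
    "estimate_response",
    "csd_fit",
    "csd_fit_voxel",
    "segment_fixels",
    "voxel_complexity",
    "roi_mean_complexity",
    "complexity_map",
]


@dataclass(frozen=True)
class ResponseFunction:
    """Zonal (m=0) SH coefficients of the single-fibre signal, fibre along z."""

    zonal: np.ndarray  # one coefficient per even degree 0, 2, ..., lmax
    lmax: int
    shell_b: float

    def __post_init__(self) -> None:
        z = np.asarray(self.zonal, dtype=float)
        if len(z) != self.lmax // 2 + 1:
            raise ValueError("zonal coefficient count does not match lmax")
        object.__setattr__(self, "zonal", z)

    def signal(self, directions: np.ndarray) -> np.ndarray:
        """Evaluate the response signal profile at unit directions."""
        B = real_sh_basis(self.lmax, directions)
        coeffs = np.zeros(n_coefficients(self.lmax))
        coeffs[zonal_indices(self.lmax)] = self.zonal
        return B @ coeffs


@dataclass
class FodField:
    """Per-voxel real even-SH coefficients of the FOD."""

    coeffs: np.ndarray  # (..., n_coefficients(lmax))
    lmax: int
    converged: np.ndarray | None = None


@dataclass(frozen=True)
class Fixel:
    orientation: np.ndarray  # unit vector, z >= 0 hemisphere representative
    density: float


def _rotation_to_z(u: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector ``u`` to +z."""
    u = np.asarray(u, dtype=float)
    u = u / np.linalg.norm(u)
    z = np.array([0.0, 0.0, 1.0])
    c = float(u @ z)
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(u, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def estimate_response(
    signals: np.ndarray,
    orientations: np.ndarray,
    gtab: GradientTable,
    lmax: int = 8,
    shell_b: float = 2000.0,
) -> ResponseFunction:
    """Average single-fibre response from candidate voxels.

    Each voxel's shell signal is normalised by its mean b=0 signal,
    its gradient directions rotated so the fibre lies along +z, and the
    rotated profiles are projected jointly onto zonal harmonics.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    orientations = np.atleast_2d(np.asarray(orientations, dtype=float))
    if len(signals) == 0:
        raise ValueError("no candidate single-fibre voxels")
    if len(signals) != len(orientations):
        raise ValueError("signals and orientations differ in length")
    shell = gtab.shell_mask(shell_b)
    if not shell.any():
        raise ValueError(f"no volumes on shell b={shell_b}")
    dirs = gtab.bvecs[shell]
    b0 = gtab.b0_mask
    rows, rhs = [], []
    zi = zonal_indices(lmax)
    for s, u in zip(signals, orientations):
        s0 = s[b0].mean()
        if s0 <= 0:
            raise ValueError("non-positive b=0 signal in response voxel")
        rot_dirs = dirs @ _rotation_to_z(u).T
        rows.append(real_sh_basis(lmax, rot_dirs)[:, zi])
        rhs.append(s[shell] / s0)
    A = np.vstack(rows)
    y = np.concatenate(rhs)
    zonal, *_ = np.linalg.lstsq(A, y, rcond=None)
    return ResponseFunction(zonal, lmax, shell_b)


@lru_cache(maxsize=8)
def _constraint_grid(n: int) -> np.ndarray:
    return fibonacci_sphere(n)


@lru_cache(maxsize=8)
def _constraint_basis(lmax: int, n: int) -> np.ndarray:
    return real_sh_basis(lmax, _constraint_grid(n))


def csd_fit_voxel(
    shell_signal: np.ndarray,
    forward: np.ndarray,
    constraint_basis: np.ndarray,
    tau: float = 0.1,
    lam: float = 1.0,
    max_iter: int = 50,
) -> tuple[np.ndarray, bool]:
    """Constrained deconvolution of one voxel; returns (coeffs, converged)."""
    n_coef = forward.shape[1]
    # ridge-stabilised initial estimate
    A0 = np.vstack([forward, 1e-3 * np.eye(n_coef)])
    y0 = np.concatenate([shell_signal, np.zeros(n_coef)])
    f, *_ = np.linalg.lstsq(A0, y0, rcond=None)
    amp = constraint_basis @ f
    pos = amp[amp > 0]
    threshold = tau * pos.mean() if pos.size else 0.0
    prev: np.ndarray | None = None
    converged = False
    for _ in range(max_iter):
        neg = amp < threshold
        if prev is not None and np.array_equal(neg, prev):
            converged = True
            break
        prev = neg
        A = np.vstack([forward, lam * constraint_basis[neg]])
        y = np.concatenate([shell_signal, np.zeros(int(neg.sum()))])
        f, *_ = np.linalg.lstsq(A, y, rcond=None)
        amp = constraint_basis @ f
    return f, converged


def csd_fit(
    signal: np.ndarray,
    gtab: GradientTable,
    response: ResponseFunction,
    lmax: int = 8,
    shell_b: float = 2000.0,
    mask: np.ndarray | None = None,
    n_constraint: int = 300,
) -> FodField:
    """Single-shell, single-tissue CSD over a volume (or a single voxel).

    The chosen shell must carry at least as many directions as SH
    coefficients.  Non-negativity is enforced iteratively on an
    ``n_constraint``-point sphere grid; voxels that fail to converge in
    50 iterations are flagged.
    """
    if response.lmax < lmax:
        raise ValueError(f"response order {response.lmax} < requested lmax {lmax}")
    shell = gtab.shell_mask(shell_b)
    ncoef = n_coefficients(lmax)
    if shell.sum() < ncoef:
        raise ValueError(f"shell b={shell_b} has {shell.sum()} directions < {ncoef} coefficients")
    B = real_sh_basis(lmax, gtab.bvecs[shell])
    conv = sh_convolution_weights(lmax, response.zonal[: lmax // 2 + 1])
    forward = B * conv[None, :]
    Bc = _constraint_basis(lmax, n_constraint)

    signal = np.asarray(signal, dtype=float)
    single = signal.ndim == 1
    vol = signal[None, :] if single else signal.reshape(-1, signal.shape[-1])
    if mask is None:
        flat_mask = np.ones(len(vol), dtype=bool)
    else:
        flat_mask = np.asarray(mask, dtype=bool).ravel()
    coeffs = np.full((len(vol), ncoef), np.nan)
    converged = np.zeros(len(vol), dtype=bool)
    b0 = gtab.b0_mask
    for i in np.flatnonzero(flat_mask):
        s0 = vol[i, b0].mean()
        if s0 <= 0:
            continue
        coeffs[i], converged[i] = csd_fit_voxel(vol[i, shell] / s0, forward, Bc)
    if single:
        return FodField(coeffs[0], lmax, converged[:1])
    shape = signal.shape[:-1]
    return FodField(coeffs.reshape(shape + (ncoef,)), lmax, converged.reshape(shape))


def _refine_peak(coeffs: np.ndarray, lmax: int, start: np.ndarray) -> tuple[np.ndarray, float]:
    """Continuous maximisation of the FOD amplitude from a grid seed."""
    theta0 = float(np.arccos(np.clip(start[2], -1, 1)))
    phi0 = float(np.arctan2(start[1], start[0]))

    def neg_amp(x):
        th, ph = x
        d = np.array([[np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]])
        return -float((real_sh_basis(lmax, d) @ coeffs)[0])

    res = minimize(neg_amp, [theta0, phi0], method="Nelder-Mead", options={"xatol": 1e-4, "fatol": 1e-10})
    th, ph = res.x
    u = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
    return u, -res.fun


@lru_cache(maxsize=4)
def _watershed_grid(n_half: int, k: int = 8):
    """Antipodally symmetric grid (2*n_half points) + k-NN neighbour table."""
    half = fibonacci_sphere(n_half)
    grid = np.vstack([half, -half])
    dots = np.clip(grid @ grid.T, -1, 1)
    np.fill_diagonal(dots, -2.0)
    nbrs = np.argsort(-dots, axis=1)[:, :k]
    return grid, nbrs


def segment_fixels(
    fod_coeffs: np.ndarray,
    lmax: int,
    peak_threshold: float = 0.1,
    n_grid: int = 300,
    refine: bool = True,
) -> list[Fixel]:
    """Segment an FOD into fixels by discrete watershed on the sphere.

    Grid points are assigned to their uphill local maximum; each
    surviving maximum (refined peak amplitude >= ``peak_threshold`` x
    the largest peak) becomes a fixel whose fibre density is the
    amplitude-weighted mass of its watershed lobe (antipodal lobes
    merged).  Returns fixels sorted by descending density; empty list
    for flat/sub-threshold FODs.
    """
    grid, nbrs = _watershed_grid(n_grid)
    amp = real_sh_basis(lmax, grid) @ np.asarray(fod_coeffs, dtype=float)
    n = len(grid)
    scale = np.max(np.abs(amp)) if np.max(np.abs(amp)) > 0 else 1.0
    # steepest-ascent pointer; strict improvement so flat FODs yield no maxima
    nbr_amp = amp[nbrs]
    best = np.argmax(nbr_amp, axis=1)
    uphill = nbrs[np.arange(n), best]
    is_max = nbr_amp.max(axis=1) <= amp + 1e-12 * scale
    uphill[is_max] = np.flatnonzero(is_max)
    strict_max = nbr_amp.max(axis=1) < amp - 1e-9 * scale
    if not strict_max.any():
        return []
    # follow pointers to a fixed point
    assign = uphill.copy()
    for _ in range(n):
        nxt = uphill[assign]
        if np.array_equal(nxt, assign):
            break
        assign = nxt
    weight = 4.0 * np.pi / n
    fixels: dict[int, dict] = {}
    for m in np.flatnonzero(strict_max):
        # merge antipodal maxima: canonical index is the partner with smaller index
        partner = (m + n // 2) % n
        key = min(m, partner) if strict_max[partner] else m
        lobe = (assign == m) | (assign == partner)
        mass = float(np.clip(amp[lobe], 0.0, None).sum() * weight)
        if key in fixels:
            continue
        u = grid[m]
        peak_amp = float(amp[m])
        if refine:
            u, peak_amp = _refine_peak(np.asarray(fod_coeffs, dtype=float), lmax, u)
        if u[2] < 0 or (u[2] == 0 and u[0] < 0):
            u = -u
        fixels[key] = {"orientation": u, "density": mass, "peak": peak_amp}
    if not fixels:
        return []
    max_peak = max(f["peak"] for f in fixels.values())
    kept = [f for f in fixels.values() if f["peak"] >= peak_threshold * max_peak and f["density"] > 0]
    kept.sort(key=lambda f: -f["density"])
    return [Fixel(f["orientation"], f["density"]) for f in kept]


def voxel_complexity(fixels) -> float:
    """Complexity of one voxel from its fixel densities (see module docstring)."""
    densities = np.array(
        [f.density if isinstance(f, Fixel) else float(f) for f in fixels], dtype=float
    )
    if np.any(densities < 0):
        raise ValueError("negative fibre density")
    densities = np.sort(densities)[::-1]
    n = len(densities)
    total = densities.sum()
    if n <= 1 or total == 0:
        return 0.0
    return float(n / (n - 1) * (1.0 - densities[0] / total))


def complexity_map(fod: FodField, mask: np.ndarray, peak_threshold: float = 0.1) -> np.ndarray:
    """Voxel-wise complexity over ``mask`` (NaN elsewhere)."""
    shape = fod.coeffs.shape[:-1]
    out = np.full(shape, np.nan)
    for v in map(tuple, np.argwhere(np.asarray(mask, dtype=bool))):
        fx = segment_fixels(fod.coeffs[v], fod.lmax, peak_threshold=peak_threshold)
        out[v] = voxel_complexity(fx)
    return out


def roi_mean_complexity(cmap: np.ndarray, rois, shape=None) -> dict:
    """ROI-averaged complexity per hemisphere plus the subject covariate.

    ``rois`` is an AlpsRois; the subject-level covariate is the mean of
    the four ROI means.
    """
    shape = cmap.shape if shape is None else shape
    out: dict = {}
    for name in ("SLF_L", "SLF_R", "SCR_L", "SCR_R"):
        m = rois.mask(name, shape)
        vals = cmap[m]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError(f"ROI {name} has no complexity values")
        out[name] = float(vals.mean())
    out["left"] = 0.5 * (out["SLF_L"] + out["SCR_L"])
    out["right"] = 0.5 * (out["SLF_R"] + out["SCR_R"])
    out["average"] = float(np.mean([out["SLF_L"], out["SLF_R"], out["SCR_L"], out["SCR_R"]]))
    return out
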