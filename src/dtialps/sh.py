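"""Real even-order spherical harmonics on the unit sphere.

Orthonormal real basis restricted to even degrees (antipodally symmetric
functions), the natural representation for diffusion signals and fibre
orientation distributions.  Ordering: degrees l = 0, 2, ..., L_max, and
within each degree m = -l..l.
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y

__all__ = ["n_coefficients", "real_sh_basis", "zonal_indices", "cart_to_sphere"]


def n_coefficients(lmax: int) -> int:
    """Number of even-degree real SH coefficients up to degree ``lmax``."""
    if lmax < 0 or lmax % 2:
        raise ValueError("lmax must be even and non-negative")
    return (lmax + 1) * (lmax + 2) // 2


def degree_order_pairs(lmax: int) -> list[tuple[int, int]]:
    return [(l, m) for l in range(0, lmax + 1, 2) for m in range(-l, l + 1)]


def zonal_indices(lmax: int) -> np.ndarray:
    """Indices of the m=0 (axially symmetric) terms in the coefficient vector."""
    return np.array([j for j, (_, m) in enumerate(degree_order_pairs(lmax)) if m == 0])


def cart_to_sphere(vecs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors -> (polar theta from +z, azimuth phi)."""
    v = np.asarray(vecs, dtype=float).reshape(-1, 3)
    theta = np.arccos(np.clip(v[:, 2], -1.0, 1.0))
    phi = np.arctan2(v[:, 1], v[:, 0])
    return theta, phi


def real_sh_basis(lmax: int, directions: np.ndarray) -> np.ndarray:
    """Evaluate the real even SH basis at unit ``directions``.

    Returns an (n_dirs, n_coefficients) matrix.  Convention: for m>0 the
    basis function is sqrt(2)*(-1)^m*Re(Y_l^m), for m<0
    sqrt(2)*(-1)^m*Im(Y_l^|m|), and Y_l^0 for m=0 (orthonormal).
    """
    theta, phi = cart_to_sphere(directions)
    cols = []
    for l, m in degree_order_pairs(lmax):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m == 0:
            cols.append(y.real)
        elif m > 0:
            cols.append(np.sqrt(2.0) * (-1.0) ** m * y.real)
        else:
            cols.append(np.sqrt(2.0) * (-1.0) ** m * y.imag)
    return np.column_stack(cols)


def sh_convolution_weights(lmax: int, zonal_coeffs: np.ndarray) -> np.ndarray:
    """Per-coefficient weights for spherical convolution with a zonal kernel.

    Funk-Hecke: convolving an SH-expanded function with an axially
    symmetric kernel of zonal coefficients r_l multiplies each (l, m)
    coefficient by sqrt(4*pi/(2l+1)) * r_l.
    """
    zl = np.asarray(zonal_coeffs, dtype=float)
    degrees = np.arange(0, lmax + 1, 2)
    if len(zl) < len(degrees):
        raise ValueError("zonal kernel has lower order than requested lmax")
    per_degree = {l: np.sqrt(4.0 * np.pi / (2 * l + 1)) * zl[i] for i, l in enumerate(degrees)}
    return np.array([per_degree[l] for l, _ in degree_order_pairs(lmax)])
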