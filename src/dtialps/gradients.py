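"""Diffusion gradient tables.

The acquisition scheme is represented as parallel arrays of b-values
(s/mm^2) and unit gradient directions in the scanner frame
(x = left-right, y = anterior-posterior, z = superior-inferior).
Direction sets are laid out deterministically with a spherical-Fibonacci
lattice so that a given shell specification always yields the same table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GradientTable", "make_gradient_table", "fibonacci_sphere", "PAPER_SHELLS"]

#: The study acquisition: four shells, (b-value, n directions).
PAPER_SHELLS: tuple[tuple[float, int], ...] = ((50.0, 17), (300.0, 8), (1000.0, 64), (2000.0, 64))

_B0_THRESHOLD = 1e-12


def fibonacci_sphere(n: int, offset: int = 0) -> np.ndarray:
    """Return ``n`` approximately uniform unit vectors on the sphere.

    Spherical-Fibonacci (golden-angle) lattice; deterministic.  ``offset``
    shifts the lattice index so that different shells do not share
    directions.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n) + offset
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - (2.0 * (np.arange(n)) + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = golden * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass(frozen=True)
class GradientTable:
    """b-values and unit gradient directions for one acquisition."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if len(bvals) != len(bvecs):
            raise ValueError(f"{len(bvals)} b-values but {len(bvecs)} directions")
        if np.any(bvals < 0):
            raise ValueError("negative b-value")
        if not np.any(bvals <= _B0_THRESHOLD):
            raise ValueError("gradient table needs at least one b=0 volume")
        dw = bvals > _B0_THRESHOLD
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("non-unit gradient direction on a diffusion-weighted volume")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= _B0_THRESHOLD

    @property
    def shells(self) -> list[float]:
        """Distinct nonzero b-values, ascending."""
        return sorted(set(self.bvals[~self.b0_mask].tolist()))

    def shell_mask(self, b: float, rtol: float = 0.01) -> np.ndarray:
        return np.abs(self.bvals - b) <= rtol * max(b, 1.0)


def make_gradient_table(spec="paper", n_b0: int = 1) -> GradientTable:
    """Build a gradient table from a shell specification.

    Parameters
    ----------
    spec
        Either the string ``"paper"`` (the study's four-shell scheme:
        b=50 with 17 directions, b=300 with 8, b=1000 with 64 and
        b=2000 with 64) or a sequence of ``(b_value, n_directions)``
        pairs.  ``n_b0`` leading b=0 volumes are prepended.
    """
    if isinstance(spec, str):
        if spec != "paper":
            raise ValueError(f"unknown gradient spec {spec!r}")
        shells = PAPER_SHELLS
    else:
        shells = tuple((float(b), int(n)) for b, n in spec)
    if n_b0 < 1:
        raise ValueError("at least one b=0 volume is required")
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    offset = 0
    for b, n in shells:
        if b < 0:
            raise ValueError("negative shell b-value")
        if b > _B0_THRESHOLD and n < 1:
            raise ValueError(f"shell b={b} has zero directions")
        dirs = fibonacci_sphere(n, offset=offset)
        offset += n
        bvals.extend([b] * n)
        bvecs.extend(dirs)
    return GradientTable(np.array(bvals), np.array(bvecs))
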