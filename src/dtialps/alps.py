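"""The DTI-ALPS index.

ALPS compares x-axis diffusivity inside projection-fibre (SCR) and
association-fibre (SLF) ROIs against the diffusivities perpendicular to
those tracts:

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

where each term is the arithmetic mean of the corresponding diffusivity
map over one ROI, and the outer "mean" is the unweighted two-term
average of ROI means (not a voxel-pooled mean).  The index is computed
per hemisphere and averaged bilaterally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SphereRoi",
    "AlpsRois",
    "AlpsResult",
    "extract_roi_mean",
    "alps_from_roi_means",
    "alps_index",
    "bilateral_alps",
    "compute_alps",
    "JHU_TEMPLATE_CENTERS",
]

logger = logging.getLogger(__name__)

#: ROI centre coordinates from the JHU white-matter atlas as printed in the
#: source protocol (template voxel space).  Documentation only: they apply
#: solely to maps already registered to that template, which this package
#: does not perform; phantom-space centres are configuration.
JHU_TEMPLATE_CENTERS = {
    "SLF_L": (128, 110, 99),
    "SLF_R": (51, 110, 99),
    "SCR_L": (116, 110, 99),
    "SCR_R": (64, 110, 99),
}

_REQUIRED = ("SLF_L", "SLF_R", "SCR_L", "SCR_R")


@dataclass(frozen=True)
class SphereRoi:
    """Spherical ROI: 0-based voxel centre + radius in voxels."""

    center: tuple[int, int, int]
    radius: float = 2.0

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        if any(not 0 <= c < s for c, s in zip(self.center, shape)):
            raise ValueError(f"ROI centre {self.center} outside grid {shape}")
        idx = np.indices(shape)
        d2 = sum((idx[a] - self.center[a]) ** 2 for a in range(3))
        m = d2 <= self.radius**2
        if not m.any():
            raise ValueError("empty ROI")
        return m


@dataclass(frozen=True)
class AlpsRois:
    """The four ALPS ROIs (explicit masks or sphere specs)."""

    slf_l: object
    slf_r: object
    scr_l: object
    scr_r: object

    @classmethod
    def from_dict(cls, d: dict) -> "AlpsRois":
        missing = [k for k in _REQUIRED if k not in d]
        if missing:
            raise ValueError(f"missing ROIs: {missing}")
        def build(v):
            if isinstance(v, SphereRoi) or isinstance(v, np.ndarray):
                return v
            return SphereRoi(tuple(int(c) for c in v["center"]), float(v.get("radius", 2.0)))
        return cls(build(d["SLF_L"]), build(d["SLF_R"]), build(d["SCR_L"]), build(d["SCR_R"]))

    def mask(self, name: str, shape) -> np.ndarray:
        roi = {"SLF_L": self.slf_l, "SLF_R": self.slf_r, "SCR_L": self.scr_l, "SCR_R": self.scr_r}[name]
        m = roi if isinstance(roi, np.ndarray) else roi.mask(shape)
        if m.shape != tuple(shape):
            raise ValueError("ROI mask grid does not match map grid")
        if not m.any():
            raise ValueError(f"empty ROI {name}")
        return m.astype(bool)

    def validate(self, shape) -> None:
        masks = {n: self.mask(n, shape) for n in _REQUIRED}
        for left, right in (("SLF_L", "SLF_R"), ("SCR_L", "SCR_R")):
            if (masks[left] & masks[right]).any():
                raise ValueError(f"{left} and {right} overlap")


@dataclass(frozen=True)
class AlpsResult:
    """Per-hemisphere ROI means and the ALPS indices derived from them."""

    roi_means_l: dict
    roi_means_r: dict
    alps_l: float
    alps_r: float

    @property
    def alps(self) -> float:
        return 0.5 * (self.alps_l + self.alps_r)


def extract_roi_mean(volume: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of ``volume`` over ``mask``; NaN voxels excluded."""
    vals = np.asarray(volume)[np.asarray(mask, dtype=bool)]
    n_nan = int(np.isnan(vals).sum())
    if n_nan == vals.size:
        raise ValueError("ROI contains only NaN voxels")
    if n_nan:
        logger.warning("excluding %d NaN voxels from ROI mean", n_nan)
    return float(np.nanmean(vals))


def alps_from_roi_means(dxx_proj: float, dxx_assoc: float, dyy_proj: float, dzz_assoc: float) -> float:
    """ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)."""
    denom = 0.5 * (dyy_proj + dzz_assoc)
    if denom <= 0:
        raise ValueError(
            "non-positive ALPS denominator; ROI means: "
            f"dxx_proj={dxx_proj}, dxx_assoc={dxx_assoc}, dyy_proj={dyy_proj}, dzz_assoc={dzz_assoc}"
        )
    return 0.5 * (dxx_proj + dxx_assoc) / denom


def alps_index(maps, rois: AlpsRois, hemisphere: str) -> tuple[float, dict]:
    """ALPS for one hemisphere from Dxx/Dyy/Dzz maps.

    ``maps`` needs attributes ``dxx``, ``dyy``, ``dzz`` (same grid).
    Returns the index and the four ROI means that fed it.
    """
    hemi = hemisphere.upper()
    if hemi not in ("L", "R"):
        raise ValueError("hemisphere must be 'L' or 'R'")
    shape = maps.dxx.shape
    slf = rois.mask(f"SLF_{hemi}", shape)
    scr = rois.mask(f"SCR_{hemi}", shape)
    means = {
        "dxx_proj": extract_roi_mean(maps.dxx, scr),
        "dxx_assoc": extract_roi_mean(maps.dxx, slf),
        "dyy_proj": extract_roi_mean(maps.dyy, scr),
        "dzz_assoc": extract_roi_mean(maps.dzz, slf),
    }
    return alps_from_roi_means(**means), means


def bilateral_alps(left: float, right: float) -> float:
    """Bilateral ALPS: arithmetic mean of the hemispheric indices."""
    if not (np.isfinite(left) and np.isfinite(right)):
        raise ValueError("hemispheric ALPS values must be finite")
    return 0.5 * (left + right)


def compute_alps(maps, rois: AlpsRois) -> AlpsResult:
    """Both hemispheres + bilateral average in one call."""
    rois.validate(maps.dxx.shape)
    alps_l, means_l = alps_index(maps, rois, "L")
    alps_r, means_r = alps_index(maps, rois, "R")
    return AlpsResult(means_l, means_r, alps_l, alps_r)
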