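"""Synthetic diffusion-MRI phantoms for the DTI-ALPS geometry.

The phantom emulates the periventricular arrangement the ALPS index
relies on: superior-longitudinal-fasciculus (SLF) ROIs containing
anterior-posterior (y) association fibres, superior-corona-radiata (SCR)
ROIs containing superior-inferior (z) projection fibres, and in both a
minor perivascular water compartment whose dominant diffusion axis is
left-right (x), orthogonal to either tract.  Ground-truth per-voxel
fibre populations are stored next to the simulated signal so fitted
results can be checked against analytic values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alps import alps_from_roi_means
from .gradients import GradientTable, make_gradient_table

__all__ = [
    "FiberPopulation",
    "NoiseModel",
    "PhantomConfig",
    "Phantom",
    "fiber_tensor",
    "simulate_voxel_signal",
    "build_alps_phantom",
    "ground_truth_alps",
    "ROI_LABELS",
]

#: ROI label codes in the phantom label volume.
ROI_LABELS = {"background": 0, "SLF_L": 1, "SLF_R": 2, "SCR_L": 3, "SCR_R": 4}
_LABEL_NAMES = {v: k for k, v in ROI_LABELS.items()}


@dataclass(frozen=True)
class FiberPopulation:
    """One fibre bundle in a voxel: orientation + signal fraction + diffusivities."""

    orientation: np.ndarray
    volume_fraction: float
    axial_diffusivity: float  # mm^2/s
    radial_diffusivity: float  # mm^2/s

    def __post_init__(self) -> None:
        u = np.asarray(self.orientation, dtype=float).ravel()
        if u.shape != (3,) or abs(np.linalg.norm(u) - 1.0) > 1e-8:
            raise ValueError("orientation must be a unit 3-vector")
        if not 0.0 <= self.volume_fraction <= 1.0:
            raise ValueError("volume_fraction outside [0, 1]")
        if self.radial_diffusivity < 0 or self.axial_diffusivity < self.radial_diffusivity:
            raise ValueError("need axial >= radial >= 0")
        object.__setattr__(self, "orientation", u)

    @property
    def tensor(self) -> np.ndarray:
        return fiber_tensor(self.orientation, self.axial_diffusivity, self.radial_diffusivity)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: none, additive Gaussian, or Rician (magnitude MRI)."""

    kind: str = "rician"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def apply(self, signal: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        if self.kind == "none" or self.sigma == 0.0:
            return np.asarray(signal, dtype=float).copy()
        rng = np.random.default_rng(self.seed) if rng is None else rng
        s = np.asarray(signal, dtype=float)
        if self.kind == "gaussian":
            return s + rng.normal(0.0, self.sigma, size=s.shape)
        n1 = rng.normal(0.0, self.sigma, size=s.shape)
        n2 = rng.normal(0.0, self.sigma, size=s.shape)
        return np.sqrt((s + n1) ** 2 + n2**2)


def fiber_tensor(orientation: np.ndarray, axial: float, radial: float) -> np.ndarray:
    """Axially symmetric diffusion tensor with principal axis ``orientation``."""
    u = np.asarray(orientation, dtype=float).ravel()
    u = u / np.linalg.norm(u)
    return radial * np.eye(3) + (axial - radial) * np.outer(u, u)


def simulate_voxel_signal(
    populations,
    iso_fraction: float,
    iso_tensor: np.ndarray,
    gtab: GradientTable,
    s0: float = 100.0,
    noise: NoiseModel | None = None,
) -> np.ndarray:
    """Multi-tensor forward model for one voxel.

    S(b, g) = S0 * [ sum_i f_i exp(-b g^T D_i g) + f_iso exp(-b g^T D_iso g) ].
    Compartments mix at the signal level (slow exchange).
    """
    if s0 < 0:
        raise ValueError("S0 must be non-negative")
    fractions = [p.volume_fraction for p in populations] + [iso_fraction]
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"volume fractions sum to {sum(fractions)}, not 1")
    b = gtab.bvals
    g = gtab.bvecs
    signal = np.zeros(len(gtab))
    tensors = [p.tensor for p in populations] + [np.asarray(iso_tensor, dtype=float)]
    for f, D in zip(fractions, tensors):
        if f == 0.0:
            continue
        adc = np.einsum("ij,jk,ik->i", g, D, g)
        signal += f * np.exp(-b * adc)
    signal *= s0
    if noise is not None:
        signal = noise.apply(signal)
    return signal


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, microstructure and acquisition of the ALPS phantom.

    Defaults give a 2 mm grid with four spherical ROIs (radius 2 voxels)
    well separated along x, white-matter-like fibre diffusivities, a 10%
    perivascular compartment with dominant x-axis, and Rician noise at
    SNR 30 on the b=0 signal.
    """

    grid_shape: tuple[int, int, int] = (32, 12, 12)
    voxel_size: float = 2.0  # mm
    roi_centers: dict = field(
        default_factory=lambda: {
            "SLF_L": (26, 6, 6),
            "SCR_L": (20, 6, 6),
            "SCR_R": (11, 6, 6),
            "SLF_R": (5, 6, 6),
        }
    )
    roi_radius: float = 2.0  # voxels
    fiber_axial: float = 1.7e-3  # mm^2/s
    fiber_radial: float = 0.3e-3
    pvs_fraction: float = 0.1
    pvs_axial: float = 2.0e-3  # dominant x-axis (along medullary veins)
    pvs_radial: float = 0.4e-3
    background_diffusivity: float = 0.8e-3
    crossing_fraction: float = 0.0  # fraction of ROI voxels given an equal orthogonal fibre
    gradient_spec: object = "paper"
    s0: float = 100.0
    noise: NoiseModel = field(default_factory=lambda: NoiseModel("rician", sigma=100.0 / 30.0, seed=0))
    mixing: str = "tensor"  # "tensor" (fast exchange) or "signal" (slow exchange)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mixing not in ("tensor", "signal"):
            raise ValueError("mixing must be 'tensor' or 'signal'")
        if not 0.0 <= self.pvs_fraction <= 1.0:
            raise ValueError("pvs_fraction outside [0, 1]")
        if not 0.0 <= self.crossing_fraction <= 1.0:
            raise ValueError("crossing_fraction outside [0, 1]")


@dataclass
class Phantom:
    """Simulated 4-D signal plus per-voxel ground truth and ROI labels."""

    signal: np.ndarray  # (x, y, z, volume)
    gtab: GradientTable
    roi_labels: np.ndarray  # int volume, codes in ROI_LABELS
    mean_tensor: np.ndarray  # (x, y, z, 3, 3) analytic voxel-average tensor
    populations: dict  # (i, j, k) -> (list[FiberPopulation], iso_fraction, iso_tensor)
    voxel_size: float
    config: PhantomConfig

    def roi_mask(self, name: str) -> np.ndarray:
        return self.roi_labels == ROI_LABELS[name]


def _sphere_mask(shape, center, radius) -> np.ndarray:
    idx = np.indices(shape)
    d2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
    return d2 <= radius**2


def build_alps_phantom(config: PhantomConfig | None = None) -> Phantom:
    """Build the ALPS phantom described by ``config``.

    SCR ROIs receive z-oriented fibre populations, SLF ROIs y-oriented
    ones, both mixed with the configured x-dominant perivascular
    compartment.  Ground truth (populations and analytic mean tensor) is
    stored alongside the simulated signal; the build is deterministic
    for a fixed config (noise has its own seed, so two configs differing
    only in noise seed share identical truth).
    """
    cfg = config or PhantomConfig()
    shape = tuple(cfg.grid_shape)
    labels = np.zeros(shape, dtype=np.int16)
    masks = {}
    for name in ("SLF_L", "SLF_R", "SCR_L", "SCR_R"):
        if name not in cfg.roi_centers:
            raise ValueError(f"missing ROI centre for {name}")
        m = _sphere_mask(shape, cfg.roi_centers[name], cfg.roi_radius)
        if not m.any():
            raise ValueError(f"ROI {name} is empty on this grid")
        masks[name] = m
    names = list(masks)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if (masks[a] & masks[b]).any():
                raise ValueError(f"ROIs {a} and {b} overlap")
    for name, m in masks.items():
        labels[m] = ROI_LABELS[name]

    pvs_tensor = fiber_tensor([1.0, 0.0, 0.0], cfg.pvs_axial, cfg.pvs_radial)
    iso_bg = cfg.background_diffusivity * np.eye(3)
    axis_of = {"SLF": np.array([0.0, 1.0, 0.0]), "SCR": np.array([0.0, 0.0, 1.0])}
    cross_axis_of = {"SLF": np.array([0.0, 0.0, 1.0]), "SCR": np.array([0.0, 1.0, 0.0])}

    rng = np.random.default_rng(cfg.seed)
    gtab = make_gradient_table(cfg.gradient_spec)
    mean_tensor = np.empty(shape + (3, 3))
    mean_tensor[...] = iso_bg
    populations: dict = {}
    fib = 1.0 - cfg.pvs_fraction
    for name, m in masks.items():
        tract = name[:3]
        voxels = np.argwhere(m)
        n_cross = int(round(cfg.crossing_fraction * len(voxels)))
        cross_idx = set(map(tuple, voxels[rng.permutation(len(voxels))[:n_cross]]))
        for v in map(tuple, voxels):
            if v in cross_idx:
                pops = [
                    FiberPopulation(axis_of[tract], fib / 2, cfg.fiber_axial, cfg.fiber_radial),
                    FiberPopulation(cross_axis_of[tract], fib / 2, cfg.fiber_axial, cfg.fiber_radial),
                ]
            else:
                pops = [FiberPopulation(axis_of[tract], fib, cfg.fiber_axial, cfg.fiber_radial)]
            populations[v] = (pops, cfg.pvs_fraction, pvs_tensor)
            mean_tensor[v] = sum(p.volume_fraction * p.tensor for p in pops) + cfg.pvs_fraction * pvs_tensor

    b = gtab.bvals
    g = gtab.bvecs
    flat_D = mean_tensor.reshape(-1, 3, 3)
    if cfg.mixing == "tensor":
        adc = np.einsum("vij,nj,ni->vn", flat_D, g, g)
        signal = cfg.s0 * np.exp(-adc * b[None, :])
        signal = signal.reshape(shape + (len(gtab),))
    else:
        signal = np.empty(shape + (len(gtab),))
        bg = cfg.s0 * np.exp(-b * cfg.background_diffusivity)
        signal[...] = bg
        for v, (pops, f_iso, iso_D) in populations.items():
            signal[v] = simulate_voxel_signal(pops, f_iso, iso_D, gtab, s0=cfg.s0)
    noise_rng = np.random.default_rng(cfg.noise.seed)
    signal = cfg.noise.apply(signal, rng=noise_rng)
    return Phantom(signal, gtab, labels, mean_tensor, populations, cfg.voxel_size, cfg)


def ground_truth_alps(phantom: Phantom) -> dict:
    """Analytic ALPS from the noiseless voxel-average tensor diagonals.

    ROI-mean Dxx/Dyy/Dzz are taken from the ground-truth mean tensors
    (never the fitted maps); serves as the oracle the fitted pipeline
    must reproduce.  Returns per-hemisphere and bilateral values plus
    the four ROI means per hemisphere.
    """
    out: dict = {}
    for hemi in ("L", "R"):
        slf = phantom.roi_mask(f"SLF_{hemi}")
        scr = phantom.roi_mask(f"SCR_{hemi}")
        if not slf.any() or not scr.any():
            raise ValueError(f"empty ROI in hemisphere {hemi}")
        dxx_proj = phantom.mean_tensor[scr][:, 0, 0].mean()
        dxx_assoc = phantom.mean_tensor[slf][:, 0, 0].mean()
        dyy_proj = phantom.mean_tensor[scr][:, 1, 1].mean()
        dzz_assoc = phantom.mean_tensor[slf][:, 2, 2].mean()
        out[f"alps_{hemi.lower()}"] = alps_from_roi_means(dxx_proj, dxx_assoc, dyy_proj, dzz_assoc)
        out[f"roi_means_{hemi.lower()}"] = {
            "dxx_proj": dxx_proj,
            "dxx_assoc": dxx_assoc,
            "dyy_proj": dyy_proj,
            "dzz_assoc": dzz_assoc,
        }
    out["alps"] = 0.5 * (out["alps_l"] + out["alps_r"])
    return out
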