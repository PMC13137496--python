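"""End-to-end pipeline: phantom -> tensor -> ALPS/complexity -> cohort -> scores -> stats.

Configuration is a plain mapping (YAML-serialisable); every stage's
randomness is seeded from the config, and a JSON manifest recording the
package version, seeds and a hash of the canonical config is written
next to the outputs so identical configs yield identical results.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alps import AlpsRois, compute_alps
from .cohort import CovariateModel, GroupSpec, OutcomeSpec, STUDY_OUTCOMES, simulate_cohort
from .fod import complexity_map, csd_fit, estimate_response, roi_mean_complexity
from .phantom import NoiseModel, PhantomConfig, build_alps_phantom, ground_truth_alps
from .stats import alps_regressions, ancova_omnibus, planned_contrasts, vif
from .tensorfit import axis_diffusivities, fit_tensor

__all__ = ["default_config", "run_pipeline", "phantom_rois", "phantom_config_from_dict", "cohort_from_config"]


def default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "phantom": {"snr": 30.0, "pvs_fraction": 0.1, "crossing_fraction": 0.3},
        "tensor": {"max_b": 1000.0},
        "csd": {"lmax": 8, "shell_b": 2000.0, "peak_threshold": 0.1},
        "cohort": {"seed": seed + 1},
        "stats": {"covariates": ["age", "sex"], "outcomes": ["moca", "mmse", "updrs3", "rbdsq"]},
        "stats_only": False,
    }


def phantom_config_from_dict(d: dict, seed: int = 0) -> PhantomConfig:
    d = dict(d or {})
    snr = d.pop("snr", 30.0)
    s0 = d.pop("s0", 100.0)
    noise = NoiseModel("none") if snr in (None, 0) else NoiseModel("rician", sigma=s0 / snr, seed=seed)
    return PhantomConfig(s0=s0, noise=noise, seed=seed, **d)


def phantom_rois(cfg: PhantomConfig) -> AlpsRois:
    return AlpsRois.from_dict(
        {name: {"center": center, "radius": cfg.roi_radius} for name, center in cfg.roi_centers.items()}
    )


def cohort_from_config(d: dict) -> pd.DataFrame:
    d = dict(d or {})
    seed = d.get("seed", 0)
    if "groups" in d:
        specs = [GroupSpec(**g) for g in d["groups"]]
    else:
        from .cohort import STUDY_GROUPS

        specs = STUDY_GROUPS
    outcomes = {k: OutcomeSpec(**v) for k, v in d.get("outcomes", {}).items()} or dict(STUDY_OUTCOMES)
    cm = CovariateModel(outcomes=outcomes, clinical_extras=d.get("clinical_extras", False))
    return simulate_cohort(specs, cm, seed=seed)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the configured stages; returns the manifest dict.

    Writes alps.csv, complexity.csv (imaging stages), cohort.csv,
    stats/*.csv, and manifest.json under ``out_dir``.  With
    ``stats_only`` the imaging stages are skipped and the cohort is
    read from ``config["cohort_csv"]`` if given.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "stats").mkdir(exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = {"version": __version__, "config_hash": _config_hash(config), "seed": seed, "outputs": []}

    if not config.get("stats_only", False):
        pcfg = _stage("phantom")(phantom_config_from_dict, config.get("phantom"), seed)
        phantom = _stage("phantom")(build_alps_phantom, pcfg)
        tensor_opts = config.get("tensor", {})
        field = _stage("tensor")(fit_tensor, phantom.signal, phantom.gtab, max_b=tensor_opts.get("max_b", 1000.0))
        maps = axis_diffusivities(field)
        rois = phantom_rois(pcfg)
        res = _stage("alps")(compute_alps, maps, rois)
        truth = ground_truth_alps(phantom)
        alps_df = pd.DataFrame(
            [
                {
                    "subject": "phantom-000",
                    "alps_left": res.alps_l,
                    "alps_right": res.alps_r,
                    "alps": res.alps,
                    "alps_truth": truth["alps"],
                    **{f"{k}_l": v for k, v in res.roi_means_l.items()},
                    **{f"{k}_r": v for k, v in res.roi_means_r.items()},
                }
            ]
        )
        alps_df.to_csv(out / "alps.csv", index=False)
        manifest["outputs"].append("alps.csv")

        csd_opts = config.get("csd", {})
        lmax = csd_opts.get("lmax", 8)
        shell_b = csd_opts.get("shell_b", 2000.0)
        roi_mask = phantom.roi_labels > 0
        single = [(v, pops[0].orientation) for v, (pops, _, _) in phantom.populations.items() if len(pops) == 1]
        signals = np.array([phantom.signal[v] for v, _ in single])
        orients = np.array([u for _, u in single])
        response = _stage("complexity")(estimate_response, signals, orients, phantom.gtab, lmax, shell_b)
        fodf = _stage("complexity")(csd_fit, phantom.signal, phantom.gtab, response, lmax, shell_b, roi_mask)
        cmap = _stage("complexity")(complexity_map, fodf, roi_mask, csd_opts.get("peak_threshold", 0.1))
        cx = roi_mean_complexity(cmap, rois)
        pd.DataFrame([{"subject": "phantom-000", **cx}]).to_csv(out / "complexity.csv", index=False)
        manifest["outputs"].append("complexity.csv")

    if config.get("cohort_csv"):
        cohort = pd.read_csv(config["cohort_csv"])
    else:
        cohort = _stage("cohort")(cohort_from_config, config.get("cohort", {"seed": seed + 1}))
    cohort.to_csv(out / "cohort.csv", index=False)
    manifest["outputs"].append("cohort.csv")

    stats_opts = config.get("stats", {})
    covs = tuple(stats_opts.get("covariates", ("age", "sex")))
    omni = _stage("stats")(ancova_omnibus, cohort, "alps", covariates=covs)
    pd.DataFrame([vars(omni)]).to_csv(out / "stats" / "omnibus.csv", index=False)
    contrasts = _stage("stats")(planned_contrasts, cohort, "alps", covariates=covs)
    pd.DataFrame([vars(c) for c in contrasts]).to_csv(out / "stats" / "contrasts.csv", index=False)
    outcomes = [o for o in stats_opts.get("outcomes", ["moca", "mmse"]) if o in cohort.columns]
    if outcomes:
        reg = _stage("stats")(alps_regressions, cohort, outcomes)
        reg.to_csv(out / "stats" / "regressions.csv", index=False)
        manifest["outputs"].append("stats/regressions.csv")
        vif_cols = [c for c in ("alps", "age", "complexity") if c in cohort.columns]
        vif_df = cohort[vif_cols].assign(sex=(cohort["sex"] == "M").astype(float)).dropna()
        vif(vif_df).to_frame().to_csv(out / "stats" / "vif.csv")
        manifest["outputs"].append("stats/vif.csv")
    manifest["outputs"] += ["stats/omnibus.csv", "stats/contrasts.csv"]

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
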