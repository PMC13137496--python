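"""Synthetic clinical cohorts with known ground truth.

Stand-in for the four-group study population (control / PD-NC / PDD /
DLB): per-group sample size, ALPS mean/SD, age distribution and sex
ratio are configurable, clinical outcome columns are generated as
linear functions of ALPS, age and sex with Gaussian residuals, and the
whole table is reproducible under a fixed seed.  Group-level ALPS
separations are expressed directly as mean differences in units of the
residual SD, so injected standardized effects are known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GroupSpec", "OutcomeSpec", "CovariateModel", "simulate_cohort", "STUDY_GROUPS", "STUDY_OUTCOMES"]


@dataclass(frozen=True)
class GroupSpec:
    """One diagnostic group: size, ALPS distribution, demographics."""

    name: str
    n: int
    alps_mean: float
    alps_sd: float
    age_mean: float
    age_sd: float
    male_fraction: float = 0.5
    complexity_mean: float = 0.30
    complexity_sd: float = 0.05
    duration_parkinsonism: tuple[float, float] | None = None  # (mean, sd) years
    duration_dementia: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.name}: n must be >= 2")
        for sd in (self.alps_sd, self.age_sd, self.complexity_sd):
            if sd < 0:
                raise ValueError(f"group {self.name}: negative SD")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction outside [0, 1]")


@dataclass(frozen=True)
class OutcomeSpec:
    """Linear generative model for one clinical column."""

    intercept: float
    alps_beta: float = 0.0
    age_beta: float = 0.0
    sex_beta: float = 0.0  # added for males
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("negative residual SD")


@dataclass(frozen=True)
class CovariateModel:
    """Dependence of ALPS on covariates plus the outcome models."""

    alps_age_beta: float = 0.0  # per year, centred at age_center
    alps_sex_beta: float = 0.0  # added for males
    age_center: float = 68.0
    outcomes: dict = field(default_factory=dict)
    clinical_extras: bool = False  # add vascular items, SVD ratings, durations


#: Default group structure mirroring the study cohort (ns, age and sex per
#: the demographics table; ALPS means/SD chosen so the injected
#: standardized separations equal the reported contrast effect sizes:
#: DLB vs PD-NC 1.29, PDD vs PD-NC 0.57, with residual SD 0.15).
STUDY_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec("control", 26, 1.510, 0.15, 66.7, 9.28, 13 / 26),
    GroupSpec("PD-NC", 60, 1.520, 0.15, 63.1, 7.33, 27 / 60, 0.32, 0.05, (5.9, 3.0), None),
    GroupSpec("PDD", 35, 1.4345, 0.15, 69.5, 7.8, 25 / 35, 0.28, 0.05, (8.2, 5.4), (1.8, 2.2)),
    GroupSpec("DLB", 51, 1.3265, 0.15, 72.7, 5.5, 43 / 51, 0.28, 0.05, (2.4, 2.1), (2.4, 2.1)),
)

#: Default clinical outcome models; ALPS slopes follow the magnitudes of
#: the unadjusted regression coefficients of the study.
STUDY_OUTCOMES: dict = {
    "moca": OutcomeSpec(14.0, alps_beta=9.6, sd=3.0),
    "mmse": OutcomeSpec(18.0, alps_beta=5.84, sd=2.0),
    "updrs3": OutcomeSpec(60.0, alps_beta=-22.36, sd=10.0),
    "rbdsq": OutcomeSpec(13.0, alps_beta=-5.5, sd=3.0),
}


def simulate_cohort(group_specs=STUDY_GROUPS, covariate_model: CovariateModel | None = None, seed: int = 0) -> pd.DataFrame:
    """Draw a per-participant cohort table.

    Returns columns subject, group, age, sex ('M'/'F'), alps,
    complexity, one column per outcome in the covariate model, and --
    when ``clinical_extras`` is set -- vascular-risk booleans, SVD
    ratings and disease durations.  Requested group sizes are respected
    exactly and the table is deterministic under ``seed``.
    """
    cm = covariate_model or CovariateModel(outcomes=dict(STUDY_OUTCOMES))
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for spec in group_specs:
        n = spec.n
        age = rng.normal(spec.age_mean, spec.age_sd, n)
        male = rng.random(n) < spec.male_fraction
        alps = (
            spec.alps_mean
            + cm.alps_age_beta * (age - cm.age_center)
            + cm.alps_sex_beta * male
            + rng.normal(0.0, spec.alps_sd, n)
        )
        row = {
            "subject": [f"sub-{offset + i:04d}" for i in range(n)],
            "group": spec.name,
            "age": age,
            "sex": np.where(male, "M", "F"),
            "alps": alps,
            "complexity": np.clip(rng.normal(spec.complexity_mean, spec.complexity_sd, n), 0.0, 1.0),
        }
        for name, out in cm.outcomes.items():
            row[name] = (
                out.intercept
                + out.alps_beta * alps
                + out.age_beta * (age - cm.age_center)
                + out.sex_beta * male
                + rng.normal(0.0, out.sd, n)
            )
        if cm.clinical_extras:
            for item in ("angina", "myocardial_infarction", "stroke", "diabetes", "high_cholesterol", "high_blood_pressure", "smoker"):
                row[item] = rng.random(n) < 0.1
            row["fazekas"] = rng.integers(0, 4, n)
            row["cmb_count"] = rng.poisson(0.3, n)
            row["lacune_count"] = rng.poisson(0.2, n)
            row["epvs_grade"] = rng.integers(0, 5, n)
            for col, spec_d in (
                ("duration_parkinsonism", spec.duration_parkinsonism),
                ("duration_dementia", spec.duration_dementia),
            ):
                if spec_d is None:
                    row[col] = np.nan
                else:
                    row[col] = np.clip(rng.normal(spec_d[0], spec_d[1], n), 0.0, None)
        frames.append(pd.DataFrame(row))
        offset += n
    return pd.concat(frames, ignore_index=True)
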