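"""Monte-Carlo calibration of the statistics layer.

Runs the group-comparison procedures on cohorts drawn from the
generator with known ground truth: type-I error of the omnibus ANCOVA
under the null, and recovery of an injected covariate-adjusted
standardized group difference (Cohen's d) by the planned-contrast
procedure.
"""

from __future__ import annotations

import numpy as np

from .cohort import CovariateModel, GroupSpec, simulate_cohort
from .stats import ancova_omnibus, planned_contrasts

__all__ = ["type_one_error_rate", "contrast_d_recovery"]

_NULL_MODEL = CovariateModel(outcomes={})


def type_one_error_rate(
    n_reps: int = 2000,
    n_per_group: int = 20,
    n_groups: int = 4,
    alpha: float = 0.05,
    covariates=("age", "sex"),
    seed: int = 0,
) -> float:
    """Rejection rate of the omnibus ANCOVA when all group means are equal.

    Groups share ALPS mean/SD and demographics and covariate effects are
    null, so the rejection rate should sit at the nominal alpha.
    """
    root = np.random.SeedSequence(seed)
    rejections = 0
    for child in root.spawn(n_reps):
        rep_seed = int(child.generate_state(1)[0] % 2**31)
        specs = [GroupSpec(f"g{i}", n_per_group, 1.5, 0.15, 68.0, 8.0, 0.5) for i in range(n_groups)]
        df = simulate_cohort(specs, _NULL_MODEL, seed=rep_seed)
        res = ancova_omnibus(df, "alps", covariates=covariates)
        rejections += res.p < alpha
    return rejections / n_reps


def contrast_d_recovery(
    delta: float,
    n1: int,
    n2: int,
    n_reps: int = 1000,
    covariates=("age", "sex"),
    residual_sd: float = 1.0,
    seed: int = 0,
) -> dict:
    """Mean recovered Cohen's d when the true standardized difference is ``delta``.

    Two groups of sizes ``n1`` (lower mean, e.g. the more affected
    diagnosis) and ``n2`` are drawn with residual SD ``residual_sd``,
    null age/sex effects, and a true adjusted standardized difference
    of ``delta``; the planned-contrast procedure with the same
    covariates estimates d in each replicate.  Returns the mean and SD
    of the estimates (reported as the magnitude, as effect sizes are
    printed).
    """
    root = np.random.SeedSequence(seed)
    estimates = np.empty(n_reps)
    for i, child in enumerate(root.spawn(n_reps)):
        rep_seed = int(child.generate_state(1)[0] % 2**31)
        specs = [
            GroupSpec("affected", n1, 1.5 - delta * residual_sd, residual_sd, 70.0, 7.0, 0.6),
            GroupSpec("reference", n2, 1.5, residual_sd, 66.0, 7.0, 0.5),
        ]
        df = simulate_cohort(specs, _NULL_MODEL, seed=rep_seed)
        (res,) = planned_contrasts(df, "alps", covariates=covariates, pairs=[("affected", "reference")])
        estimates[i] = abs(res.d)
    return {"mean_d": float(estimates.mean()), "sd_d": float(estimates.std(ddof=1)), "n_reps": n_reps}
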