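"""Group-comparison and regression statistics.

ANCOVA via a shared least-squares GLM engine (omnibus F from
full-vs-reduced residual sums of squares), planned two-group contrasts
with covariate-adjusted Cohen's d and Benjamini-Hochberg FDR, linear
regressions of clinical outcomes on ALPS under nested covariate sets,
variance inflation factors, the paired hemisphere t-test, and the
nonparametric table tests (Kruskal-Wallis / rank-sum with Dunn
post-hoc).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GlmFit",
    "OmnibusResult",
    "ContrastResult",
    "RegressionRow",
    "build_design",
    "fit_glm",
    "ancova_omnibus",
    "planned_contrasts",
    "cohens_d_adjusted",
    "bh_fdr",
    "alps_regressions",
    "vif",
    "hemisphere_comparison",
    "nonparametric_tests",
    "dunn_posthoc",
]


@dataclass
class GlmFit:
    """Least-squares fit summary."""

    names: list
    coef: np.ndarray
    rss: float
    df_resid: int
    fitted: np.ndarray
    r2: float
    n: int
    rank: int
    xtx_inv: np.ndarray

    def se(self) -> np.ndarray:
        sigma2 = self.rss / self.df_resid
        return np.sqrt(np.clip(np.diag(self.xtx_inv) * sigma2, 0.0, None))

    def t_test(self, name: str) -> tuple[float, float]:
        """Two-sided t-test of one coefficient against zero."""
        j = self.names.index(name)
        t = self.coef[j] / self.se()[j]
        p = 2.0 * sps.t.sf(abs(t), self.df_resid)
        return float(t), float(p)


def _aliased_columns(X: np.ndarray, names) -> list:
    """Columns made redundant by the others (QR with pivoting)."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[j] for j in piv[rank:]]


def fit_glm(y, X, names=None) -> GlmFit:
    """Ordinary least squares with an explicit design matrix.

    Raises on rank deficiency, naming the aliased columns; assumes
    missing values were removed upstream (listwise deletion).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values in y or design; apply listwise deletion first")
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(f"rank-deficient design; aliased columns: {_aliased_columns(X, names)}")
    if n <= rank:
        raise ValueError("more parameters than observations")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    resid = y - fitted
    rss = float(resid @ resid)
    has_intercept = np.allclose(X[:, 0], 1.0)
    tss = float(((y - y.mean()) ** 2).sum()) if has_intercept else float(y @ y)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    xtx_inv = np.linalg.inv(X.T @ X)
    return GlmFit(names, coef, rss, n - rank, fitted, r2, n, rank, xtx_inv)


def build_design(df: pd.DataFrame, covariates=(), group: str | None = None) -> tuple[np.ndarray, list]:
    """Design matrix [intercept | group dummies | covariates].

    Categorical covariates (object/category dtype, e.g. sex) are
    treatment-coded with the first sorted level as reference; the group
    factor likewise.
    """
    cols = [np.ones(len(df))]
    names = ["intercept"]
    if group is not None:
        levels = sorted(df[group].unique())
        for lev in levels[1:]:
            cols.append((df[group] == lev).to_numpy(dtype=float))
            names.append(f"{group}[{lev}]")
    for cov in covariates:
        s = df[cov]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(s.unique())
            for lev in levels[1:]:
                cols.append((s == lev).to_numpy(dtype=float))
                names.append(f"{cov}[{lev}]")
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(cov)
    return np.column_stack(cols), names


@dataclass(frozen=True)
class OmnibusResult:
    F: float
    df1: int
    df2: int
    p: float


def _complete_cases(df: pd.DataFrame, cols) -> pd.DataFrame:
    return df.dropna(subset=[c for c in cols if c in df.columns]).reset_index(drop=True)


def ancova_omnibus(df: pd.DataFrame, y: str, group: str = "group", covariates=("age", "sex")) -> OmnibusResult:
    """Omnibus group effect controlling for covariates.

    F = ((RSS_reduced - RSS_full)/df_diff) / (RSS_full/df_resid), the
    reduced model dropping the group factor (full-vs-reduced, Type
    II-like for a single factor).
    """
    data = _complete_cases(df, [y, group, *covariates])
    groups = sorted(data[group].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups after listwise deletion")
    counts = data[group].value_counts()
    if (counts < 2).any():
        raise ValueError(f"groups with fewer than 2 observations: {counts[counts < 2].index.tolist()}")
    X_full, names_full = build_design(data, covariates, group=group)
    X_red, _ = build_design(data, covariates, group=None)
    full = fit_glm(data[y], X_full, names_full)
    red = fit_glm(data[y], X_red)
    df1 = full.rank - red.rank
    df2 = full.df_resid
    y_arr = data[y].to_numpy(dtype=float)
    eps = np.finfo(float).eps * len(y_arr) * max(float(y_arr @ y_arr), 1.0)
    if full.rss <= eps and red.rss <= eps:  # exact fit in both models
        return OmnibusResult(0.0, df1, df2, 1.0)
    F = ((red.rss - full.rss) / df1) / (full.rss / df2) if full.rss > 0 else np.inf
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return OmnibusResult(float(max(F, 0.0)), df1, df2, p)


@dataclass
class ContrastResult:
    label: str
    F: float
    p: float
    d: float
    n1: int
    n2: int
    p_fdr: float = np.nan


def cohens_d_adjusted(df: pd.DataFrame, y: str, group: str, pair, covariates=("age", "sex")) -> tuple[float, GlmFit]:
    """Covariate-adjusted standardized difference for one group pair.

    d = (adjusted mean of pair[1] - adjusted mean of pair[0]) / pooled
    residual SD of the two-group ANCOVA.  With no covariates this
    reduces to the classical pooled-SD Cohen's d.
    """
    a, b = pair
    sub = df[df[group].isin(pair)]
    X, names = build_design(sub, covariates)
    X = np.column_stack([X[:, :1], (sub[group] == b).to_numpy(dtype=float), X[:, 1:]])
    names = ["intercept", f"I[{b}]"] + names[1:]
    fit = fit_glm(sub[y], X, names)
    sd = np.sqrt(fit.rss / fit.df_resid)
    return float(fit.coef[1] / sd), fit


def planned_contrasts(df: pd.DataFrame, y: str, group: str = "group", covariates=("age", "sex"), pairs=None) -> list[ContrastResult]:
    """Pairwise two-group ANCOVAs with joint BH-FDR across the pairs.

    Each contrast restricts the data to its two groups and fits the
    same covariate model; Cohen's d is the covariate-adjusted mean
    difference divided by the pooled residual SD.
    """
    if pairs is None:
        pairs = _default_pairs(df[group].unique())
    seen = set()
    for p in pairs:
        key = frozenset(p)
        if key in seen:
            raise ValueError(f"duplicate contrast pair {p}")
        seen.add(key)
    results = []
    for a, b in pairs:
        sub = _complete_cases(df[df[group].isin((a, b))], [y, group, *covariates])
        omni = ancova_omnibus(sub, y, group=group, covariates=covariates)
        d, _ = cohens_d_adjusted(sub, y, group, (a, b), covariates)
        n1 = int((sub[group] == a).sum())
        n2 = int((sub[group] == b).sum())
        results.append(ContrastResult(f"{a} vs {b}", omni.F, omni.p, d, n1, n2))
    adj = bh_fdr([r.p for r in results])
    for r, q in zip(results, adj):
        r.p_fdr = float(q)
    return results


def _default_pairs(groups) -> list:
    """The study's six planned comparisons when all four groups are present."""
    g = set(groups)
    canonical = [
        ("control", "PD-NC"),
        ("control", "PDD"),
        ("control", "DLB"),
        ("PD-NC", "PDD"),
        ("PD-NC", "DLB"),
        ("PDD", "DLB"),
    ]
    pairs = [p for p in canonical if set(p) <= g]
    if not pairs:
        from itertools import combinations

        pairs = list(combinations(sorted(g), 2))
    return pairs


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class RegressionRow:
    outcome: str
    covariate_set: str
    beta_alps: float
    p: float
    r2: float
    n: int
    p_fdr: float = np.nan
    flagged: bool = False


def alps_regressions(
    df: pd.DataFrame,
    outcomes,
    covariate_sets: dict | None = None,
    alps_col: str = "alps",
    patient_groups=("PD-NC", "PDD", "DLB"),
    min_n: int = 10,
) -> pd.DataFrame:
    """Outcome ~ ALPS (+ covariates) across combined patient groups.

    One row per outcome x covariate set, reporting the ALPS
    coefficient, its p-value (BH-FDR-adjusted across the outcome family
    within each covariate set), and model R^2.  Outcomes with fewer
    than ``min_n`` complete cases are flagged and excluded from the FDR
    family.
    """
    if covariate_sets is None:
        covariate_sets = {"none": (), "age": ("age",), "age_sex_complexity": ("age", "sex", "complexity")}
    data = df[df["group"].isin(patient_groups)] if "group" in df.columns else df
    rows: list[RegressionRow] = []
    for set_name, covs in covariate_sets.items():
        family: list[RegressionRow] = []
        for outcome in outcomes:
            sub = _complete_cases(data, [outcome, alps_col, *covs])
            if len(sub) < min_n:
                rows.append(RegressionRow(outcome, set_name, np.nan, np.nan, np.nan, len(sub), flagged=True))
                continue
            X, names = build_design(sub, (alps_col, *covs))
            fit = fit_glm(sub[outcome], X, names)
            _, p = fit.t_test(alps_col)
            row = RegressionRow(outcome, set_name, float(fit.coef[names.index(alps_col)]), p, fit.r2, len(sub))
            family.append(row)
            rows.append(row)
        if family:
            for row, q in zip(family, bh_fdr([r.p for r in family])):
                row.p_fdr = float(q)
    return pd.DataFrame([vars(r) for r in rows])


def vif(predictors: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor.

    VIF_j = 1/(1 - R^2_j) where R^2_j regresses predictor j on the
    remaining predictors (with intercept).  Raises on perfect
    collinearity, naming the offending column.
    """
    X = predictors.astype(float)
    if X.shape[1] < 2:
        raise ValueError("need at least two predictors")
    out = {}
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise ValueError(f"constant predictor {col!r}")
        others = X.drop(columns=col)
        design = np.column_stack([np.ones(len(X)), others.to_numpy()])
        fit = fit_glm(X[col].to_numpy(), design, ["intercept", *others.columns])
        if fit.r2 > 1.0 - 1e-10:
            raise ValueError(f"predictor {col!r} is perfectly collinear with the others")
        out[col] = 1.0 / (1.0 - fit.r2)
    return pd.Series(out, name="vif")


def hemisphere_comparison(left, right) -> tuple[float, float]:
    """Paired t-test of left vs right hemispheric ALPS."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape or left.size < 2:
        raise ValueError("need paired samples of equal length >= 2")
    diff = left - right
    if np.std(diff, ddof=1) == 0:
        if np.allclose(diff, 0):
            return 0.0, 1.0
        raise ValueError("zero variance of nonzero differences: t undefined")
    t, p = sps.ttest_rel(left, right)
    return float(t), float(p)


def dunn_posthoc(values, groups) -> pd.DataFrame:
    """Dunn's rank-based post-hoc z tests with tie correction and BH-FDR."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ranks = sps.rankdata(values)
    n = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    names = sorted(pd.unique(groups).tolist())
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ra, rb = ranks[groups == a], ranks[groups == b]
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / len(ra) + 1.0 / len(rb)))
            z = (ra.mean() - rb.mean()) / se
            rows.append({"pair": f"{a} vs {b}", "z": float(z), "p": float(2 * sps.norm.sf(abs(z)))})
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def nonparametric_tests(values, groups) -> dict:
    """Kruskal-Wallis (>2 groups, tie-corrected) or rank-sum W (2 groups).

    Returns a dict with the statistic, its p-value, and for >2 groups
    the Dunn post-hoc table.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = sorted(pd.unique(groups).tolist())
    if len(names) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in names]
    if np.all(values == values[0]):
        raise ValueError("all values tied; rank tests undefined")
    if len(names) == 2:
        w, p = sps.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        return {"statistic": float(w), "statistic_name": "W", "p": float(p)}
    h, p = sps.kruskal(*samples)
    return {
        "statistic": float(h),
        "statistic_name": "chi2",
        "p": float(p),
        "dunn": dunn_posthoc(values, groups),
    }
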