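"""Derived clinical variables and cohort inclusion rules.

Composite cognitive score (z-scored mean of MoCA plus one prioritised
task per cognitive domain), a configurable NPI-4 estimate, the LBD
symptom composite, the 0-7 vascular-risk factor count, the 0-4 total
small-vessel-disease (SVD) burden score, and the inclusion filters
(control MMSE >= 25; patients within 10 years of diagnosis, PDD counted
from the dementia diagnosis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "COMPOSITE_COMPONENTS",
    "reference_stats_from",
    "composite_cognitive_score",
    "npi4_estimate",
    "lbd_symptom_composite",
    "vascular_risk_score",
    "svd_burden",
    "apply_inclusion_filters",
    "VASCULAR_ITEMS",
]

#: (column, direction): +1 higher-is-better, -1 timed/lower-is-better.
#: MoCA plus the prioritised task of each domain: Stroop colour naming
#: (attention, seconds), category fluency (executive), letter fluency
#: (language), Hooper visual organisation (visuospatial).
COMPOSITE_COMPONENTS: tuple[tuple[str, int], ...] = (
    ("moca", +1),
    ("stroop_colour", -1),
    ("fluency_category", +1),
    ("fluency_letter", +1),
    ("hooper", +1),
)

VASCULAR_ITEMS: tuple[str, ...] = (
    "angina",
    "myocardial_infarction",
    "stroke",
    "diabetes",
    "high_cholesterol",
    "high_blood_pressure",
    "smoker",
)


def reference_stats_from(df: pd.DataFrame, columns, group: str = "control") -> dict:
    """Per-column (mean, SD) from the reference population.

    Default reference is the control group (conventional in
    neuropsychology); pass ``group=None`` to use the full sample.
    """
    ref = df if group is None else df[df["group"] == group]
    if ref.empty:
        raise ValueError(f"no rows in reference group {group!r}")
    stats = {}
    for col in columns:
        vals = ref[col].dropna()
        if len(vals) < 2 or vals.std(ddof=1) == 0:
            raise ValueError(f"cannot z-score against column {col!r} (constant or too few values)")
        stats[col] = (float(vals.mean()), float(vals.std(ddof=1)))
    return stats


def _zscore(value, col, reference_stats, direction=+1):
    mean, sd = reference_stats[col]
    return direction * (value - mean) / sd


def composite_cognitive_score(
    df: pd.DataFrame,
    reference_stats: dict | None = None,
    reference_group: str = "control",
    components=COMPOSITE_COMPONENTS,
) -> pd.Series:
    """Mean of z-scored components; timed tasks sign-flipped (higher = better).

    Missing components are skipped per participant (mean of the
    available z-scores); the result is NaN where every component is
    missing.
    """
    cols = [c for c, _ in components]
    if reference_stats is None:
        reference_stats = reference_stats_from(df, cols, reference_group)
    zs = pd.DataFrame(
        {col: _zscore(df[col], col, reference_stats, direction) for col, direction in components}
    )
    return zs.mean(axis=1, skipna=True)


def npi4_estimate(record, mapping_config: dict) -> tuple[float, list[str]]:
    """Configured estimate of the NPI-4 from available instruments.

    ``mapping_config["items"]`` is a list of ``{"sources": [...],
    "weight": w}`` entries: for each item the first present (non-NaN)
    source field is used, scaled by its weight, and the items are
    summed.  The item-level mapping itself is runtime configuration,
    not code.  Returns the score and the provenance (which field fed
    each item); NaN if any item has no available source.
    """
    items = mapping_config.get("items")
    if not items:
        raise ValueError("mapping_config must provide a non-empty 'items' list")
    # structurally absent fields (vs fields present but NaN) are an error
    absent = [src for item in items for src in item["sources"] if _absent(record, src)]
    if absent:
        raise KeyError(f"mapping references absent fields: {sorted(set(absent))}")
    get = record.get if hasattr(record, "get") else lambda k, d=None: getattr(record, k, d)
    total = 0.0
    provenance = []
    for item in items:
        used = None
        for src in item["sources"]:
            val = get(src)
            if _present(val):
                total += float(item.get("weight", 1.0)) * float(val)
                used = src
                break
        if used is None:
            return float("nan"), provenance
        provenance.append(used)
    return total, provenance


def _absent(record, key) -> bool:
    if hasattr(record, "get"):
        try:
            record[key]
            return False
        except (KeyError, IndexError):
            return True
    return not hasattr(record, key)


def _present(val) -> bool:
    return val is not None and not (isinstance(val, float) and np.isnan(val))


def lbd_symptom_composite(npi4, updrs3, dcfs, moca, reference_stats: dict, zscore: bool = True):
    """Severity composite: mean of NPI-4 estimate, UPDRS-III, DCFS and MoCA.

    Components are z-scored against ``reference_stats`` and
    severity-aligned (MoCA sign-flipped) so higher = worse; the
    raw-average option skips z-scoring (MoCA still negated).  NaN if
    any component is missing.
    """
    parts = {"npi4": npi4, "updrs3": updrs3, "dcfs": dcfs, "moca": moca}
    vals = []
    for name, v in parts.items():
        direction = -1 if name == "moca" else +1
        v = np.asarray(v, dtype=float)
        vals.append(_zscore(v, name, reference_stats, direction) if zscore else direction * v)
    stacked = np.stack(vals)
    out = stacked.mean(axis=0)
    out = np.where(np.any(np.isnan(stacked), axis=0), np.nan, out)
    return float(out) if out.ndim == 0 else out


def vascular_risk_score(items) -> int:
    """Count of positive vascular-risk factors (0-7)."""
    items = list(items)
    if len(items) != 7:
        raise ValueError(f"expected 7 vascular-risk items, got {len(items)}")
    if any(i is None or (isinstance(i, float) and np.isnan(i)) for i in items):
        raise ValueError("missing vascular-risk item")
    return int(sum(bool(i) for i in items))


def svd_burden(fazekas: int, cmb_count: int, lacune_count: int, epvs_grade: int) -> int:
    """Total SVD burden (0-4): one point per imaging feature present.

    Points: >=1 lacune; >=1 cerebral microbleed; moderate-severe
    (grade 2-4) basal-ganglia enlarged perivascular spaces; modified
    Fazekas score of 2 or 3.
    """
    if not 0 <= fazekas <= 3:
        raise ValueError(f"Fazekas score {fazekas} outside 0-3")
    if not 0 <= epvs_grade <= 4:
        raise ValueError(f"EPVS grade {epvs_grade} outside 0-4")
    if cmb_count < 0 or lacune_count < 0:
        raise ValueError("negative lesion count")
    return int(lacune_count >= 1) + int(cmb_count >= 1) + int(epvs_grade >= 2) + int(fazekas >= 2)


@dataclass(frozen=True)
class FilterPolicy:
    mmse_cutoff: float = 25.0  # controls below this are excluded
    max_duration_years: float = 10.0  # inclusive bound
    control_group: str = "control"
    dementia_duration_groups: tuple[str, ...] = ("PDD", "DLB")


def apply_inclusion_filters(df: pd.DataFrame, policy: FilterPolicy | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort inclusion rules; returns (filtered cohort, exclusion log).

    Controls with MMSE below the cutoff are removed; patients more than
    ``max_duration_years`` (inclusive bound) from the relevant
    diagnosis are removed -- the dementia diagnosis for PDD/DLB, onset
    of parkinsonism otherwise.  Idempotent.
    """
    policy = policy or FilterPolicy()
    log_rows = []
    keep = pd.Series(True, index=df.index)
    for idx, row in df.iterrows():
        if row["group"] == policy.control_group:
            mmse = row.get("mmse", np.nan)
            if pd.notna(mmse) and mmse < policy.mmse_cutoff:
                keep[idx] = False
                log_rows.append({"subject": row.get("subject", idx), "rule": "control_mmse_below_cutoff", "value": mmse})
            continue
        col = "duration_dementia" if row["group"] in policy.dementia_duration_groups else "duration_parkinsonism"
        dur = row.get(col, np.nan)
        if pd.notna(dur) and dur > policy.max_duration_years:
            keep[idx] = False
            log_rows.append({"subject": row.get("subject", idx), "rule": f"{col}_over_{policy.max_duration_years:g}y", "value": dur})
    log = pd.DataFrame(log_rows, columns=["subject", "rule", "value"])
    return df[keep].reset_index(drop=True), log
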