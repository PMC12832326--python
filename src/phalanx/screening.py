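"""Score subjects against the normative table and emit radiographic flags.

Flags follow the clinical definitions with strict inequalities:

* metacarpal sign 4:3 / 5:3 — age-matched z-score strictly below -2
  (a subject exactly at -2 is NOT flagged);
* brachydactyly type A3 (BDA3) — 5:3 MP ratio strictly below 0.5.

"Age-matched" means the subject's bone-age group row of the reference
table; no interpolation between discrete groups. SHOX wrist signs
(triangularization, radial lucency, carpal pyramidalization) are
image-reading judgments consumed here as tri-state boolean annotations,
never computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bones import RATIOS, assign_age_group
from .errors import PhalanxError
from .reference import ReferenceTable

SCREENING_COLUMNS = [
    "subject_id",
    "group_used",
    "z43mc",
    "z53mc",
    "z53mp",
    "flag_mc43_short",
    "flag_mc53_short",
    "flag_bda3",
]

_Z_COLUMN = {"r43mc": "z43mc", "r53mc": "z53mc", "r53mp": "z53mp"}

SHOX_SIGNS = ("shox_triangularization", "shox_lucency", "shox_pyramidalization")


@dataclass
class ScreeningResult:
    """Z-scores and flags for one subject."""

    subject_id: str
    group_used: int
    z43mc: float
    z53mc: float
    z53mp: float
    flag_mc43_short: bool
    flag_mc53_short: bool
    flag_bda3: bool


def zscore(
    ratio_value: float, ratio_name: str, bone_age: float, table: ReferenceTable
) -> float:
    """SDS of a ratio value against the subject's age-matched group row."""
    if ratio_name not in RATIOS:
        raise PhalanxError(f"unknown ratio {ratio_name!r}; allowed: {RATIOS}")
    group = assign_age_group(bone_age)
    gs = table.group_stat(ratio_name, group)
    return (ratio_value - gs.mean) / gs.sd


def classify_subject(
    ratios_row,
    bone_age: float,
    table: ReferenceTable,
    *,
    bda3_threshold: float = 0.5,
    mc_sds_threshold: float = -2.0,
) -> ScreeningResult:
    """Screen one subject. ``ratios_row`` is a mapping with the three ratios
    (and optionally ``subject_id``)."""
    group = assign_age_group(bone_age)
    z = {
        name: zscore(float(ratios_row[name]), name, bone_age, table)
        for name in RATIOS
    }
    return ScreeningResult(
        subject_id=str(ratios_row.get("subject_id", "")),
        group_used=group,
        z43mc=z["r43mc"],
        z53mc=z["r53mc"],
        z53mp=z["r53mp"],
        flag_mc43_short=bool(z["r43mc"] < mc_sds_threshold),
        flag_mc53_short=bool(z["r53mc"] < mc_sds_threshold),
        flag_bda3=bool(float(ratios_row["r53mp"]) < bda3_threshold),
    )


def screen_cohort(
    ratios: pd.DataFrame,
    metadata: pd.DataFrame,
    table: ReferenceTable,
    *,
    bda3_threshold: float = 0.5,
    mc_sds_threshold: float = -2.0,
    min_bone_age: Optional[float] = None,
) -> pd.DataFrame:
    """Vectorized screening of a whole cohort; one row per subject.

    ``min_bone_age`` restricts the cohort to older bone ages (subgroup
    re-analysis support); no subject is dropped for any other reason.
    """
    merged = ratios.merge(
        metadata[["subject_id", "bone_age"]], on="subject_id", how="left"
    )
    if merged["bone_age"].isna().any():
        missing = merged.loc[merged["bone_age"].isna(), "subject_id"].tolist()
        raise PhalanxError(f"no metadata row for subject(s): {missing[:5]}")
    if min_bone_age is not None:
        merged = merged[merged["bone_age"] >= min_bone_age].reset_index(drop=True)
    group = assign_age_group(merged["bone_age"].to_numpy())

    out = pd.DataFrame(
        {"subject_id": merged["subject_id"], "group_used": group}
    )
    for name in RATIOS:
        mean = np.empty(len(merged))
        sd = np.empty(len(merged))
        for g in np.unique(group):
            gs = table.group_stat(name, int(g))  # raises if SD unavailable
            mean[group == g] = gs.mean
            sd[group == g] = gs.sd
        out[_Z_COLUMN[name]] = (merged[name].to_numpy(float) - mean) / sd
    out["flag_mc43_short"] = out["z43mc"] < mc_sds_threshold
    out["flag_mc53_short"] = out["z53mc"] < mc_sds_threshold
    out["flag_bda3"] = merged["r53mp"].to_numpy(float) < bda3_threshold
    return out[SCREENING_COLUMNS]


FLAG_COLUMNS = ("flag_mc43_short", "flag_mc53_short", "flag_bda3")


def _proportion_entry(flags: pd.Series) -> dict:
    known = flags.dropna()
    n = int(len(known))
    count = int(known.sum()) if n else 0
    entry: dict = {"count": count, "n": n}
    entry["proportion"] = (count / n) if n else None
    if n == 0:
        entry["note"] = "not computable: empty denominator"
    return entry


def _compare_two_by_two(a: dict, b: dict) -> dict:
    """Chi-square (Yates-free Pearson) when all expected counts >= 5, else
    Fisher's exact (two-sided)."""
    table = np.array(
        [[a["count"], a["n"] - a["count"]], [b["count"], b["n"] - b["count"]]]
    )
    if table.sum() == 0 or a["n"] == 0 or b["n"] == 0:
        return {"test": "none", "note": "not computable: empty denominator"}
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    if np.any(col.sum(axis=0) == 0) or np.any(expected == 0):
        # a margin is empty (e.g. zero flags in both cohorts): no association
        return {"test": "chi_square", "statistic": 0.0, "p_value": 1.0}
    if expected.min() >= 5.0:
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        return {"test": "chi_square", "statistic": float(chi2), "p_value": float(p)}
    stat, p = sps.fisher_exact(table, alternative="two-sided")
    return {"test": "fisher_exact", "statistic": float(stat), "p_value": float(p)}


def cohort_prevalence(
    results: pd.DataFrame,
    shox_annotations: Optional[pd.DataFrame] = None,
    compare_to: Optional[
        tuple[pd.DataFrame, Optional[pd.DataFrame]]
    ] = None,
) -> dict:
    """Per-flag (and per-SHOX-sign) counts and proportions, with an optional
    2x2 comparison against a second cohort.

    ``shox_annotations`` is a metadata table with the tri-state SHOX sign
    columns; unknown annotations leave that sign's denominator.
    ``compare_to`` is a ``(results, shox_annotations)`` pair for the other
    cohort. Returns a JSON-serializable dict keyed by flag name.
    """
    if len(results) == 0:
        raise PhalanxError("cohort_prevalence requires a non-empty cohort")

    def collect(res, shox):
        entries = {}
        for flag in FLAG_COLUMNS:
            entries[flag] = _proportion_entry(res[flag].astype("boolean"))
        if shox is not None:
            for sign in SHOX_SIGNS:
                entries[sign] = _proportion_entry(shox[sign])
        return entries

    summary = collect(results, shox_annotations)
    if compare_to is not None:
        other_res, other_shox = compare_to
        other = collect(other_res, other_shox)
        for key, entry in summary.items():
            if key in other:
                entry["comparison"] = _compare_two_by_two(entry, other[key])
                entry["comparison"]["other_count"] = other[key]["count"]
                entry["comparison"]["other_n"] = other[key]["n"]
    return summary
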