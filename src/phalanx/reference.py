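"""Normative reference table: trimmed, age-stratified ratio statistics.

The normative model is deliberately simple — per bone-age group and per
ratio, a sample mean and SD — because screening downstream only needs an
age-matched z-score. Before the table is built, distribution tails are
trimmed: a subject is excluded when ANY of its three ratios lies more than
``trim_limit`` (default 2.25) pooled SDs from the pooled mean (union rule,
single pass on the input-sample moments, strict inequality at the
boundary). Trimming emulates reference-range construction from a
population whose clinical background is unknown.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats

from .bones import N_GROUPS, RATIOS, assign_age_group
from .errors import PhalanxError, SchemaVersionError, UnavailableGroupError

logger = logging.getLogger(__name__)

FORMAT_TAG = "phalanx-ref/1"

__all__ = [
    "GroupStat",
    "ReferenceTable",
    "TrimReport",
    "DistributionDiagnostics",
    "assign_age_group",
    "trim_outliers",
    "build_reference",
    "distribution_diagnostics",
]


class GroupStat(BaseModel):
    """Sample size, mean and SD of one ratio in one stratum."""

    n: int
    mean: float
    sd: Optional[float] = None  # None when n < 2


class ReferenceTable(BaseModel):
    """Per-group and pooled normative statistics for the three ratios."""

    format: str = FORMAT_TAG
    trim_limit: float
    groups: dict[str, dict[int, GroupStat]]
    pooled: dict[str, GroupStat]
    provenance: dict = Field(default_factory=dict)

    def group_stat(self, ratio: str, group: int) -> GroupStat:
        """Stats of ``ratio`` in age group ``group``; error if SD unusable."""
        try:
            gs = self.groups[ratio][group]
        except KeyError:
            raise UnavailableGroupError(
                f"reference table has no entry for {ratio} in group {group}"
            ) from None
        if gs.sd is None or gs.sd <= 0:
            raise UnavailableGroupError(
                f"reference SD unavailable for {ratio} in group {group} "
                f"(n={gs.n}); screening against this group is refused"
            )
        return gs

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(self.model_dump(mode="json"), indent=1, sort_keys=True)
        )

    @classmethod
    def from_json(cls, path) -> "ReferenceTable":
        data = json.loads(Path(path).read_text())
        tag = data.get("format")
        if tag != FORMAT_TAG:
            raise SchemaVersionError(
                f"unsupported reference-table format {tag!r}; "
                f"expected {FORMAT_TAG!r}"
            )
        return cls.model_validate(data)


@dataclass
class TrimReport:
    """Bookkeeping of the outlier-exclusion pass."""

    n_input: int
    n_excluded_per_ratio: dict[str, int]
    n_excluded_total: int
    n_retained: int
    excluded: pd.DataFrame = field(repr=False)  # subject_id, reason

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_per_ratio": dict(self.n_excluded_per_ratio),
            "n_excluded_total": self.n_excluded_total,
            "n_retained": self.n_retained,
        }


@dataclass
class DistributionDiagnostics:
    """Bias-adjusted sample skewness and excess kurtosis (normal -> 0, 0)."""

    skewness: float
    excess_kurtosis: float
    n: int


def trim_outliers(
    ratios: pd.DataFrame, trim_limit: float = 2.25
) -> tuple[pd.DataFrame, TrimReport]:
    """Exclude subjects with |z| > trim_limit on any ratio (pooled moments).

    Single pass: z-scores use the pooled all-age mean/SD of the *input*
    sample; decisions never feed back into the moments. A subject sitting
    exactly at |z| = trim_limit is retained (strict inequality). A ratio
    with zero SD contributes no exclusions (degenerate-distribution guard).
    """
    if trim_limit <= 0:
        raise PhalanxError("trim_limit must be strictly positive")
    if len(ratios) < 10:
        raise PhalanxError(
            f"trimming requires at least 10 subjects, got {len(ratios)}"
        )
    exclude = pd.DataFrame(False, index=ratios.index, columns=list(RATIOS))
    per_ratio_reason = {}
    for ratio in RATIOS:
        values = ratios[ratio].to_numpy(float)
        mean = values.mean()
        sd = values.std(ddof=1)
        if sd == 0.0:
            logger.warning(
                "ratio %s has zero pooled SD; no exclusions on it", ratio
            )
            continue
        z = (values - mean) / sd
        exclude[ratio] = np.abs(z) > trim_limit
        per_ratio_reason[ratio] = z

    any_excluded = exclude.any(axis=1)
    reasons = []
    for idx in ratios.index[any_excluded]:
        parts = [
            f"{ratio}: z={per_ratio_reason[ratio][ratios.index.get_loc(idx)]:+.2f}"
            for ratio in RATIOS
            if exclude.at[idx, ratio]
        ]
        reasons.append((ratios.at[idx, "subject_id"], "; ".join(parts)))
    report = TrimReport(
        n_input=len(ratios),
        n_excluded_per_ratio={r: int(exclude[r].sum()) for r in RATIOS},
        n_excluded_total=int(any_excluded.sum()),
        n_retained=int((~any_excluded).sum()),
        excluded=pd.DataFrame(reasons, columns=["subject_id", "reason"]),
    )
    return ratios.loc[~any_excluded].reset_index(drop=True), report


def build_reference(
    retained: pd.DataFrame,
    metadata: pd.DataFrame,
    trim_limit: float = 2.25,
    *,
    provenance_extra: Optional[dict] = None,
) -> ReferenceTable:
    """Build the per-group and pooled normative table from retained ratios.

    SDs use the n-1 denominator. A group with n < 2 is kept in the table
    with ``sd=None``; screening against it refuses explicitly.
    """
    merged = retained.merge(
        metadata[["subject_id", "bone_age"]], on="subject_id", how="left"
    )
    if merged["bone_age"].isna().any():
        missing = merged.loc[merged["bone_age"].isna(), "subject_id"].tolist()
        raise PhalanxError(f"no metadata row for subject(s): {missing[:5]}")
    merged["age_group"] = assign_age_group(merged["bone_age"].to_numpy())

    groups: dict[str, dict[int, GroupStat]] = {r: {} for r in RATIOS}
    pooled: dict[str, GroupStat] = {}
    for ratio in RATIOS:
        for g in range(1, N_GROUPS + 1):
            vals = merged.loc[merged["age_group"] == g, ratio].to_numpy(float)
            n = len(vals)
            groups[ratio][g] = GroupStat(
                n=n,
                mean=float(vals.mean()) if n else float("nan"),
                sd=float(vals.std(ddof=1)) if n >= 2 else None,
            )
        vals = merged[ratio].to_numpy(float)
        pooled[ratio] = GroupStat(
            n=len(vals),
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if len(vals) >= 2 else None,
        )

    digest = hashlib.sha256(
        pd.util.hash_pandas_object(
            retained[["subject_id", *RATIOS]], index=False
        ).to_numpy().tobytes()
    ).hexdigest()
    provenance = {"input_sha256": digest, "n_subjects": int(len(retained))}
    if provenance_extra:
        provenance.update(provenance_extra)
    return ReferenceTable(
        trim_limit=trim_limit, groups=groups, pooled=pooled, provenance=provenance
    )


def distribution_diagnostics(values) -> DistributionDiagnostics:
    """Bias-adjusted skewness and excess kurtosis of a sample (n >= 4)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise PhalanxError(
            f"distribution diagnostics require n >= 4, got n={arr.size}"
        )
    if arr.std() == 0.0:
        raise PhalanxError("distribution diagnostics undefined for a constant sample")
    return DistributionDiagnostics(
        skewness=float(stats.skew(arr, bias=False)),
        excess_kurtosis=float(stats.kurtosis(arr, fisher=True, bias=False)),
        n=int(arr.size),
    )
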