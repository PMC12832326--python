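"""Landmark-based radiogrammetry: lengths and ratios from annotations.

A bone is measured as the Euclidean distance from the midpoint of its base
to the midpoint of its distal end, in (continuous, sub-pixel) pixel
coordinates with the usual image convention (origin top-left, y downward).
Because magnification varies film to film, only ratios of lengths within
one film are analyzed; compute_ratios therefore requires all five bones of
a subject and rejects the subject otherwise.

Cohort-level data travel as pandas DataFrames:

* landmarks: ``subject_id, bone, base_x, base_y, head_x, head_y``
* lengths:   ``subject_id, mc3, mc4, mc5, mp3, mp5``
* ratios:    ``subject_id, r43mc, r53mc, r53mp``
* metadata:  ``subject_id, cohort, bone_age, age_group, karyotype,
  gh_treated, height_percentile, shox_triangularization, shox_lucency,
  shox_pyramidalization``
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bones import BONES, RATIO_BONES
from .errors import DuplicateRecordError, SchemaError, ZeroLengthError

LANDMARK_COLUMNS = ["subject_id", "bone", "base_x", "base_y", "head_x", "head_y"]
LENGTH_COLUMNS = ["subject_id", *BONES]
RATIO_COLUMNS = ["subject_id", "r43mc", "r53mc", "r53mp"]
METADATA_COLUMNS = [
    "subject_id",
    "cohort",
    "bone_age",
    "age_group",
    "karyotype",
    "gh_treated",
    "height_percentile",
    "shox_triangularization",
    "shox_lucency",
    "shox_pyramidalization",
]

_TRISTATE = {"true": True, "false": False, "": pd.NA}


@dataclass(frozen=True)
class BoneAnnotation:
    """One bone's two landmark points on one radiograph (pixels)."""

    subject_id: str
    bone: str
    base_mid: tuple[float, float]
    head_mid: tuple[float, float]

    def __post_init__(self):
        if self.bone not in BONES:
            raise SchemaError(
                f"unknown bone {self.bone!r}; allowed: {', '.join(BONES)}"
            )
        coords = (*self.base_mid, *self.head_mid)
        if not all(math.isfinite(c) and c >= 0 for c in coords):
            raise SchemaError(
                f"landmark coordinates must be finite and nonnegative: {coords}"
            )


def bone_length(annotation: BoneAnnotation) -> float:
    """Euclidean base-to-head distance of one annotation, in pixels."""
    dx = annotation.head_mid[0] - annotation.base_mid[0]
    dy = annotation.head_mid[1] - annotation.base_mid[1]
    length = math.hypot(dx, dy)
    if length == 0.0:
        raise ZeroLengthError(
            f"coincident landmarks for subject {annotation.subject_id!r} "
            f"bone {annotation.bone}"
        )
    return length


def annotations_to_lengths(landmarks: pd.DataFrame) -> pd.DataFrame:
    """Convert a landmarks table into a wide per-subject lengths table.

    Subjects missing any of the five bones are dropped silently here; the
    completeness rule is enforced (with reasons) by :func:`compute_ratios`.
    """
    _require_columns(landmarks, LANDMARK_COLUMNS, "landmarks")
    _check_duplicates(landmarks, ["subject_id", "bone"])
    bad = ~landmarks["bone"].isin(BONES)
    if bad.any():
        raise SchemaError(
            f"unknown bone value(s) {sorted(landmarks.loc[bad, 'bone'].unique())}; "
            f"allowed: {', '.join(BONES)}"
        )
    lengths = np.hypot(
        landmarks["head_x"] - landmarks["base_x"],
        landmarks["head_y"] - landmarks["base_y"],
    )
    long = landmarks[["subject_id", "bone"]].assign(length=lengths)
    wide = long.pivot(index="subject_id", columns="bone", values="length")
    wide = wide.reindex(columns=list(BONES)).dropna().reset_index()
    wide.columns.name = None
    return wide


def compute_ratios(
    lengths: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject ratios 4:3 MC, 5:3 MC, 5:3 MP from a lengths table.

    Returns ``(ratios, rejects)``. A subject enters ``ratios`` only with
    all five bones present and strictly positive; otherwise it lands in
    ``rejects`` with columns ``subject_id, reason``.
    """
    _require_columns(lengths, LENGTH_COLUMNS, "lengths")
    _check_duplicates(lengths, ["subject_id"])
    vals = lengths[list(BONES)].apply(pd.to_numeric, errors="coerce")
    missing = vals.isna()
    nonpos = vals.le(0.0) & ~missing
    bad = missing.any(axis=1) | nonpos.any(axis=1)

    reasons = []
    for idx in lengths.index[bad]:
        parts = [f"missing {b}" for b in BONES if missing.at[idx, b]]
        parts += [f"non-positive {b}" for b in BONES if nonpos.at[idx, b]]
        reasons.append((lengths.at[idx, "subject_id"], "; ".join(parts)))
    rejects = pd.DataFrame(reasons, columns=["subject_id", "reason"])

    ok = lengths.loc[~bad, ["subject_id"]].copy()
    v = vals.loc[~bad]
    for ratio, (num, den) in RATIO_BONES.items():
        ok[ratio] = (v[num] / v[den]).to_numpy()
    return ok.reset_index(drop=True), rejects


# ---------------------------------------------------------------------------
# CSV readers / writers (comma-separated, '.' decimal, UTF-8, header required)


def _require_columns(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {missing}")


def _check_duplicates(df: pd.DataFrame, keys) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        first = df.loc[dup, keys].iloc[0].tolist()
        raise DuplicateRecordError(f"duplicate key {tuple(first)} on {keys}")


def read_annotations(path) -> pd.DataFrame:
    """Read and validate a landmarks CSV."""
    df = pd.read_csv(path, dtype={"subject_id": str, "bone": str})
    _require_columns(df, LANDMARK_COLUMNS, "landmarks")
    _check_duplicates(df, ["subject_id", "bone"])
    bad = ~df["bone"].isin(BONES)
    if bad.any():
        raise SchemaError(
            f"unknown bone value(s) {sorted(df.loc[bad, 'bone'].unique())}; "
            f"allowed: {', '.join(BONES)}"
        )
    coords = df[["base_x", "base_y", "head_x", "head_y"]].to_numpy(float)
    if not np.all(np.isfinite(coords)) or np.any(coords < 0):
        raise SchemaError("landmark coordinates must be finite and nonnegative")
    return df


def read_lengths(path) -> pd.DataFrame:
    """Read and validate a bone-lengths CSV (one row per subject)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(df, LENGTH_COLUMNS, "lengths")
    _check_duplicates(df, ["subject_id"])
    return df


def read_metadata(path) -> pd.DataFrame:
    """Read and validate a subject-metadata CSV.

    Tri-state booleans are serialized as ``true``/``false``/empty and come
    back as pandas nullable booleans.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "cohort": str}, keep_default_na=False, na_values=[])
    _require_columns(df, METADATA_COLUMNS, "metadata")
    _check_duplicates(df, ["subject_id"])
    bad = ~df["cohort"].isin(["reference", "TS"])
    if bad.any():
        raise SchemaError(
            f"unknown cohort value(s) {sorted(df.loc[bad, 'cohort'].unique())}; "
            "allowed: reference, TS"
        )
    df["bone_age"] = pd.to_numeric(df["bone_age"])
    df["age_group"] = pd.to_numeric(df["age_group"]).astype(int)
    hp = df["height_percentile"].astype(str).str.strip()
    df["height_percentile"] = pd.to_numeric(hp.where(hp != "", other=np.nan))
    for col in (
        "gh_treated",
        "shox_triangularization",
        "shox_lucency",
        "shox_pyramidalization",
    ):
        raw = df[col].astype(str).str.lower()
        unknown = ~raw.isin(_TRISTATE)
        if unknown.any():
            raise SchemaError(
                f"column {col} must be true/false/empty, got "
                f"{sorted(raw[unknown].unique())}"
            )
        df[col] = raw.map(_TRISTATE).astype("boolean")
    return df


def read_ratios(path) -> pd.DataFrame:
    """Read and validate a ratios CSV."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    _require_columns(df, RATIO_COLUMNS, "ratios")
    _check_duplicates(df, ["subject_id"])
    return df


def write_ratios(ratios: pd.DataFrame, path) -> None:
    """Write a ratios CSV in the documented dialect."""
    _require_columns(ratios, RATIO_COLUMNS, "ratios")
    ratios[RATIO_COLUMNS].to_csv(path, index=False)
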