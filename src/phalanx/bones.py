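"""Shared vocabulary: bone names, ratio names, bone-age groups.

Ratios are unitless and magnification-invariant, which is why they (and not
absolute pixel lengths) are the analysis currency throughout the package.
"""

from __future__ import annotations

import numpy as np

from .errors import AgeRangeError

#: Bones measured on a left-hand film: 3rd–5th metacarpals, 3rd and 5th
#: middle phalanges. Lower-case names are the canonical column names.
BONES: tuple[str, ...] = ("mc3", "mc4", "mc5", "mp3", "mp5")

#: The three length ratios: 4th:3rd metacarpal, 5th:3rd metacarpal,
#: 5th:3rd middle phalanx.
RATIOS: tuple[str, ...] = ("r43mc", "r53mc", "r53mp")

#: Map ratio name -> (numerator bone, denominator bone).
RATIO_BONES: dict[str, tuple[str, str]] = {
    "r43mc": ("mc4", "mc3"),
    "r53mc": ("mc5", "mc3"),
    "r53mp": ("mp5", "mp3"),
}

#: Bone-age group edges in years. Groups are half-open [lo, hi) except the
#: last, which is closed at 18.0: 1: [0,6), 2: [6,8), 3: [8,11), 4: [11,13),
#: 5: [13,15), 6: [15,18]. The bins track pubertal developmental stages.
AGE_EDGES: tuple[float, ...] = (0.0, 6.0, 8.0, 11.0, 13.0, 15.0, 18.0)

N_GROUPS = 6


def assign_age_group(bone_age):
    """Map bone age (years) to group 1–6.

    Accepts a scalar or array. Raises :class:`AgeRangeError` for ages
    outside [0, 18]; exactly 18.0 belongs to group 6.
    """
    age = np.asarray(bone_age, dtype=float)
    if np.any(~np.isfinite(age)) or np.any(age < 0.0) or np.any(age > 18.0):
        raise AgeRangeError(
            f"bone age outside [0, 18] years: {np.asarray(bone_age)!r}"
        )
    # right edge of each interior bin is exclusive; 18.0 folds into group 6
    group = np.digitize(age, AGE_EDGES[1:-1], right=False) + 1
    group = np.where(age == 18.0, N_GROUPS, group)
    if np.isscalar(bone_age) or np.ndim(bone_age) == 0:
        return int(group)
    return group.astype(int)


def group_bounds(group: int) -> tuple[float, float]:
    """Return the [lo, hi) age bounds of a group (group 6 is [15, 18])."""
    if not 1 <= group <= N_GROUPS:
        raise AgeRangeError(f"age group must be 1..6, got {group}")
    return AGE_EDGES[group - 1], AGE_EDGES[group]
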