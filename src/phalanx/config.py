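"""Generator and pipeline configuration.

The defaults ARE the study conditions: a reference cohort of 4,438 female
bone-age films with pooled 4:3 MC ratio 0.889 +/- 0.019, 5:3 MC ratio
0.822 +/- 0.022 and inter-ratio correlation 0.49; a Turner-syndrome (TS)
cohort of 81 films ages 3.0-17.9 with ratio moments 0.860 +/- 0.050,
0.820 +/- 0.040, 0.600 +/- 0.090 and correlations 0.478 / 0.26. Values not
printed anywhere (age-group occupancy, 5:3 MP reference marginal, the third
TS correlation pair) are derived defaults documented in docs/methods.md.
"""

from __future__ import annotations

import math
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .bones import N_GROUPS
from .calibration import TsMixture, calibrate_reference_noise

# ---------------------------------------------------------------------------
# Published cohort moments the generator is calibrated against.
REF_R43_MEAN, REF_R43_SD = 0.889, 0.019
REF_R53_MEAN, REF_R53_SD = 0.822, 0.022
REF_MC_CORR = 0.49
TS_RATIO_MEANS = (0.860, 0.820, 0.600)
TS_RATIO_SDS = (0.050, 0.040, 0.090)
TS_CORR_43_53MC = 0.478
TS_CORR_43_53MP = 0.26

# Derived defaults (rationale in docs/methods.md).
GROUP6_MC_DROP = 0.008  # late-puberty dip of both MC ratios in group 6
REF_MP53_GROUP_MEANS = (0.61, 0.61, 0.61, 0.61, 0.64, 0.64)
REF_MP53_SD = 0.0575
MC3_PROPORTION = 0.42  # MC3 length as a fraction of the hand scale
MP3_PROPORTION = 0.20
TS_AGE_RANGE = (3.0, 17.9)
# age slope of the TS 5:3 MP ratio reproducing r ~ 0.28 with bone age
_TS_AGE_SD = (TS_AGE_RANGE[1] - TS_AGE_RANGE[0]) / math.sqrt(12.0)
TS_MP_AGE_SLOPE = 0.28 * TS_RATIO_SDS[2] / _TS_AGE_SD


def default_log_noise_sd() -> dict[str, float]:
    """Per-bone log-noise SDs reproducing the printed reference moments."""
    sd3, sd4, sd5 = calibrate_reference_noise(
        REF_R43_SD / REF_R43_MEAN, REF_R53_SD / REF_R53_MEAN, REF_MC_CORR
    )
    # MP ratio noise: split evenly between numerator and denominator bones
    mp_pooled_mean = sum(REF_MP53_GROUP_MEANS) / N_GROUPS
    s_mp = REF_MP53_SD / mp_pooled_mean
    return {
        "sd3": sd3,
        "sd4": sd4,
        "sd5": sd5,
        "sdMP3": s_mp / math.sqrt(2.0),
        "sdMP5": s_mp / math.sqrt(2.0),
    }


def _ref_mc_ratio_targets() -> tuple[list[float], list[float]]:
    """Per-group 4:3 and 5:3 MC ratio means: flat over groups 1-5, lower in
    group 6, pooling (uniform weights) to the printed means."""
    r43_hi = REF_R43_MEAN + GROUP6_MC_DROP / N_GROUPS
    r53_hi = REF_R53_MEAN + GROUP6_MC_DROP / N_GROUPS
    r43 = [r43_hi] * (N_GROUPS - 1) + [r43_hi - GROUP6_MC_DROP]
    r53 = [r53_hi] * (N_GROUPS - 1) + [r53_hi - GROUP6_MC_DROP]
    return r43, r53


def default_mc_proportions() -> list[tuple[float, float, float]]:
    """Per-group (MC3, MC4, MC5) expected length proportions.

    Proportions carry a log-normal mean correction so that the expected
    *ratio* (not the ratio of expectations) hits each group's target.
    """
    noise = default_log_noise_sd()
    corr43 = math.exp(-(noise["sd3"] ** 2 + noise["sd4"] ** 2) / 2.0)
    corr53 = math.exp(-(noise["sd3"] ** 2 + noise["sd5"] ** 2) / 2.0)
    r43, r53 = _ref_mc_ratio_targets()
    return [
        (
            MC3_PROPORTION,
            MC3_PROPORTION * r43[g] * corr43,
            MC3_PROPORTION * r53[g] * corr53,
        )
        for g in range(N_GROUPS)
    ]


def default_mp_proportions() -> list[tuple[float, float]]:
    """Per-group (MP3, MP5) expected length proportions; the group-5/6 step
    in MP5 encodes the upward age trend of the 5:3 MP ratio."""
    noise = default_log_noise_sd()
    corr = math.exp(-(noise["sdMP3"] ** 2 + noise["sdMP5"] ** 2) / 2.0)
    return [
        (MP3_PROPORTION, MP3_PROPORTION * m * corr)
        for m in REF_MP53_GROUP_MEANS
    ]


class GeneratorConfig(BaseModel):
    """All distributional parameters of the synthetic cohorts."""

    model_config = ConfigDict(validate_assignment=True)

    ref_n: int = Field(default=4438, ge=0)
    ts_n: int = Field(default=81, ge=0)
    age_group_weights: tuple[float, float, float, float, float, float] = (
        1 / 6,
    ) * 6
    mc_proportions: list[tuple[float, float, float]] = Field(
        default_factory=default_mc_proportions
    )
    mp_proportions: list[tuple[float, float]] = Field(
        default_factory=default_mp_proportions
    )
    log_noise_sd: dict[str, float] = Field(default_factory=default_log_noise_sd)
    hand_scale_sd: float = Field(default=0.12, gt=0)
    magnification_range: tuple[float, float] = (0.8, 1.25)

    # reference BDA3 tail: (fraction, 5:3 MP ratio mean, ratio SD)
    ref_bda3_tail: tuple[float, float, float] = (0.013, 0.49, 0.008)

    ts_ratio_means: tuple[float, float, float] = TS_RATIO_MEANS
    ts_ratio_sds: tuple[float, float, float] = TS_RATIO_SDS
    ts_mixture: Optional[TsMixture] = None
    # center of the mixture's unaffected component (the reference pooled
    # 4:3 MC mean the mixture was fitted against)
    ts_mixture_mu0: float = REF_R43_MEAN
    # (r43-r53mc, r43-r53mp, r53mc-r53mp); the third pair is unpublished
    ts_correlations: tuple[float, float, float] = (
        TS_CORR_43_53MC,
        TS_CORR_43_53MP,
        0.2,
    )
    # length-level backend couplings for (MC4, MC5, MP5)
    ts_severity_loading: tuple[float, float, float] = (0.054, 0.041, 0.118)
    ts_age_range: tuple[float, float] = TS_AGE_RANGE
    ts_mp_age_slope: float = TS_MP_AGE_SLOPE

    shox_sign_probs: tuple[float, float, float] = (0.333, 0.235, 0.136)
    monosomy_prob: float = Field(default=33 / 81, ge=0, le=1)
    gh_prob: float = Field(default=0.82, ge=0, le=1)

    seed: int = 12061

    @field_validator("age_group_weights")
    @classmethod
    def _weights_sum_to_one(cls, v):
        if any(w < 0 for w in v):
            raise ValueError("age_group_weights must be nonnegative")
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"age_group_weights must sum to 1, got {sum(v)}")
        return v

    @field_validator("log_noise_sd")
    @classmethod
    def _noise_keys(cls, v):
        required = {"sd3", "sd4", "sd5", "sdMP3", "sdMP5"}
        if set(v) != required:
            raise ValueError(f"log_noise_sd must have keys {sorted(required)}")
        if any(s < 0 for s in v.values()):
            raise ValueError("log-noise SDs must be nonnegative")
        return v

    @field_validator("magnification_range")
    @classmethod
    def _mag_range(cls, v):
        lo, hi = v
        if not (0 < lo <= hi):
            raise ValueError("magnification_range must satisfy 0 < min <= max")
        return v

    @field_validator("ts_ratio_sds")
    @classmethod
    def _positive_sds(cls, v):
        if any(s <= 0 for s in v):
            raise ValueError("TS ratio SDs must be strictly positive")
        return v

    @field_validator("shox_sign_probs")
    @classmethod
    def _probs(cls, v):
        if any(not 0 <= p <= 1 for p in v):
            raise ValueError("SHOX sign probabilities must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _mixture_and_tail(self):
        if self.ts_mixture is not None:
            mix = TsMixture(*self.ts_mixture)
            if not 0 <= mix.pi_affected <= 1:
                raise ValueError("mixture pi_affected must lie in [0, 1]")
            if mix.base_sd <= 0:
                raise ValueError("mixture base_sd must be strictly positive")
        frac, mean, sd = self.ref_bda3_tail
        if not 0 <= frac <= 1 or mean <= 0 or sd <= 0:
            raise ValueError("ref_bda3_tail must be (frac in [0,1], mean>0, sd>0)")
        lo, hi = self.ts_age_range
        if not 0 <= lo < hi <= 18:
            raise ValueError("ts_age_range must be within [0, 18] with lo < hi")
        return self


class PipelineConfig(BaseModel):
    """End-to-end pipeline settings: thresholds and the single master seed."""

    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    trim_limit: float = Field(default=2.25, gt=0)
    bda3_threshold: float = 0.5
    mc_sds_threshold: float = -2.0
    fixed_cutoff: float = 0.876  # proposed 4:3 MC diagnostic cut-off
    seed: int = 12061
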