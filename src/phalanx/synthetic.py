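"""Synthetic cohorts with the published statistical structure.

Two populations are emulated so that every downstream stage (measurement,
reference building, screening, ROC) is testable without radiographs:

* a female pediatric *reference* cohort (default n = 4,438) whose pooled
  4:3 MC and 5:3 MC ratio moments, inter-ratio correlation, age-group
  trends and lower 5:3 MP tail match the published reference population;
* a *Turner syndrome* cohort (default n = 81) with the published ratio
  means/SDs, inter-ratio correlations, an affected subgroup in the 4:3 MC
  ratio (the "metacarpal sign" mixture), and clinical metadata (karyotype,
  GH treatment, SHOX-sign annotations, height percentile).

Length model (reference and length-level TS backend): for subject i in age
group g and bone b,

    length_ib = base(age_i) * proportion_gb * exp(h_i + eps_ib) * mag_i

with h_i ~ N(0, hand_scale_sd) a shared hand-size factor, eps_ib per-bone
log-noise, and mag_i a per-film uniform magnification. All three ratios
cancel base, h and mag exactly, so magnification never contaminates the
analysis currency. The multiplicative form guarantees positive lengths and
makes ratio moments analytically tractable for calibration
(see :mod:`phalanx.calibration`).

All randomness flows from ``config.seed`` through named substreams, so
regenerating with one parameter changed (e.g. the magnification range)
leaves every other draw untouched.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bones import AGE_EDGES, BONES, N_GROUPS, RATIOS
from .calibration import (
    TsMixture,
    calibrate_reference_noise,
    fit_ts_mixture as _fit_mixture_core,
    mixture_moments,
    mixture_ppf,
)
from .config import GeneratorConfig
from .errors import ConfigError, NotPositiveDefiniteError
from .measurement import LANDMARK_COLUMNS, LENGTH_COLUMNS, METADATA_COLUMNS

__all__ = [
    "calibrate_reference_noise",
    "fit_ts_mixture",
    "ts_age_group_weights",
    "generate_reference_cohort",
    "generate_ts_cohort",
    "emit_landmarks",
    "write_lengths",
    "write_metadata",
    "write_landmarks",
    "write_ratios_csv",
    "write_config_sidecar",
]

_HP_CORR = 0.27  # target correlation of 4:3 MC latent with height percentile


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Named deterministic substream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _hand_base(age: np.ndarray) -> np.ndarray:
    """Expected hand scale in pixels as a function of bone age (cancels in
    every ratio; only sets a realistic absolute pixel scale)."""
    return 90.0 + 6.0 * age


def ts_age_group_weights(age_range: tuple[float, float]) -> np.ndarray:
    """Age-group occupancy implied by a uniform bone-age distribution."""
    lo, hi = age_range
    overlaps = [
        max(0.0, min(hi, AGE_EDGES[g + 1]) - max(lo, AGE_EDGES[g]))
        for g in range(N_GROUPS)
    ]
    w = np.asarray(overlaps, dtype=float)
    if w.sum() <= 0:
        raise ConfigError(f"age range {age_range} overlaps no age group")
    return w / w.sum()


def fit_ts_mixture(
    target_mean: float,
    target_sd: float,
    target_flag_prev: float,
    reference_table,
    *,
    age_weights: Optional[Sequence[float]] = None,
    age_range: tuple[float, float] = (3.0, 17.9),
    tol: float = 0.02,
) -> TsMixture:
    """Calibrate the affected-subgroup mixture against a reference table.

    The unaffected component is centered at the table's pooled 4:3 MC mean;
    the flag prevalence is evaluated against the age-matched -2 SD
    thresholds of the table's groups, weighted by the TS cohort's age-group
    occupancy (uniform over ``age_range`` unless ``age_weights`` is given).
    """
    mu0 = reference_table.pooled["r43mc"].mean
    thresholds = [
        reference_table.group_stat("r43mc", g).mean
        - 2.0 * reference_table.group_stat("r43mc", g).sd
        for g in range(1, N_GROUPS + 1)
    ]
    if age_weights is None:
        age_weights = ts_age_group_weights(age_range)
    return _fit_mixture_core(
        target_mean, target_sd, target_flag_prev, mu0, thresholds, age_weights,
        tol=tol,
    )


# ---------------------------------------------------------------------------
# reference cohort


def _draw_ages(rng, n: int, weights) -> tuple[np.ndarray, np.ndarray]:
    group = rng.choice(N_GROUPS, size=n, p=np.asarray(weights, float))
    lo = np.asarray(AGE_EDGES[:-1])[group]
    hi = np.asarray(AGE_EDGES[1:])[group]
    age = lo + rng.uniform(size=n) * (hi - lo)
    return group, age


def _reference_metadata(ids, age, group) -> pd.DataFrame:
    n = len(ids)
    na_bool = pd.array([pd.NA] * n, dtype="boolean")
    return pd.DataFrame(
        {
            "subject_id": ids,
            "cohort": "reference",
            "bone_age": np.round(age, 4),
            "age_group": group + 1,
            "karyotype": "unknown",
            "gh_treated": na_bool,
            "height_percentile": np.nan,
            "shox_triangularization": na_bool,
            "shox_lucency": na_bool,
            "shox_pyramidalization": na_bool,
        }
    )[METADATA_COLUMNS]


def generate_reference_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the reference cohort; returns ``(metadata, lengths)``.

    Deterministic given ``config.seed``. The magnification factor lives on
    its own substream, so changing ``magnification_range`` perturbs no
    other draw.
    """
    n = config.ref_n
    if n == 0:
        return (
            pd.DataFrame(columns=METADATA_COLUMNS),
            pd.DataFrame(columns=LENGTH_COLUMNS),
        )
    seed = config.seed
    group, age = _draw_ages(_rng(seed, 0, 0), n, config.age_group_weights)
    hand = _rng(seed, 0, 1).normal(0.0, config.hand_scale_sd, size=n)

    noise = config.log_noise_sd
    eps_mc = _rng(seed, 0, 2).normal(
        0.0, [noise["sd3"], noise["sd4"], noise["sd5"]], size=(n, 3)
    )
    eps_mp = _rng(seed, 0, 3).normal(
        0.0, [noise["sdMP3"], noise["sdMP5"]], size=(n, 2)
    )
    mag = _rng(seed, 0, 4).uniform(*config.magnification_range, size=n)

    base = _hand_base(age) * np.exp(hand)
    mc = base[:, None] * np.asarray(config.mc_proportions)[group] * np.exp(eps_mc)
    mp = base[:, None] * np.asarray(config.mp_proportions)[group] * np.exp(eps_mp)

    # BDA3 tail: a small subpopulation with a congenitally short 5th middle
    # phalanx, concentrated just below the 0.5 ratio threshold
    tail_rng = _rng(seed, 0, 5)
    frac, t_mean, t_sd = config.ref_bda3_tail
    is_tail = tail_rng.uniform(size=n) < frac
    tail_ratio = np.clip(tail_rng.normal(t_mean, t_sd, size=n), 0.05, None)
    mp[is_tail, 1] = mp[is_tail, 0] * tail_ratio[is_tail]

    lengths = np.column_stack([mc, mp]) * mag[:, None]
    ids = [f"REF{i + 1:05d}" for i in range(n)]
    lengths_df = pd.DataFrame(lengths, columns=list(BONES))
    lengths_df.insert(0, "subject_id", ids)
    return _reference_metadata(ids, age, group), lengths_df


# ---------------------------------------------------------------------------
# Turner-syndrome cohort


def _mixture_linearity(mix: TsMixture, mu0: float) -> float:
    """cov(G(Z), Z) / SD(G(Z)) for G the mixture quantile of Phi(Z).

    This is the attenuation a Gaussian copula applies to Pearson
    correlations involving the (possibly bimodal) mixture marginal; the
    latent correlation is inflated by its inverse.
    """
    z = np.linspace(-8.0, 8.0, 4001)
    g = mixture_ppf(stats.norm.cdf(z), mix, mu0)
    cov = np.trapezoid(g * z * stats.norm.pdf(z), z)
    _, sd = mixture_moments(mix, mu0)
    return float(cov / sd)


def _ts_latent_correlation(config: GeneratorConfig, mu0: float) -> np.ndarray:
    """Latent MVN correlation matrix reproducing the target Pearson
    correlations after the marginal transforms."""
    c12, c13, c23 = config.ts_correlations
    lo, hi = config.ts_age_range
    sd_mp = config.ts_ratio_sds[2]
    explained = config.ts_mp_age_slope**2 * (hi - lo) ** 2 / 12.0
    if explained >= sd_mp**2:
        raise ConfigError(
            "ts_mp_age_slope explains more variance than the 5:3 MP ratio has"
        )
    f3 = np.sqrt(sd_mp**2 - explained) / sd_mp
    lin = 1.0
    if config.ts_mixture is not None:
        lin = _mixture_linearity(TsMixture(*config.ts_mixture), mu0)
    rho = np.array(
        [c12 / lin, c13 / (lin * f3), c23 / f3]
    )
    if np.any(np.abs(rho) >= 1.0):
        raise NotPositiveDefiniteError(
            f"latent correlations {rho.round(3).tolist()} leave [-1, 1]; "
            "lower the targets or the marginal distortions"
        )
    r = np.array(
        [[1.0, rho[0], rho[1]], [rho[0], 1.0, rho[2]], [rho[1], rho[2], 1.0]]
    )
    try:
        np.linalg.cholesky(r)
    except np.linalg.LinAlgError:
        raise NotPositiveDefiniteError(
            f"implied latent correlation matrix is not positive definite:\n{r}"
        ) from None
    return r


def _ts_metadata(
    config: GeneratorConfig, ids, age, z1: np.ndarray
) -> pd.DataFrame:
    n = len(ids)
    seed = config.seed
    meta_rng = _rng(seed, 1, 2)
    karyotype = np.where(
        meta_rng.uniform(size=n) < config.monosomy_prob, "monosomy_45X", "other"
    )
    gh = meta_rng.uniform(size=n) < config.gh_prob
    shox = {
        name: meta_rng.uniform(size=n) < p
        for name, p in zip(
            ("shox_triangularization", "shox_lucency", "shox_pyramidalization"),
            config.shox_sign_probs,
        )
    }
    # short stature latent, positively coupled to the 4:3 MC latent
    eps = _rng(seed, 1, 3).normal(size=n)
    latent = _HP_CORR * z1 + np.sqrt(1.0 - _HP_CORR**2) * eps - 1.1
    height_pct = np.round(100.0 * stats.norm.cdf(latent), 2)
    from .bones import assign_age_group

    df = pd.DataFrame(
        {
            "subject_id": ids,
            "cohort": "TS",
            "bone_age": np.round(age, 4),
            "age_group": assign_age_group(age),
            "karyotype": karyotype,
            "gh_treated": pd.array(gh, dtype="boolean"),
            "height_percentile": height_pct,
            **{k: pd.array(v, dtype="boolean") for k, v in shox.items()},
        }
    )
    return df[METADATA_COLUMNS]


def generate_ts_cohort(
    config: GeneratorConfig, backend: str = "ratio_level"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the TS cohort; returns ``(metadata, ratios_or_lengths)``.

    ``ratio_level`` draws the three ratios directly from a Gaussian copula
    with the published means/SDs and correlations, substituting the fitted
    affected-subgroup mixture for the 4:3 MC marginal when
    ``config.ts_mixture`` is set — highest calibration fidelity, no
    lengths. ``length_level`` reuses the reference length model plus a
    shared latent "severity" deficit on MC4, MC5 and MP5 — supports the
    landmark round trip. Deterministic given ``config.seed``.
    """
    if backend not in ("ratio_level", "length_level"):
        raise ConfigError(f"unknown TS backend {backend!r}")
    n = config.ts_n
    if n == 0:
        cols = (
            ["subject_id", *RATIOS] if backend == "ratio_level" else LENGTH_COLUMNS
        )
        return pd.DataFrame(columns=METADATA_COLUMNS), pd.DataFrame(columns=cols)

    seed = config.seed
    lo, hi = config.ts_age_range
    age = _rng(seed, 1, 0).uniform(lo, hi, size=n)
    ids = [f"TS{i + 1:04d}" for i in range(n)]
    means, sds = config.ts_ratio_means, config.ts_ratio_sds
    mu0 = config.ts_mixture_mu0

    if backend == "ratio_level":
        r_latent = _ts_latent_correlation(config, mu0)
        chol = np.linalg.cholesky(r_latent)
        z = _rng(seed, 1, 1).normal(size=(n, 3)) @ chol.T
        if config.ts_mixture is not None:
            mix = TsMixture(*config.ts_mixture)
            r43 = mixture_ppf(stats.norm.cdf(z[:, 0]), mix, mu0)
        else:
            r43 = means[0] + sds[0] * z[:, 0]
        r53mc = means[1] + sds[1] * z[:, 1]
        explained = config.ts_mp_age_slope**2 * (hi - lo) ** 2 / 12.0
        sd_resid = np.sqrt(sds[2] ** 2 - explained)
        r53mp = (
            means[2]
            + config.ts_mp_age_slope * (age - (lo + hi) / 2.0)
            + sd_resid * z[:, 2]
        )
        data = pd.DataFrame(
            {
                "subject_id": ids,
                "r43mc": np.clip(r43, 1e-6, None),
                "r53mc": np.clip(r53mc, 1e-6, None),
                "r53mp": np.clip(r53mp, 1e-6, None),
            }
        )
        z1 = z[:, 0]
    else:
        noise = config.log_noise_sd
        draws = _rng(seed, 1, 1)
        hand = draws.normal(0.0, config.hand_scale_sd, size=n)
        eps_mc = draws.normal(
            0.0, [noise["sd3"], noise["sd4"], noise["sd5"]], size=(n, 3)
        )
        eps_mp = draws.normal(0.0, [noise["sdMP3"], noise["sdMP5"]], size=(n, 2))
        severity = _rng(seed, 1, 4).normal(size=n)
        mag = _rng(seed, 1, 5).uniform(*config.magnification_range, size=n)

        lam4, lam5, lamp5 = config.ts_severity_loading
        # per-subject 5:3 MP target follows the TS age trend
        mp_target = means[2] + config.ts_mp_age_slope * (age - (lo + hi) / 2.0)
        p3, pmp3 = config.mc_proportions[0][0], config.mp_proportions[0][0]
        corr = lambda a, b, lam: np.exp(-(a**2 + b**2 + lam**2) / 2.0)
        p4 = p3 * means[0] * corr(noise["sd3"], noise["sd4"], lam4)
        p5 = p3 * means[1] * corr(noise["sd3"], noise["sd5"], lam5)
        pmp5 = pmp3 * mp_target * corr(noise["sdMP3"], noise["sdMP5"], lamp5)

        base = _hand_base(age) * np.exp(hand)
        mc3 = base * p3 * np.exp(eps_mc[:, 0])
        mc4 = base * p4 * np.exp(eps_mc[:, 1] - lam4 * severity)
        mc5 = base * p5 * np.exp(eps_mc[:, 2] - lam5 * severity)
        mp3 = base * pmp3 * np.exp(eps_mp[:, 0])
        mp5 = base * pmp5 * np.exp(eps_mp[:, 1] - lamp5 * severity)
        lengths = np.column_stack([mc3, mc4, mc5, mp3, mp5]) * mag[:, None]
        data = pd.DataFrame(lengths, columns=list(BONES))
        data.insert(0, "subject_id", ids)
        z1 = eps_mc[:, 1] - lam4 * severity
        z1 = (z1 - z1.mean()) / (z1.std() or 1.0)

    return _ts_metadata(config, ids, age, z1), data


# ---------------------------------------------------------------------------
# landmarks


def emit_landmarks(lengths: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Inverse of the measurement convention, for round-trip testing.

    For every (subject, bone), place the base midpoint at a pseudo-random
    image position with a pseudo-random orientation, and put the head
    midpoint at exactly the stated length.
    """
    vals = lengths[list(BONES)].to_numpy(float)
    if np.any(~(vals > 0)):
        raise ConfigError("emit_landmarks requires strictly positive lengths")
    n = len(lengths)
    rng = _rng(seed, 2, 0)
    base = rng.uniform(200.0, 800.0, size=(n, len(BONES), 2))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(n, len(BONES)))
    head_x = base[:, :, 0] + vals * np.cos(theta)
    head_y = base[:, :, 1] + vals * np.sin(theta)
    rows = pd.DataFrame(
        {
            "subject_id": np.repeat(lengths["subject_id"].to_numpy(), len(BONES)),
            "bone": np.tile(BONES, n),
            "base_x": base[:, :, 0].ravel(),
            "base_y": base[:, :, 1].ravel(),
            "head_x": head_x.ravel(),
            "head_y": head_y.ravel(),
        }
    )
    return rows[LANDMARK_COLUMNS]


# ---------------------------------------------------------------------------
# writers (comma-separated, '.' decimal, UTF-8; deterministic byte output)

_BOOL_OUT = {True: "true", False: "false"}


def write_lengths(lengths: pd.DataFrame, path) -> None:
    lengths[LENGTH_COLUMNS].to_csv(path, index=False)


def write_landmarks(landmarks: pd.DataFrame, path) -> None:
    landmarks[LANDMARK_COLUMNS].to_csv(path, index=False)


def write_ratios_csv(ratios: pd.DataFrame, path) -> None:
    ratios[["subject_id", *RATIOS]].to_csv(path, index=False)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata[METADATA_COLUMNS].copy()
    for col in (
        "gh_treated",
        "shox_triangularization",
        "shox_lucency",
        "shox_pyramidalization",
    ):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else _BOOL_OUT[bool(v)])
    out["height_percentile"] = out["height_percentile"].map(
        lambda v: "" if pd.isna(v) else repr(float(v))
    )
    out.to_csv(path, index=False)


def write_config_sidecar(config, path) -> None:
    """Echo the full configuration (including seed) next to the outputs."""
    Path(path).write_text(
        json.dumps(config.model_dump(mode="json"), indent=1, sort_keys=True)
    )
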