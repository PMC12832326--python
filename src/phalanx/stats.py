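"""Statistical toolkit: ROC/AUC, Youden cut-off, correlations, ANOVA.

Orientation is fixed globally for ROC analysis: a LOWER ratio indicates
the TS-like (diseased) class, so AUC > 0.5 means the ratio discriminates
in the clinically expected direction. Sensitivity at a cutoff c is the
fraction of TS values strictly below c; specificity is the fraction of
reference values at or above c (a value exactly at the cutoff counts as
negative). These conventions make every reported number bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import PhalanxError, UndefinedCorrelationError


@dataclass
class ROCResult:
    """AUC with DeLong CI plus the Youden-optimal operating point."""

    auc: float
    auc_ci_low: float
    auc_ci_high: float
    youden_cutoff: float
    youden_j: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    orientation: str = "lower ratio indicates TS"

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci_low": self.auc_ci_low,
            "auc_ci_high": self.auc_ci_high,
            "youden_cutoff": self.youden_cutoff,
            "youden_j": self.youden_j,
            "sens_at_cutoff": self.sens_at_cutoff,
            "spec_at_cutoff": self.spec_at_cutoff,
            "orientation": self.orientation,
        }


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    adjusted_for: Optional[str] = None


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    #: Scheffé-adjusted p per group pair, keyed by (i, j) with i < j
    pairwise_p: dict


def _validate_samples(reference_values, ts_values):
    ref = np.asarray(reference_values, dtype=float)
    ts = np.asarray(ts_values, dtype=float)
    if ref.size == 0 or ts.size == 0:
        raise PhalanxError("both samples must be non-empty")
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(ts))):
        raise PhalanxError("samples must be finite")
    return ref, ts


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _auc_and_delong_variance(ref: np.ndarray, ts: np.ndarray):
    """Mann-Whitney AUC and its DeLong variance.

    Internally scores are negated ratios so that higher score = more
    TS-like; AUC = P(ts < ref) + 0.5 P(ts = ref).
    """
    x = -ts  # diseased scores
    y = -ref  # control scores
    m, n = x.size, y.size
    tz = _midrank(np.concatenate([x, y]))
    tx = _midrank(x)
    ty = _midrank(y)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # structural components over diseased
    v10 = 1.0 - (tz[m:] - ty) / m  # over controls
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return float(auc), s01 / m + s10 / n


def empirical_auc(
    reference_values, ts_values, *, alpha: float = 0.05
) -> tuple[float, float, float]:
    """AUC (pairwise concordance, ties 1/2) with a DeLong Wald CI.

    Returns ``(auc, ci_low, ci_high)``; the CI is clipped to [0, 1].
    """
    ref, ts = _validate_samples(reference_values, ts_values)
    auc, var = _auc_and_delong_variance(ref, ts)
    half = stats.norm.ppf(1.0 - alpha / 2.0) * math.sqrt(max(var, 0.0))
    return auc, max(0.0, auc - half), min(1.0, auc + half)


def binormal_auc(mu_ref: float, sd_ref: float, mu_ts: float, sd_ts: float) -> float:
    """Closed-form AUC when both classes are normal:
    Phi((mu_ref - mu_ts) / sqrt(sd_ref^2 + sd_ts^2))."""
    if sd_ref <= 0 or sd_ts <= 0:
        raise PhalanxError("binormal AUC requires strictly positive SDs")
    return float(stats.norm.cdf((mu_ref - mu_ts) / math.hypot(sd_ref, sd_ts)))


def _sens_spec_empirical(cutoff, ref_sorted, ts_sorted):
    sens = np.searchsorted(ts_sorted, cutoff, side="left") / ts_sorted.size
    spec = (
        ref_sorted.size - np.searchsorted(ref_sorted, cutoff, side="left")
    ) / ref_sorted.size
    return sens, spec


def youden_cutoff(
    reference_values, ts_values
) -> tuple[float, float, float, float]:
    """Youden-optimal cutoff: returns ``(cutoff, J, sens, spec)``.

    Candidates are midpoints between adjacent distinct pooled values;
    J(c) = sens(c) + spec(c) - 1. Ties on J break to the smallest cutoff.
    """
    ref, ts = _validate_samples(reference_values, ts_values)
    pooled = np.unique(np.concatenate([ref, ts]))
    if pooled.size == 1:
        # all values identical: J = 0 everywhere; report the single value
        return float(pooled[0]), 0.0, 0.0, 1.0
    candidates = (pooled[:-1] + pooled[1:]) / 2.0
    ref_s, ts_s = np.sort(ref), np.sort(ts)
    sens = np.searchsorted(ts_s, candidates, side="left") / ts.size
    spec = (ref.size - np.searchsorted(ref_s, candidates, side="left")) / ref.size
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (smallest) maximizer
    return float(candidates[best]), float(j[best]), float(sens[best]), float(spec[best])


def sens_spec_at(
    cutoff: float,
    reference_values=None,
    ts_values=None,
    *,
    ref_moments: Optional[tuple[float, float]] = None,
    ts_moments: Optional[tuple[float, float]] = None,
) -> tuple[float, float]:
    """Sensitivity/specificity at a fixed cutoff, empirical or analytic.

    Empirical mode: pass both sample arrays. Analytic mode: pass
    ``ref_moments=(mu, sd)`` and ``ts_moments=(mu, sd)``; normal CDF tails
    replace the empirical fractions.
    """
    if ref_moments is not None and ts_moments is not None:
        mu_t, sd_t = ts_moments
        mu_r, sd_r = ref_moments
        if sd_t <= 0 or sd_r <= 0:
            raise PhalanxError("analytic mode requires strictly positive SDs")
        sens = float(stats.norm.cdf((cutoff - mu_t) / sd_t))
        spec = float(1.0 - stats.norm.cdf((cutoff - mu_r) / sd_r))
        return sens, spec
    ref, ts = _validate_samples(reference_values, ts_values)
    sens, spec = _sens_spec_empirical(cutoff, np.sort(ref), np.sort(ts))
    return float(sens), float(spec)


def roc_analysis(reference_values, ts_values) -> ROCResult:
    """Full ROC summary: AUC + DeLong CI + Youden operating point."""
    auc, lo, hi = empirical_auc(reference_values, ts_values)
    cut, j, sens, spec = youden_cutoff(reference_values, ts_values)
    return ROCResult(auc, lo, hi, cut, j, sens, spec)


# ---------------------------------------------------------------------------
# correlations


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with its two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise PhalanxError("pearson requires equal-length samples with n >= 3")
    if x.std() == 0.0 or y.std() == 0.0:
        raise UndefinedCorrelationError("a variable has zero variance")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


def partial_correlation(x, y, covariate, name: str = "covariate") -> CorrelationResult:
    """Correlation of x and y after removing a linear covariate effect.

    Both variables are regressed on the covariate; the Pearson correlation
    of the residuals is returned with a t-based p-value on n - 3 df.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    c = np.asarray(covariate, float)
    n = x.size
    if not (y.size == n and c.size == n) or n < 4:
        raise PhalanxError("partial correlation requires n >= 4")
    if c.std() == 0.0:
        raise UndefinedCorrelationError("covariate has zero variance")
    design = np.column_stack([np.ones(n), c])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    # near-zero residual variance (e.g. x or y collinear with the
    # covariate) leaves the correlation numerically undefined
    if rx.std() <= 1e-10 * x.std() or ry.std() <= 1e-10 * y.std():
        raise UndefinedCorrelationError(
            "zero residual variance after removing the covariate"
        )
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    t = r * math.sqrt(df / max(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(r, float(p), n, adjusted_for=name)


# ---------------------------------------------------------------------------
# group comparisons


def _maybe_log(values: np.ndarray, log_transform: bool) -> np.ndarray:
    if not log_transform:
        return values
    if np.any(values <= 0.0):
        raise PhalanxError("log transform requires strictly positive values")
    return np.log(values)


def anova_scheffe(groups, log_transform: bool = False) -> AnovaResult:
    """One-way ANOVA with Scheffé-adjusted pairwise comparisons.

    The pairwise statistic is
    F_pair = (mean_i - mean_j)^2 / (MSW (1/n_i + 1/n_j) (k - 1))
    referred to F(k-1, N-k); it is conservative relative to the
    unadjusted pairwise contrast. ``log_transform`` tests log(values)
    instead; the ratios are near-symmetric, so it is off by default.
    """
    samples = [_maybe_log(np.asarray(g, float), log_transform) for g in groups]
    k = len(samples)
    if k < 2 or any(s.size < 2 for s in samples):
        raise PhalanxError("anova requires >= 2 groups with n >= 2 each")
    ns = np.array([s.size for s in samples])
    means = np.array([s.mean() for s in samples])
    n_total = int(ns.sum())
    df_b, df_w = k - 1, n_total - k
    msw = sum((s.size - 1) * s.var(ddof=1) for s in samples) / df_w

    if msw == 0.0:
        # degenerate: no within-group spread at all
        equal = np.allclose(means, means[0])
        f = 0.0 if equal else math.inf
        p = 1.0 if equal else 0.0
        pairwise = {
            (i, j): 1.0 if means[i] == means[j] else 0.0
            for i in range(k)
            for j in range(i + 1, k)
        }
        return AnovaResult(f, df_b, df_w, p, pairwise)

    f, p = stats.f_oneway(*samples)
    pairwise = {}
    for i in range(k):
        for j in range(i + 1, k):
            f_pair = (means[i] - means[j]) ** 2 / (
                msw * (1.0 / ns[i] + 1.0 / ns[j]) * df_b
            )
            pairwise[(i, j)] = float(stats.f.sf(f_pair, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, float(p), pairwise)


def two_sample_t(
    x, y, variant: str = "student", log_transform: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t-test; ``student`` (pooled) or ``welch``."""
    x = _maybe_log(np.asarray(x, float), log_transform)
    y = _maybe_log(np.asarray(y, float), log_transform)
    if x.size < 2 or y.size < 2:
        raise PhalanxError("t-test requires n >= 2 per sample")
    if variant not in ("student", "welch"):
        raise PhalanxError(f"unknown t-test variant {variant!r}")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return math.inf, 0.0
    res = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)
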