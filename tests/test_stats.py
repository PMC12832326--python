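"""ROC/AUC, Youden cut-off, correlations, ANOVA and t-test behavior.

Brute-force oracles (exhaustive pair enumeration, full threshold scans)
check the vectorized implementations on small samples.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phalanx.errors import PhalanxError, UndefinedCorrelationError
from phalanx.stats import (
    anova_scheffe,
    binormal_auc,
    empirical_auc,
    partial_correlation,
    pearson,
    roc_analysis,
    sens_spec_at,
    two_sample_t,
    youden_cutoff,
)


def brute_force_auc(ref, ts):
    """P(ts < ref) + 0.5 P(ts == ref) over all pairs."""
    wins = sum(
        1.0 if t < r else (0.5 if t == r else 0.0)
        for t, r in itertools.product(ts, ref)
    )
    return wins / (len(ref) * len(ts))


samples = st.lists(
    st.integers(0, 20).map(lambda v: v / 10.0), min_size=1, max_size=50
)


class TestEmpiricalAuc:
    def test_small_example(self):
        auc, _, _ = empirical_auc([2, 3, 4], [1, 2.5])
        assert auc == pytest.approx(5 / 6)

    @given(ref=samples, ts=samples)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_equals_pairwise_concordance_oracle(self, ref, ts):
        auc, _, _ = empirical_auc(ref, ts)
        assert auc == pytest.approx(brute_force_auc(ref, ts), abs=1e-12)

    def test_null_case_near_half(self, rng):
        a = rng.normal(size=10_000)
        b = rng.normal(size=10_000)
        auc, lo, hi = empirical_auc(a, b)
        assert auc == pytest.approx(0.5, abs=0.02)
        assert lo <= auc <= hi

    def test_perfect_separation(self):
        auc, _, _ = empirical_auc([5, 6, 7], [1, 2])
        assert auc == 1.0

    def test_identical_constants_give_half(self):
        auc, _, _ = empirical_auc([1.0] * 5, [1.0] * 7)
        assert auc == 0.5

    def test_matches_binormal_at_large_n(self, rng):
        n = 50_000
        ref = rng.normal(0.889, 0.019, n)
        ts = rng.normal(0.860, 0.050, n)
        expected = binormal_auc(0.889, 0.019, 0.860, 0.050)
        auc, _, _ = empirical_auc(ref, ts)
        # 3 Monte-Carlo SEs of the Mann-Whitney estimator
        se = math.sqrt(expected * (1 - expected) * (2 / n))
        assert abs(auc - expected) < max(3 * se, 0.005)

    def test_invariant_under_decreasing_transform(self, rng):
        ref = rng.normal(0.9, 0.02, 300)
        ts = rng.normal(0.85, 0.05, 80)
        auc1, _, _ = empirical_auc(ref, ts)
        auc2, _, _ = empirical_auc(np.exp(-ref), np.exp(-ts))
        # a strictly decreasing transform flips the orientation
        assert auc2 == pytest.approx(1.0 - auc1, abs=1e-12)

    def test_delong_ci_covers_truth_reasonably(self, rng):
        hits = 0
        truth = binormal_auc(0.0, 1.0, -1.0, 1.0)
        reps = 200
        for _ in range(reps):
            ref = rng.normal(0.0, 1.0, 60)
            ts = rng.normal(-1.0, 1.0, 40)
            _, lo, hi = empirical_auc(ref, ts)
            hits += lo <= truth <= hi
        assert hits / reps > 0.85


class TestBinormalAuc:
    def test_printed_moment_values(self):
        assert binormal_auc(0.889, 0.019, 0.860, 0.050) == pytest.approx(
            0.706, abs=0.001
        )
        assert binormal_auc(0.822, 0.022, 0.820, 0.040) == pytest.approx(
            0.518, abs=0.001
        )

    def test_equal_means_is_half(self):
        assert binormal_auc(0.8, 0.02, 0.8, 0.05) == 0.5

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(PhalanxError):
            binormal_auc(0.8, 0.0, 0.7, 0.05)


def brute_force_youden(ref, ts):
    """All (midpoint, exact Youden J) pairs, J in exact rational arithmetic."""
    pooled = sorted(set(ref) | set(ts))
    out = []
    for a, b in zip(pooled[:-1], pooled[1:]):
        c = (a + b) / 2.0
        sens = Fraction(sum(t < c for t in ts), len(ts))
        spec = Fraction(sum(r >= c for r in ref), len(ref))
        out.append((c, sens + spec - 1))
    return out


class TestYouden:
    def test_midpoint_example(self):
        cut, j, sens, spec = youden_cutoff([0.90, 0.92], [0.80, 0.86])
        assert cut == pytest.approx(0.88)
        assert j == 1.0 and sens == 1.0 and spec == 1.0

    def test_identical_samples_zero_j_smallest_midpoint(self):
        vals = [0.8, 0.85, 0.9]
        cut, j, _, _ = youden_cutoff(vals, vals)
        assert j == pytest.approx(0.0)
        assert cut == pytest.approx(0.825)

    @given(ref=samples, ts=samples)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_beats_every_scanned_midpoint(self, ref, ts):
        if len(set(ref) | set(ts)) < 2:
            return
        cut, j, sens, spec = youden_cutoff(ref, ts)
        scan = brute_force_youden(ref, ts)
        jmax = max(je for _, je in scan)
        # the chosen cut-off attains the exact maximum J
        assert j == pytest.approx(float(jmax), abs=1e-12)
        winners = [c for c, je in scan if je == jmax]
        assert any(cut == pytest.approx(c, abs=1e-12) for c in winners)
        assert j == pytest.approx(sens + spec - 1.0, abs=1e-12)


class TestSensSpecAt:
    def test_analytic_at_proposed_cutoff(self):
        sens, spec = sens_spec_at(
            0.876, ref_moments=(0.889, 0.019), ts_moments=(0.860, 0.050)
        )
        assert sens == pytest.approx(0.626, abs=0.002)
        assert spec == pytest.approx(0.753, abs=0.002)

    def test_extreme_cutoffs(self):
        ref, ts = [2.0, 3.0], [1.0, 1.5]
        assert sens_spec_at(0.5, ref, ts) == (0.0, 1.0)
        assert sens_spec_at(10.0, ref, ts) == (1.0, 0.0)

    def test_value_at_cutoff_counts_as_negative(self):
        sens, spec = sens_spec_at(2.0, [2.0, 3.0], [2.0, 1.0])
        assert sens == 0.5  # the ts value at the cutoff is not called
        assert spec == 1.0  # the ref value at the cutoff stays negative


class TestRocAnalysis:
    def test_invariants_of_result(self, rng):
        ref = rng.normal(0.889, 0.019, 500)
        ts = rng.normal(0.860, 0.050, 100)
        res = roc_analysis(ref, ts)
        assert res.auc_ci_low <= res.auc <= res.auc_ci_high
        assert res.youden_j == pytest.approx(
            res.sens_at_cutoff + res.spec_at_cutoff - 1.0
        )
        assert res.orientation == "lower ratio indicates TS"


class TestCorrelations:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 1e-10

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_partial_on_covariate_itself_undefined(self, rng):
        c = rng.normal(size=50)
        with pytest.raises(UndefinedCorrelationError):
            partial_correlation(c, rng.normal(size=50), c)

    def test_partial_removes_common_driver(self, rng):
        n = 10_000
        c = rng.normal(size=n)
        x = 0.8 * c + rng.normal(size=n)
        y = -0.5 * c + rng.normal(size=n)
        raw = pearson(x, y)
        part = partial_correlation(x, y, c)
        assert abs(raw.r) > 0.15
        assert abs(part.r) < 0.03

    def test_partial_matches_pingouin(self, rng):
        import pandas as pd

        n = 200
        c = rng.normal(size=n)
        x = 0.5 * c + rng.normal(size=n)
        y = 0.3 * c + rng.normal(size=n)
        ours = partial_correlation(x, y, c)
        ref = pg.partial_corr(
            data=pd.DataFrame({"x": x, "y": y, "c": c}), x="x", y="y", covar="c"
        )
        assert ours.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert ours.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)


class TestAnovaScheffe:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        res = anova_scheffe([g, g, g])
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert all(p == pytest.approx(1.0) for p in res.pairwise_p.values())

    def test_two_groups_f_equals_t_squared(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.3, 1, 35)
        res = anova_scheffe([x, y])
        t, _ = two_sample_t(x, y, "student")
        assert res.f_statistic == pytest.approx(t**2, rel=1e-10)
        # with k=2 the Scheffé pairwise p equals the overall p
        assert res.pairwise_p[(0, 1)] == pytest.approx(res.p_value, rel=1e-10)

    def test_shifted_group_detected_against_all_others(self, rng):
        pooled_sd = 1.0
        groups = [rng.normal(0.0, pooled_sd, 200) for _ in range(5)]
        groups.append(rng.normal(-2.0 * pooled_sd, pooled_sd, 200))
        res = anova_scheffe(groups)
        for i in range(5):
            assert res.pairwise_p[(i, 5)] < 0.001

    def test_scheffe_is_conservative(self, rng):
        """Scheffé pairwise p >= unadjusted pairwise contrast p."""
        groups = [rng.normal(m, 1, 30) for m in (0.0, 0.2, 0.5, 0.1)]
        res = anova_scheffe(groups)
        ns = [len(g) for g in groups]
        means = [g.mean() for g in groups]
        msw = sum((len(g) - 1) * g.var(ddof=1) for g in groups) / (
            sum(ns) - len(groups)
        )
        for (i, j), p_scheffe in res.pairwise_p.items():
            f_unadj = (means[i] - means[j]) ** 2 / (
                msw * (1 / ns[i] + 1 / ns[j])
            )
            p_unadj = stats.f.sf(f_unadj, 1, sum(ns) - len(groups))
            assert p_scheffe >= p_unadj - 1e-12

    def test_degenerate_zero_within_variance(self):
        res = anova_scheffe([[1.0, 1.0], [2.0, 2.0]])
        assert res.p_value == 0.0
        res_eq = anova_scheffe([[1.0, 1.0], [1.0, 1.0]])
        assert res_eq.p_value == 1.0


class TestTwoSampleT:
    def test_identical_samples(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_large_shift_significant(self, rng):
        x = rng.normal(size=100)
        t, p = two_sample_t(x + 100.0, x)
        assert p < 1e-10

    def test_zero_variance_equal_means(self):
        assert two_sample_t([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_log_transform_flag(self, rng):
        """log_transform=True must equal testing log(values); it refuses
        nonpositive data."""
        x = np.exp(rng.normal(0, 0.3, 50))
        y = np.exp(rng.normal(0.2, 0.3, 50))
        assert two_sample_t(x, y, log_transform=True) == pytest.approx(
            two_sample_t(np.log(x), np.log(y))
        )
        res = anova_scheffe([x, y], log_transform=True)
        assert res.f_statistic == pytest.approx(
            anova_scheffe([np.log(x), np.log(y)]).f_statistic
        )
        with pytest.raises(PhalanxError):
            two_sample_t([1.0, -1.0, 2.0], [1.0, 2.0, 3.0], log_transform=True)

    def test_type_one_error_rate_under_null(self, rng):
        reps, n = 2000, 30
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        res = stats.ttest_ind(x, y, axis=1)
        # sanity of the simulation itself
        assert (res.pvalue < 0.05).mean() == pytest.approx(0.05, abs=0.02)
        # spot-check our wrapper against scipy on a handful of rows
        for i in range(5):
            t, p = two_sample_t(x[i], y[i], "student")
            assert t == pytest.approx(float(res.statistic[i]))
            assert p == pytest.approx(float(res.pvalue[i]))
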