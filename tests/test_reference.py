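"""Age groups, trimming rule, reference table and distribution diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phalanx.bones import N_GROUPS, assign_age_group
from phalanx.errors import AgeRangeError, PhalanxError, UnavailableGroupError
from phalanx.reference import (
    ReferenceTable,
    build_reference,
    distribution_diagnostics,
    trim_outliers,
)


class TestAssignAgeGroup:
    @pytest.mark.parametrize(
        "age,group",
        [
            (0.0, 1),
            (5.9, 1),
            (6.0, 2),
            (7.99, 2),
            (8.0, 3),
            (10.9, 3),
            (11.0, 4),
            (13.0, 5),
            (14.99, 5),
            (15.0, 6),
            (17.9, 6),
            (18.0, 6),
        ],
    )
    def test_bin_boundaries(self, age, group):
        assert assign_age_group(age) == group

    @pytest.mark.parametrize("age", [-0.1, 18.01, float("nan")])
    def test_out_of_range(self, age):
        with pytest.raises(AgeRangeError):
            assign_age_group(age)


def _iid_normal_ratios(n, rng):
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "r43mc": rng.normal(0.889, 0.019, n),
            "r53mc": rng.normal(0.822, 0.022, n),
            "r53mp": rng.normal(0.62, 0.055, n),
        }
    )


class TestTrimOutliers:
    def test_union_rule_retention_on_independent_normals(self, rng):
        """Per ratio, 2*(1-Phi(2.25)) ~ 2.44% fall outside; with three
        independent ratios the union rule retains ~0.9756^3 = 92.85%."""
        ratios = _iid_normal_ratios(10_000, rng)
        retained, report = trim_outliers(ratios, 2.25)
        expected = (2 * stats.norm.cdf(2.25) - 1) ** 3
        assert report.n_retained / report.n_input == pytest.approx(
            expected, abs=0.01
        )
        assert report.n_retained + report.n_excluded_total == report.n_input
        assert report.n_excluded_total <= sum(
            report.n_excluded_per_ratio.values()
        )
        assert len(retained) == report.n_retained

    def test_single_pass_uses_input_moments_only(self, rng):
        """Decisions depend only on the input-sample moments: re-trimming
        manually with the ORIGINAL moments reproduces the retained set,
        even though the retained sample's own moments differ."""
        ratios = _iid_normal_ratios(5_000, rng)
        retained, _ = trim_outliers(ratios, 2.25)
        keep = np.ones(len(ratios), dtype=bool)
        for col in ("r43mc", "r53mc", "r53mp"):
            v = ratios[col].to_numpy(float)
            z = (v - v.mean()) / v.std(ddof=1)
            keep &= ~(np.abs(z) > 2.25)
        pd.testing.assert_frame_equal(
            retained, ratios[keep].reset_index(drop=True)
        )

    def test_degenerate_distribution_guard(self):
        ratios = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(20)],
                "r43mc": 0.889,
                "r53mc": 0.822,
                "r53mp": 0.62,
            }
        )
        retained, report = trim_outliers(ratios)
        assert report.n_excluded_total == 0
        assert len(retained) == 20

    def test_boundary_subject_exactly_at_limit_is_retained(self, rng):
        """Strict inequality: |z| == trim_limit is kept, anything beyond
        goes. Realized by setting the limit to the sample's exact max |z|."""
        ratios = _iid_normal_ratios(200, rng)
        def col_zmax(c):
            v = ratios[c].to_numpy(float)
            return float(np.abs((v - v.mean()) / v.std(ddof=1)).max())

        zmax = max(col_zmax(c) for c in ("r43mc", "r53mc", "r53mp"))
        _, at_limit = trim_outliers(ratios, trim_limit=zmax)
        assert at_limit.n_excluded_total == 0
        _, below_limit = trim_outliers(ratios, trim_limit=zmax * (1 - 1e-12))
        assert below_limit.n_excluded_total >= 1

    def test_minimum_sample_size(self, rng):
        with pytest.raises(PhalanxError):
            trim_outliers(_iid_normal_ratios(5, rng))


class TestBuildReference:
    def test_two_group_hand_arithmetic(self):
        ratios = pd.DataFrame(
            {
                "subject_id": ["A", "B", "C", "D"],
                "r43mc": [0.8, 0.9, 0.8, 0.9],
                "r53mc": [0.8, 0.9, 0.8, 0.9],
                "r53mp": [0.8, 0.9, 0.8, 0.9],
            }
        )
        metadata = pd.DataFrame(
            {"subject_id": ["A", "B", "C", "D"], "bone_age": [3.0, 3.0, 9.0, 9.0]}
        )
        table = build_reference(ratios, metadata)
        for g in (1, 3):
            gs = table.group_stat("r43mc", g)
            assert gs.mean == pytest.approx(0.85)
            assert gs.sd == pytest.approx(0.0707, abs=1e-3)
            assert gs.n == 2

    def test_order_invariance(self, reference_build):
        table, _, retained, meta = reference_build
        shuffled = retained.sample(frac=1.0, random_state=0).reset_index(drop=True)
        table2 = build_reference(shuffled, meta, table.trim_limit)
        for ratio in ("r43mc", "r53mc", "r53mp"):
            for g in range(1, N_GROUPS + 1):
                a, b = table.group_stat(ratio, g), table2.group_stat(ratio, g)
                assert a.mean == pytest.approx(b.mean, abs=1e-12)
                assert a.sd == pytest.approx(b.sd, abs=1e-12)

    def test_pooled_mean_matches_calibration_after_trim(self, reference_table):
        assert reference_table.pooled["r43mc"].mean == pytest.approx(
            0.889, abs=0.002
        )
        assert reference_table.pooled["r43mc"].n == sum(
            reference_table.groups["r43mc"][g].n for g in range(1, 7)
        )

    def test_group6_mc_dip_and_group56_mp_step(self, reference_table):
        for ratio in ("r43mc", "r53mc"):
            means = [
                reference_table.group_stat(ratio, g).mean for g in range(1, 7)
            ]
            assert all(means[5] < m for m in means[:5])
        mp = [reference_table.group_stat("r53mp", g).mean for g in range(1, 7)]
        assert min(mp[4:]) > max(mp[:4])

    def test_json_round_trip_exact(self, tmp_path, reference_table):
        path = tmp_path / "ref.json"
        reference_table.to_json(path)
        back = ReferenceTable.from_json(path)
        assert back.trim_limit == reference_table.trim_limit
        for ratio in ("r43mc", "r53mc", "r53mp"):
            for g in range(1, N_GROUPS + 1):
                a = reference_table.group_stat(ratio, g)
                b = back.group_stat(ratio, g)
                assert abs(a.mean - b.mean) <= 1e-12
                assert abs(a.sd - b.sd) <= 1e-12

    def test_small_group_has_unusable_sd(self):
        ratios = pd.DataFrame(
            {
                "subject_id": ["A", "B", "C"],
                "r43mc": [0.8, 0.9, 0.85],
                "r53mc": [0.8, 0.9, 0.85],
                "r53mp": [0.8, 0.9, 0.85],
            }
        )
        metadata = pd.DataFrame(
            {"subject_id": ["A", "B", "C"], "bone_age": [3.0, 3.0, 16.0]}
        )
        table = build_reference(ratios, metadata)
        with pytest.raises(UnavailableGroupError):
            table.group_stat("r43mc", 6)  # n = 1
        with pytest.raises(UnavailableGroupError):
            table.group_stat("r43mc", 2)  # n = 0


class TestDistributionDiagnostics:
    def test_normal_sample_near_zero(self, rng):
        d = distribution_diagnostics(rng.normal(size=100_000))
        assert d.skewness == pytest.approx(0.0, abs=0.02)
        assert d.excess_kurtosis == pytest.approx(0.0, abs=0.05)

    def test_exponential_sample_skewness_two(self, rng):
        d = distribution_diagnostics(rng.exponential(size=100_000))
        assert d.skewness == pytest.approx(2.0, abs=0.1)

    def test_reference_ratios_are_near_normal(self, reference_build):
        _, _, retained, _ = reference_build
        for ratio in ("r43mc", "r53mc"):
            d = distribution_diagnostics(retained[ratio])
            assert abs(d.skewness) < 0.25
            assert abs(d.excess_kurtosis) < 0.6

    def test_constant_or_tiny_samples_rejected(self):
        with pytest.raises(PhalanxError):
            distribution_diagnostics([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(PhalanxError):
            distribution_diagnostics([1.0, 2.0, 3.0])
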