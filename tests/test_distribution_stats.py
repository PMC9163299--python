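import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import dip_brute_force
from prebotpy.distribution_stats import (
    ModeEstimate,
    burstlet_consistency_check,
    dip_statistic,
    dip_test,
    dip_with_modal_interval,
    estimate_modes,
    grubbs_critical_value,
    grubbs_exclude,
)


class TestGrubbs:
    def test_constant_sample_no_exclusion(self):
        r = grubbs_exclude(np.ones(5))
        assert r.excluded_indices == [] and r.kept.size == 5

    def test_single_outlier_removed_then_stops(self):
        x = np.array([1.0, 1.1, 0.9, 1.05, 0.95, 8.0])
        r = grubbs_exclude(x, alpha=0.05)
        assert r.excluded_indices == [5]
        assert r.kept.size == 5
        # direct check against the closed-form critical value
        g = np.max(np.abs(x - x.mean())) / x.std(ddof=1)
        assert g > grubbs_critical_value(6, 0.05)

    def test_excluded_value_is_max_deviation(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(size=20), [40.0]])
        r = grubbs_exclude(x)
        assert r.excluded_indices[0] == int(np.argmax(np.abs(x - x.mean())))

    def test_exclusions_monotone_in_alpha(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(size=15), [8.0, 12.0]])
        counts = [
            len(grubbs_exclude(x, alpha=a).excluded_indices)
            for a in (0.2, 0.1, 0.05, 0.01, 0.001)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_tiny_sample_noop(self):
        r = grubbs_exclude(np.array([1.0, 9.0]))
        assert r.excluded_indices == []


class TestDipStatistic:
    def test_three_point_samples_match_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=3)
            assert abs(dip_statistic(x) - dip_brute_force(x)) < 1e-10

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_bounds_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        x = rng.normal(size=n)
        d = dip_statistic(x)
        assert 1 / (2 * n) - 1e-12 <= d <= 0.25 + 1e-12

    @given(st.floats(-5, 5), st.floats(0.1, 10))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_affine_invariance(self, b, a):
        x = np.random.default_rng(9).normal(size=25)
        assert abs(dip_statistic(a * x + b) - dip_statistic(x)) < 1e-12
        assert abs(dip_statistic(-a * x + b) - dip_statistic(x)) < 1e-12

    def test_two_tight_clusters_approach_quarter(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([1e-6 * rng.random(50), 1 + 1e-6 * rng.random(50)])
        assert abs(dip_statistic(x) - 0.25) < 1e-3

    def test_evenly_spaced_sample_attains_lower_bound(self):
        assert dip_statistic(np.arange(12.0)) == pytest.approx(1 / 24, abs=1e-12)

    def test_modal_interval_brackets_the_mode(self):
        rng = np.random.default_rng(3)
        x = rng.normal(5.0, 1.0, size=200)
        _, (lo, hi) = dip_with_modal_interval(x)
        assert lo <= hi

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            dip_statistic(np.array([1.0]))


class TestDipTest:
    def test_determinism(self):
        x = np.random.default_rng(4).normal(size=40)
        r1 = dip_test(x, n_boot=300, seed=11)
        r2 = dip_test(x, n_boot=300, seed=11)
        assert r1.p_value == r2.p_value and r1.dip == r2.dip

    def test_bimodal_sample_rejects(self, uniform_null_table):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 0.05, 30), rng.normal(1, 0.05, 30)])
        assert dip_test(x, null_dips=uniform_null_table).p_value < 0.01

    def test_dropout_free_periods_unimodal(self, uniform_null_table):
        from prebotpy.synthetic import SynthConfig, generate_period_sample

        ok = 0
        for seed in range(50):
            per, _ = generate_period_sample(
                SynthConfig(seed=seed, jitter_cv=0.1), "baseline", 60
            )
            ok += dip_test(per, null_dips=uniform_null_table).p_value > 0.05
        assert ok >= 45  # >= 90% of seeds


class TestModes:
    def test_two_component_recovery(self):
        rng = np.random.default_rng(10)
        x = np.concatenate([rng.normal(1.0, 0.05, 140), rng.normal(2.0, 0.1, 60)])
        est = estimate_modes(x, max_components=3, seed=0)
        assert est.n_components == 2
        assert abs(est.means[0] - 1.0) < 0.05 and abs(est.means[1] - 2.0) < 0.05
        assert abs(est.weights[0] - 0.7) < 0.1

    def test_single_gaussian_selects_one_component(self):
        x = np.random.default_rng(11).normal(1.0, 0.1, 200)
        assert estimate_modes(x, seed=0).n_components == 1

    def test_degenerate_equal_sample(self):
        est = estimate_modes(np.ones(10), seed=0)
        assert est.n_components == 1 and est.modes[0][1] == 0.0


class TestBurstletConsistency:
    def test_integer_multiple_modes(self):
        report = burstlet_consistency_check(
            ModeEstimate([(1.0, 0.05, 0.7), (2.0, 0.1, 0.3)], 2)
        )
        assert report.consistent_with_dropout
        assert report.ratios == [2.0]
        assert report.burstlet_fraction == 0.7

    def test_printed_mode_pair_is_flagged(self):
        # observed multimodal slice: modes 0.93 and 1.43 -> ratio 1.54,
        # not an integer multiple within 15%: inconsistent with pure dropout
        report = burstlet_consistency_check(
            ModeEstimate([(0.93, 0.08, 0.6), (1.43, 0.16, 0.4)], 2)
        )
        assert not report.consistent_with_dropout
        assert abs(report.ratios[0] - 1.5376) < 1e-3

    def test_single_mode_message(self):
        report = burstlet_consistency_check(ModeEstimate([(1.0, 0.1, 1.0)], 1))
        assert "no dropout signature" in report.message
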