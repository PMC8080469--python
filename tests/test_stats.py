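from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sasskit.exceptions import DegenerateDataError
from sasskit.stats import (
    amplitude_tests,
    circular_correlation,
    circular_median,
    group_tests,
    min_detectable_d,
    plv,
    stars,
    wallraff_test,
    wrap_angles,
)


class TestPlv:
    def test_identical_angles_give_one(self):
        assert plv(np.full(50, 1.3)) == pytest.approx(1.0)

    def test_uniform_grid_gives_zero(self):
        for n in (2, 3, 8):
            grid = 2 * np.pi * np.arange(n) / n
            assert plv(grid) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_random_small_sample_expectation(self, rng):
        """For n iid uniform angles E[PLV] ~ sqrt(pi/4)/sqrt(n) (Rayleigh)."""
        n, reps = 200, 1000
        vals = [plv(rng.uniform(-np.pi, np.pi, n)) for _ in range(reps)]
        expect = np.sqrt(np.pi / 4) / np.sqrt(n)
        assert abs(np.mean(vals) - expect) / expect < 0.1

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(-10, 10), st.integers(0, 1000))
    def test_rotation_invariance(self, offset, seed):
        a = np.random.default_rng(seed).uniform(-np.pi, np.pi, 37)
        assert plv(a + offset) == pytest.approx(plv(a), abs=1e-9)

    def test_empty_errors(self):
        with pytest.raises(DegenerateDataError):
            plv(np.array([]))


class TestCircularMedian:
    def test_single_angle_is_itself(self):
        assert circular_median(np.array([0.7])) == pytest.approx(0.7)

    def test_symmetric_triple(self):
        assert circular_median(np.array([-0.1, 0.0, 0.1])) == pytest.approx(0.0)

    def test_grid_oracle_agreement(self, rng):
        """The data-point median's mean distance matches a 1e4-point grid
        minimizer within grid resolution."""
        from sasskit.stats import angular_distance

        grid = np.linspace(-np.pi, np.pi, 10_000, endpoint=False)
        for _ in range(5):
            a = wrap_angles(rng.vonmises(rng.uniform(-3, 3), 1.0, 25))
            med = circular_median(a)
            ours = angular_distance(a, med).mean()
            grid_best = min(angular_distance(a, g).mean() for g in grid)
            assert ours <= grid_best + 2 * np.pi / 10_000


class TestWallraff:
    def test_no_dispersion_difference_large_p(self, rng):
        a = rng.vonmises(0.0, 4.0, 200)
        res = wallraff_test(a, a.copy(), sided="two")
        assert res.p_value > 0.5

    def test_detects_doubled_spread(self, rng):
        a = rng.vonmises(0.0, 8.0, 200)
        b = rng.vonmises(0.0, 2.0, 200)
        res = wallraff_test(a, b, sided="one")
        assert res.p_value < 0.01

    def test_degenerate_identical_angles(self):
        a = np.full(10, 0.5)
        res = wallraff_test(a, a, sided="two")
        assert res.p_value == 1.0 and res.degenerate

    def test_rotation_and_reflection_invariance(self, rng):
        a = rng.vonmises(0.0, 3.0, 40)
        b = rng.vonmises(1.0, 1.5, 35)
        base = wallraff_test(a, b)
        rot = wallraff_test(a + 2.0, b + 2.0)
        refl = wallraff_test(-a, -b)
        assert rot.statistic == pytest.approx(base.statistic)
        assert refl.statistic == pytest.approx(base.statistic)

    def test_paired_requires_equal_n(self, rng):
        with pytest.raises(DegenerateDataError):
            wallraff_test(rng.vonmises(0, 1, 10), rng.vonmises(0, 1, 11), paired=True)


class TestAmplitudeTests:
    def test_identical_samples(self, rng):
        x = rng.standard_normal(100)
        res = amplitude_tests(x, x.copy(), x.copy())
        assert res["stim_raw_vs_stim_sass"].degenerate
        assert res["no_stim_vs_stim_sass"].p_value > 0.99

    def test_huge_shift_four_stars(self, rng):
        no_stim = rng.standard_normal(200)
        stim_raw = no_stim + 10.0 + 0.1 * rng.standard_normal(200)  # ten sigma
        res = amplitude_tests(no_stim, stim_raw, no_stim.copy())
        assert res["no_stim_vs_stim_raw"].p_value < 1e-4
        assert res["no_stim_vs_stim_raw"].stars == "****"

    def test_matches_scipy_oracle(self, rng):
        from scipy import stats as sst

        a, b, c = (rng.standard_normal(50) for _ in range(3))
        res = amplitude_tests(a, b, c)
        assert res["no_stim_vs_stim_raw"].p_value == pytest.approx(
            sst.ttest_ind(b, a, alternative="greater").pvalue
        )
        assert res["stim_raw_vs_stim_sass"].p_value == pytest.approx(
            sst.ttest_rel(b, c, alternative="greater").pvalue
        )

    def test_length_mismatch_errors(self, rng):
        with pytest.raises(DegenerateDataError):
            amplitude_tests(rng.standard_normal(10), rng.standard_normal(10),
                            rng.standard_normal(9))


class TestMinDetectableD:
    def test_published_power_analysis_value(self):
        """n = 200/group, alpha .05 two-sided, power .80 -> d = 0.281."""
        assert round(min_detectable_d(200, 0.05, 0.80, "two"), 3) == 0.281

    def test_normal_approximation_agreement(self):
        from scipy.stats import norm

        for n in (200, 500, 1000):  # approximation degrades below ~100/group
            d = min_detectable_d(n, 0.05, 0.80, "two")
            approx = (norm.ppf(0.975) + norm.ppf(0.80)) * np.sqrt(2 / n)
            assert abs(d - approx) < 0.002

    def test_power_to_alpha_limit_gives_zero(self):
        assert min_detectable_d(200, 0.05, 0.0500001, "two") < 0.01

    def test_one_sided_smaller_than_two_sided(self):
        assert min_detectable_d(200, sided="one") < min_detectable_d(200, sided="two")


class TestGroupTests:
    def test_identical_vectors_give_p_one(self):
        v = np.arange(6.0)
        res = group_tests({"no_stim": v, "stim_raw": v, "stim_sass": v})
        assert res["no_stim_vs_stim_sass"].p_value == pytest.approx(1.0)

    def test_complete_separation_exact_tail(self):
        """N = 6 per condition, full separation: one-sided exact rank-sum
        p equals 1/C(12,6)."""
        lo = np.arange(6.0)
        hi = lo + 100.0
        res = group_tests({"no_stim": hi, "stim_raw": lo, "stim_sass": hi})
        assert res["no_stim_vs_stim_raw"].p_value == pytest.approx(1 / comb(12, 6))

    def test_participant_order_invariance(self, rng):
        v = {k: rng.standard_normal(6) for k in ("no_stim", "stim_raw", "stim_sass")}
        perm = {k: x[::-1].copy() for k, x in v.items()}
        r1, r2 = group_tests(v), group_tests(perm)
        for key in r1:
            assert r1[key].p_value == pytest.approx(r2[key].p_value)

    def test_amplitude_direction(self, rng):
        """For amplitudes the artifact inflates the uncleaned condition."""
        lo = np.arange(6.0)
        res = group_tests(
            {"no_stim": lo, "stim_raw": lo + 100, "stim_sass": lo}, metric="amplitude"
        )
        assert res["no_stim_vs_stim_raw"].p_value < 0.01


class TestCircularCorrelation:
    def test_perfect_association(self, rng):
        a = rng.uniform(-np.pi, np.pi, 100)
        assert circular_correlation(a, a) == pytest.approx(1.0)

    def test_independent_near_zero(self, rng):
        a = rng.uniform(-np.pi, np.pi, 2000)
        b = rng.uniform(-np.pi, np.pi, 2000)
        assert abs(circular_correlation(a, b)) < 0.1


def test_star_thresholds():
    assert stars(0.2) == "ns"
    assert stars(0.04) == "*"
    assert stars(0.004) == "**"
    assert stars(0.0004) == "***"
    assert stars(0.00004) == "****"
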