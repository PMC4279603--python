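"""Frequency classes, the population statistics panel and the cut-off."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmofreq.stats import (
    FrequencyDistribution,
    StatsError,
    bin_values,
    chi_square_normality,
    cutoff_summary,
    empirical_skewness,
    min_replicates_for_rsd,
    population_sd,
    population_stats,
)

value_arrays = st.lists(
    st.floats(min_value=-100, max_value=100), min_size=5, max_size=60
).filter(lambda v: max(v) - min(v) > 0.1)


class TestBinning:
    def test_uniform_values_spread_evenly(self):
        dist = bin_values(np.arange(10.0), n_classes=5)
        np.testing.assert_array_equal(dist.counts, [2, 2, 2, 2, 2])
        assert dist.upper_limits[-1] == pytest.approx(9.0)

    @given(value_arrays)
    @settings(max_examples=100, deadline=None)
    def test_counts_conserved(self, values):
        dist = bin_values(values, n_classes=7)
        assert dist.counts.sum() == len(values)
        widths = np.diff(dist.class_edges)
        np.testing.assert_allclose(widths, widths[0], rtol=1e-9)

    def test_maximum_falls_in_last_class(self):
        dist = bin_values([0.0, 0.5, 1.0], n_classes=4)
        assert dist.counts[-1] >= 1

    def test_degenerate_population_single_occupied_class(self):
        with pytest.warns(UserWarning, match="identical"):
            dist = bin_values([0.1] * 50, n_classes=6)
        assert dist.counts[0] == 50
        assert dist.counts[1:].sum() == 0


class TestPopulationStats:
    def test_population_divisor_hand_example(self):
        # {1, 3}: population SD is 1 (divisor n), never the sample 1.414...
        assert population_sd([1.0, 3.0]) == pytest.approx(1.0, abs=1e-12)
        st_ = population_stats([1.0, 3.0], nominal=2.5, dist=None)
        assert st_.mean == pytest.approx(2.0)
        assert st_.sd_population == pytest.approx(1.0)
        assert st_.rsd == pytest.approx(50.0)
        assert st_.rel_abs_deviation == pytest.approx(20.0)
        assert st_.sd_population != pytest.approx(math.sqrt(2), abs=1e-3)

    @given(value_arrays)
    @settings(max_examples=100, deadline=None)
    def test_variance_times_n_equals_sum_of_squares(self, values):
        v = np.asarray(values)
        var_n = population_sd(v) ** 2 * len(v)
        assert var_n == pytest.approx(float(np.sum((v - v.mean()) ** 2)), rel=1e-9, abs=1e-9)

    def test_values_at_nominal_are_perfectly_true(self):
        st_ = population_stats([0.1] * 20, nominal=0.1)
        assert st_.rsd == 0.0
        assert st_.rel_abs_deviation == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(st_.skewness)  # undefined at zero spread

    def test_zero_mean_rejected(self):
        with pytest.raises(StatsError, match="zero mean"):
            population_stats([-1.0, 1.0], nominal=1.0)


class TestSkewness:
    def test_symmetric_values_have_zero_skew(self):
        assert empirical_skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # {0,0,0,1}: mean 0.25, population sd sqrt(3)/4; direct evaluation
        assert empirical_skewness([0.0, 0.0, 0.0, 1.0]) == pytest.approx(1.1547, abs=1e-4)

    @given(value_arrays, st.floats(min_value=0.1, max_value=10),
           st.floats(min_value=-5, max_value=5))
    @settings(max_examples=100, deadline=None)
    def test_affine_invariance(self, values, b, a):
        base = empirical_skewness(values)
        shifted = empirical_skewness([a + b * x for x in values])
        assert shifted == pytest.approx(base, rel=1e-6, abs=1e-8)
        flipped = empirical_skewness([a - b * x for x in values])
        assert flipped == pytest.approx(-base, rel=1e-6, abs=1e-8)

    def test_zero_spread_rejected(self):
        with pytest.raises(StatsError):
            empirical_skewness([2.0, 2.0, 2.0])


def erf_oracle_chi2(edges, counts, mean, sd):
    """Independent reimplementation: Gaussian masses via math.erf, plain sums."""
    def cdf(x):
        if x == -math.inf:
            return 0.0
        if x == math.inf:
            return 1.0
        return 0.5 * (1 + math.erf((x - mean) / (sd * math.sqrt(2))))

    def sf(x):
        if x == math.inf:
            return 0.0
        return 0.5 * math.erfc((x - mean) / (sd * math.sqrt(2)))

    lo = [-math.inf] + list(edges[1:-1])
    hi = list(edges[1:-1]) + [math.inf]
    n_total = sum(counts)
    chi2 = 0.0
    for n_obs, a, b in zip(counts, lo, hi):
        p = (sf(a) - sf(b)) if a >= mean else (cdf(b) - cdf(a))
        m = p * n_total
        chi2 += (n_obs - m) ** 2 / m
    return chi2


class TestChiSquare:
    def test_counts_equal_expected_gives_p_100(self):
        # manufacture a distribution whose counts exactly equal the Gaussian
        # expectation (float counts are accepted by the checker)
        edges = np.linspace(-2, 2, 9)
        from scipy.stats import norm

        open_edges = edges.copy()
        open_edges[0], open_edges[-1] = -np.inf, np.inf
        expected = np.diff(norm.cdf(open_edges, 0.0, 1.0)) * 1000
        dist = FrequencyDistribution(class_edges=edges, counts=expected, n_total=1000)
        chi2, df, p = chi_square_normality(dist, mean=0.0, sd=1.0)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 5  # 8 classes - 3
        assert p == pytest.approx(1.0)

    def test_matches_erf_oracle(self, rng):
        for _ in range(20):
            values = rng.normal(10, 2, size=500)
            dist = bin_values(values, n_classes=8)
            chi2, _, _ = chi_square_normality(dist, values.mean(), values.std())
            oracle = erf_oracle_chi2(dist.class_edges, dist.counts, values.mean(), values.std())
            assert chi2 == pytest.approx(oracle, rel=1e-10)

    def test_upper_tail_probability_semantics(self):
        edges = np.linspace(-3, 3, 11)
        counts = np.array([1, 5, 30, 120, 250, 280, 200, 90, 20, 4])
        dist = FrequencyDistribution(class_edges=edges, counts=counts, n_total=1000)
        chi2, df, p = chi_square_normality(dist, 0.0, 1.0)
        from scipy.stats import chi2 as chi2_dist

        assert p == pytest.approx(float(chi2_dist.sf(chi2, df)), rel=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        values = rng.gamma(4, 2, size=800)
        dist = bin_values(values, n_classes=10)
        chi2_a, _, _ = chi_square_normality(dist, values.mean(), values.std())
        scaled = 3.0 * values + 7.0
        dist_b = bin_values(scaled, n_classes=10)
        chi2_b, _, _ = chi_square_normality(dist_b, scaled.mean(), scaled.std())
        assert chi2_b == pytest.approx(chi2_a, rel=1e-6)

    def test_too_few_classes_rejected(self):
        dist = bin_values([1.0, 2.0, 3.0], n_classes=3)
        with pytest.raises(StatsError, match="4 classes"):
            chi_square_normality(dist, 2.0, 1.0)


class TestCutoff:
    def make_dist(self, counts):
        counts = np.asarray(counts)
        edges = np.arange(len(counts) + 1, dtype=float)
        return FrequencyDistribution(
            class_edges=edges, counts=counts, n_total=int(counts.sum())
        )

    def test_dominant_class_example(self):
        # enumeration over candidate thresholds: 4800/5000 = 96% suffices
        cut = cutoff_summary(self.make_dist([50, 4800, 100, 50]))
        assert cut.count_threshold == 4800
        assert len(cut.included_upper_limits) == 1
        assert cut.achieved_coverage == pytest.approx(0.96)
        assert cut.half_range == 0.0

    def test_single_occupied_class(self):
        cut = cutoff_summary(self.make_dist([0, 0, 10, 0]))
        assert cut.middle_class == pytest.approx(3.0)  # that class's upper limit
        assert cut.half_range == 0.0

    def test_middle_class_and_half_range_formulas(self):
        counts = [1, 30, 50, 40, 20, 2]
        cut = cutoff_summary(self.make_dist(counts))
        # thresholds: 20 covers (30+50+40+20)/143 = 97.9%
        assert cut.count_threshold == 20
        u_first, u_last = cut.included_class_range
        assert cut.middle_class == pytest.approx((u_last + u_first) / 2)
        assert cut.half_range == pytest.approx((u_last - u_first) / 2)
        assert (u_first, u_last) == (2.0, 5.0)

    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=4, max_size=25)
           .filter(lambda c: sum(c) > 0))
    @settings(max_examples=150, deadline=None)
    def test_coverage_always_reached_and_threshold_maximal(self, counts):
        dist = self.make_dist(counts)
        cut = cutoff_summary(dist)
        assert cut.achieved_coverage >= 0.95
        # a strictly higher threshold must fall short of the target
        higher = [c for c in np.unique(dist.counts) if c > cut.count_threshold]
        if higher:
            c2 = min(higher)
            covered = dist.counts[dist.counts >= c2].sum()
            assert covered < 0.95 * dist.n_total


class TestSweepHelpers:
    def test_grid_dimensions_and_rsd_decreases(self, fitted_results):
        grid = fitted_results.grid
        assert len(grid) == 2 * 4  # settings x ks
        for sid in ("setting_1", "setting_2"):
            rsds = [grid[(sid, k)].stats.rsd for k in (2, 4, 8, 16)]
            assert rsds == sorted(rsds, reverse=True)

    def test_min_replicates_selection(self, fitted_results):
        grid = fitted_results.grid
        assert min_replicates_for_rsd(grid, rsd_threshold=1000.0) == 2
        assert min_replicates_for_rsd(grid, rsd_threshold=-1.0) is None
        worst_k2 = max(grid[(s, 2)].stats.rsd for s, k in grid if k == 2)
        assert min_replicates_for_rsd(grid, rsd_threshold=worst_k2) == 2
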