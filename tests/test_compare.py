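"""Summary statistics, randomization tests, KS, and histogram densities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reefwave.compare import (
    _shuffled_groups,
    histogram_densities,
    ks_test,
    mc_difference_test,
    percentile_difference_test,
    summarize,
)
from reefwave.errors import EmptySeriesError, InsufficientNullError, InvalidConfigError


def rescale(values, lo, hi):
    v = np.asarray(values, dtype=float)
    v = (v - v.min()) / (v.max() - v.min())
    return lo + v * (hi - lo)


class TestSummarize:
    @pytest.mark.parametrize("lo,hi,expected", [(19.54, 30.01, 10.47), (7.836, 8.069, 0.233)])
    def test_range_is_max_minus_min(self, rng, lo, hi, expected):
        s = summarize(rescale(rng.normal(size=500), lo, hi))
        assert s.range == pytest.approx(expected, abs=1e-9)
        assert s.max == pytest.approx(hi) and s.min == pytest.approx(lo)

    def test_constant_series(self):
        s = summarize(np.full(10, 4.2))
        assert s.sd == pytest.approx(0.0, abs=1e-12) and s.range == 0.0
        assert s.q25 == s.q75 == 4.2
        assert s.mean == pytest.approx(4.2, rel=1e-12)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=200))
    def test_ordering_invariants(self, values):
        s = summarize(np.array(values))
        assert s.min <= s.q25 <= s.q75 <= s.max
        assert s.range == pytest.approx(s.max - s.min)

    def test_single_sample_rejected(self):
        with pytest.raises(EmptySeriesError):
            summarize(np.array([1.0]))


class TestMcDifferenceTest:
    def test_extreme_shift_attains_minimum_p(self, rng):
        a = rng.normal(size=200)
        b = a + 10 * a.std()
        r = mc_difference_test(a, b, metric="mean", n_rand=199, seed=0)
        assert r.p_two_tailed == pytest.approx(1 / 200)

    def test_zero_observed_difference_gives_p_one(self, rng):
        a = rng.normal(size=100)
        r = mc_difference_test(a, a.copy(), metric="mean", n_rand=99, seed=0)
        assert r.observed_diff == 0.0
        assert r.p_two_tailed == 1.0

    def test_variance_metric_detects_spread_difference(self, rng):
        a = rng.normal(size=400)
        b = 5.0 * rng.normal(size=400)
        r = mc_difference_test(a, b, metric="variance", n_rand=199, seed=1)
        assert r.p_two_tailed == pytest.approx(1 / 200)

    def test_type_i_error_calibrated(self):
        rejections = 0
        n_sets = 120
        for seed in range(n_sets):
            r = np.random.default_rng(seed)
            a, b = r.normal(size=60), r.normal(size=60)
            res = mc_difference_test(a, b, metric="mean", n_rand=99, seed=seed + 1)
            rejections += res.p_two_tailed <= 0.05
        assert abs(rejections / n_sets - 0.05) < 0.05

    def test_shuffles_preserve_group_sizes_and_pool(self, rng):
        pool = rng.normal(size=23)
        for ga, gb in _shuffled_groups(pool, 9, 50, rng, chunk=17):
            assert ga.shape[1] == 9 and gb.shape[1] == 14
            for row_a, row_b in zip(ga, gb):
                assert np.array_equal(np.sort(np.concatenate([row_a, row_b])), np.sort(pool))

    def test_too_few_randomizations_rejected(self, rng):
        with pytest.raises(InsufficientNullError):
            mc_difference_test(rng.normal(size=10), rng.normal(size=10), n_rand=5)

    def test_unknown_metric_rejected(self, rng):
        with pytest.raises(InvalidConfigError):
            mc_difference_test(rng.normal(size=10), rng.normal(size=10), metric="median")


class TestPercentileDifferenceTest:
    def test_identical_samples_give_zero_diff_and_p_one(self, rng):
        a = rng.normal(size=300)
        pc = percentile_difference_test(a, a.copy(), n_rand=49, seed=0)
        assert np.allclose(pc.diff, 0.0)
        assert np.all(pc.p == 1.0)

    def test_uniform_shift_detected_at_every_percentile(self, rng):
        a = rng.normal(size=300)
        pc = percentile_difference_test(a, a + 1.0, n_rand=199, seed=0)
        assert np.allclose(pc.diff, 1.0, atol=1e-9)
        assert np.all(pc.p == pytest.approx(1 / 200))

    def test_upper_tail_contamination_pattern(self):
        # b differs from a only in its upper tail: significance should
        # concentrate in the high percentiles
        upper_rate, lower_rate = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            a = r.normal(size=600)
            b = r.normal(size=600)
            tail = b > np.percentile(b, 80)
            b[tail] += 2.0
            pc = percentile_difference_test(a, b, n_rand=199, seed=seed)
            upper_rate.append(pc.significant_at_05[pc.percentiles >= 85].mean())
            lower_rate.append(pc.significant_at_05[pc.percentiles <= 50].mean())
        assert np.mean(upper_rate) > 0.7
        assert np.mean(lower_rate) < 0.3
        assert np.mean(upper_rate) > 2 * np.mean(lower_rate)

    def test_diffs_consistent_with_summary_quartiles(self, rng):
        a, b = rng.normal(size=400), rng.normal(size=400) + 0.3
        pc = percentile_difference_test(a, b, percentile_grid=[25, 75], n_rand=19, seed=0)
        sa, sb = summarize(a), summarize(b)
        assert pc.diff[0] == pytest.approx(sb.q25 - sa.q25)
        assert pc.diff[1] == pytest.approx(sb.q75 - sa.q75)


class TestKs:
    def test_identical_samples(self, rng):
        a = rng.normal(size=100)
        d, p = ks_test(a, a.copy())
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self, rng):
        d, _ = ks_test(rng.uniform(0, 1, 100), rng.uniform(5, 6, 100))
        assert d == 1.0

    def test_offset_uniforms_analytic_d(self, rng):
        a = rng.uniform(0, 1, 1000)
        b = rng.uniform(0.5, 1.5, 1000)
        d, p = ks_test(a, b)
        assert d == pytest.approx(0.5, abs=0.05)
        assert p < 1e-10


class TestHistogramDensities:
    def test_single_bin_density(self, rng):
        v = rng.uniform(2.0, 4.0, 100)
        h = histogram_densities(v, v, np.array([2.0, 4.0]))
        assert h["density_a"][0] == pytest.approx(0.5)

    def test_densities_integrate_to_one(self, rng):
        a, b = rng.normal(size=500), rng.normal(size=700) + 1
        edges = np.linspace(-5, 6, 40)
        h = histogram_densities(a, b, edges)
        w = np.diff(edges)
        assert (h["density_a"] * w).sum() == pytest.approx(1.0, abs=1e-9)
        assert (h["density_b"] * w).sum() == pytest.approx(1.0, abs=1e-9)

    def test_low_ph_site_has_more_mass_below_its_median(self):
        from reefwave.synthetic import moorea_like, taiwan_like

        m = moorea_like(seed=3, duration_days=10.0, dt_minutes=12.0).generate()["pH_total"]
        t = taiwan_like(seed=3, duration_days=10.0, dt_minutes=12.0).generate()["pH_total"]
        pool = np.concatenate([m.values, t.values])
        edges = np.linspace(pool.min(), pool.max(), 60)
        h = histogram_densities(m.values, t.values, edges)
        w = np.diff(edges)
        cut = np.median(t.values)
        below = edges[1:] <= cut
        mass_t = (h["density_b"] * w)[below].sum()
        mass_m = (h["density_a"] * w)[below].sum()
        assert mass_t > mass_m

    def test_bad_bins_rejected(self, rng):
        with pytest.raises(InvalidConfigError):
            histogram_densities(rng.normal(size=10), rng.normal(size=10), [1.0, 1.0])
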