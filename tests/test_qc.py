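"""QC chain: trimming, outlier rules, uniform resampling, low-pass filtering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reefwave.errors import EmptySeriesError, InvalidConfigError
from reefwave.qc import clean_outliers, lowpass_1h, resample_uniform, trim
from reefwave.series import EnvironmentalSeries


def uniform_series(values, dt=600.0, variable="value"):
    return EnvironmentalSeries.from_regular("2012-05-24", dt, values, variable=variable)


class TestTrim:
    def test_full_span_is_identity(self):
        s = uniform_series(np.arange(100.0))
        t = trim(s, s.timestamps[0], s.timestamps[-1])
        assert np.array_equal(t.values, s.values)

    def test_middle_day_of_45d_series_has_145_samples(self):
        s = uniform_series(np.zeros(45 * 144 + 1))
        start = s.timestamps[0] + np.timedelta64(20, "D")
        t = trim(s, start, start + np.timedelta64(1, "D"))
        assert len(t) == 145  # inclusive endpoints

    def test_window_before_series_raises(self):
        s = uniform_series(np.zeros(10))
        early = s.timestamps[0] - np.timedelta64(2, "D")
        with pytest.raises(EmptySeriesError):
            trim(s, early, early + np.timedelta64(1, "D"))


class TestCleanOutliers:
    def test_clean_data_has_zero_removals(self, rng):
        s = uniform_series(8.0 + 0.01 * rng.normal(size=500), variable="pH_total")
        out, rep = clean_outliers(s)
        assert rep.n_removed_out_of_range == 0 and rep.n_removed_spike == 0
        assert out.n_valid == s.n_valid

    def test_out_of_range_value_removed(self, rng):
        v = 8.0 + 0.01 * rng.normal(size=500)
        v[123] = 11.0
        out, rep = clean_outliers(uniform_series(v, variable="pH_total"),
                                  valid_range=(7.0, 9.0), spike_k=None)
        assert rep.n_removed_out_of_range == 1
        assert not out.valid[123]

    def test_injected_spikes_are_flagged(self, rng):
        # bounded background noise: rolling MAD ~0.005, no tail to mis-flag
        v = rng.uniform(-0.01, 0.01, size=2000)
        idx = [200, 600, 1000, 1400, 1800]
        v[idx] += 1.0  # far above 6x the rolling MAD of the background
        out, rep = clean_outliers(uniform_series(v), spike_k=6.0)
        assert rep.n_removed_spike == 5
        assert not out.valid[idx].any()

    def test_bookkeeping_identity_on_constructed_fixture(self, rng):
        v = 8.0 + 0.01 * rng.normal(size=800)
        v[rng.choice(800, 10, replace=False)] = 12.0
        out, rep = clean_outliers(uniform_series(v, variable="pH_total"))
        assert rep.n_input - rep.n_removed_out_of_range - rep.n_removed_spike == out.n_valid

    @given(st.integers(0, 20), st.integers(0, 2**31 - 1))
    def test_bookkeeping_identity_property(self, n_bad, seed):
        r = np.random.default_rng(seed)
        v = 8.0 + 0.02 * r.normal(size=300)
        if n_bad:
            v[r.choice(300, min(n_bad, 300), replace=False)] = 99.0
        out, rep = clean_outliers(uniform_series(v, variable="pH_total"))
        assert rep.n_valid_output == out.n_valid
        assert rep.n_input == 300


class TestResample:
    def test_already_uniform_is_identity(self, rng):
        s = uniform_series(rng.normal(size=200))
        out = resample_uniform(s, 600.0)
        assert np.allclose(out.values, s.values, atol=1e-12)
        assert out.dt == 600.0

    def test_linear_midpoint(self):
        s = EnvironmentalSeries(
            site="t", variable="value",
            timestamps=np.array(["2012-01-01T00:00:00", "2012-01-01T00:10:00"],
                                dtype="datetime64[ns]"),
            values=np.array([0.0, 1.0]),
        )
        out = resample_uniform(s, 300.0)
        assert out.values[1] == pytest.approx(0.5)

    def test_long_gap_stays_invalid(self):
        n = 45 * 144 + 1
        valid = np.ones(n, dtype=bool)
        gap = slice(10 * 144, 13 * 144)
        valid[gap] = False
        s = EnvironmentalSeries.from_regular("2012-05-24", 600.0, np.arange(n, dtype=float),
                                             valid=valid)
        out = resample_uniform(s, 600.0, gap_tolerance_seconds=3600.0)
        assert not out.valid[gap].any()
        assert out.valid[:10 * 144].all()

    def test_nonpositive_dt_rejected(self):
        s = uniform_series(np.arange(10.0))
        with pytest.raises(InvalidConfigError):
            resample_uniform(s, 0.0)

    def test_resample_then_trim_commutes_on_gap_free_series(self, rng):
        s = uniform_series(rng.normal(size=1000))
        a = s.timestamps[0] + np.timedelta64(1, "D")
        b = s.timestamps[0] + np.timedelta64(5, "D")
        first = trim(resample_uniform(s, 600.0), a, b)
        second = resample_uniform(trim(s, a, b), 600.0)
        assert np.allclose(first.values, second.values, atol=1e-9)


class TestLowpass:
    def test_constant_series_unchanged(self):
        s = uniform_series(np.full(500, 7.5))
        assert np.allclose(lowpass_1h(s).values, 7.5, atol=1e-12)

    def test_ten_minute_oscillation_removed(self):
        t = np.arange(2000) * 120.0
        s = uniform_series(np.sin(2 * np.pi * t / 600.0), dt=120.0)
        out = lowpass_1h(s)
        assert np.abs(out.values[200:-200]).max() <= 0.1

    def test_diel_oscillation_preserved(self):
        t = np.arange(6 * 144) * 600.0
        s = uniform_series(np.sin(2 * np.pi * t / 86400.0))
        out = lowpass_1h(s)
        interior = slice(144, -144)
        amp = np.abs(out.values[interior] - s.values[interior]).max()
        assert amp < 0.01  # within 1 % of unit amplitude

    def test_mean_preserved(self, rng):
        v = 8.0 + 0.03 * rng.normal(size=3000)
        s = uniform_series(v)
        out = lowpass_1h(s)
        assert abs(out.values.mean() - v.mean()) / abs(v.mean()) < 1e-9

    def test_idempotent_on_passband(self):
        t = np.arange(8 * 144) * 600.0
        s = uniform_series(np.sin(2 * np.pi * t / 86400.0))
        once = lowpass_1h(s)
        twice = lowpass_1h(once)
        interior = slice(144, -144)
        assert np.abs(twice.values[interior] - once.values[interior]).max() < 0.02

    def test_nonuniform_input_rejected(self):
        ts = np.array(["2012-01-01T00:00", "2012-01-01T00:10", "2012-01-01T00:25"],
                      dtype="datetime64[ns]")
        s = EnvironmentalSeries(site="t", variable="value", timestamps=ts,
                                values=np.zeros(3))
        with pytest.raises(InvalidConfigError):
            lowpass_1h(s)
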