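"""Morlet transform: spectral localization, energy bookkeeping, red-noise test."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from reefwave.errors import DegenerateInputError, InvalidConfigError
from reefwave.wavelet import (
    Ar1Model,
    WaveletParams,
    ar1_fit,
    ar1_simulate,
    cross_wavelet,
    cwt_morlet,
    global_spectrum,
    rednoise_significance,
    scale_averaged_power,
)

DT = 600.0


def mk(values, series_factory=None, dt=DT):
    from reefwave.series import EnvironmentalSeries

    return EnvironmentalSeries.from_regular("2012-05-24", dt, values)


def cosine(period_hours, n, dt=DT, amp=1.0, phase=0.0):
    t = np.arange(n) * dt
    return amp * np.cos(2 * np.pi * t / (period_hours * 3600.0) + phase)


class TestAr1Fit:
    def test_white_noise_alpha_near_zero(self, rng):
        m = ar1_fit(rng.normal(size=10_000))
        assert m.alpha < 0.03

    def test_recovers_simulated_alpha(self):
        ests = []
        for seed in range(50):
            x = ar1_simulate(Ar1Model(0.8, 1.0, 0), 10_000, np.random.default_rng(seed))
            ests.append(ar1_fit(x).alpha)
        assert abs(np.mean(ests) - 0.8) < 0.02

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            ar1_fit(np.full(100, 3.0))

    def test_sigma2_consistent_with_variance(self, rng):
        x = ar1_simulate(Ar1Model(0.6, 2.0, 0), 20_000, rng)
        m = ar1_fit(x)
        assert m.variance == pytest.approx(x.var(), rel=1e-6)


class TestCwt:
    def test_constant_series_has_no_power(self):
        spec = cwt_morlet(mk(np.full(512, 5.0) + 0.0 * np.arange(512)))
        assert np.all(spec.power <= 1e-20)

    def test_period_mapping_for_omega0_6(self):
        p = WaveletParams()
        assert p.fourier_factor == pytest.approx(1.033, abs=1e-3)
        spec = cwt_morlet(mk(np.random.default_rng(0).normal(size=256)))
        assert np.allclose(spec.periods * 3600.0, 1.033 * spec.scales, rtol=1e-3)

    def test_diel_peak_location(self):
        spec = cwt_morlet(mk(cosine(24.0, 45 * 144)))
        gs = global_spectrum(spec)
        peak = spec.periods[np.nanargmax(gs)]
        step = 2 ** spec.params.dj
        assert 24.0 / step <= peak <= 24.0 * step

    def test_two_component_signal_gives_two_peaks(self):
        spec = cwt_morlet(mk(cosine(24.0, 45 * 144) + cosine(12.0, 45 * 144)))
        gs = global_spectrum(spec)
        idx = find_peaks(gs)[0]
        assert len(idx) == 2
        step = 2 ** spec.params.dj
        for target, i in zip((12.0, 24.0), idx):
            assert target / step <= spec.periods[i] <= target * step

    def test_coi_symmetric_about_midpoint(self):
        spec = cwt_morlet(mk(np.random.default_rng(1).normal(size=401)))
        assert np.allclose(spec.coi, spec.coi[::-1], rtol=1e-12)

    def test_nonuniform_series_rejected(self):
        from reefwave.series import EnvironmentalSeries

        ts = np.array(["2012-01-01T00:00", "2012-01-01T00:10", "2012-01-01T00:25",
                       "2012-01-01T00:40", "2012-01-01T01:00"], dtype="datetime64[ns]")
        s = EnvironmentalSeries(site="t", variable="v", timestamps=ts, values=np.arange(5.0))
        with pytest.raises(InvalidConfigError):
            cwt_morlet(s)

    def test_white_noise_global_spectrum_is_flat(self):
        # E[power] for white noise is the series variance at every scale
        acc = None
        for seed in range(30):
            x = np.random.default_rng(seed).normal(size=1024)
            spec = cwt_morlet(mk(x))
            gs = global_spectrum(spec, exclude_outside_coi=True)
            acc = gs if acc is None else acc + gs
        acc /= 30
        lo = np.nanargmin(np.abs(spec.periods - 1.0))
        hi = np.nanargmin(np.abs(spec.periods - 10.0))
        assert acc[hi] / acc[lo] == pytest.approx(1.0, abs=0.2)


class TestScaleAveragedPower:
    def test_zero_signal_gives_zero(self):
        spec = cwt_morlet(mk(np.zeros(256)))
        assert np.allclose(scale_averaged_power(spec), 0.0, atol=1e-20)

    def test_reconstructs_ar1_variance(self):
        ratios = []
        for seed in range(5):
            x = ar1_simulate(Ar1Model(0.7, 1.0, 0), 4096, np.random.default_rng(seed))
            spec = cwt_morlet(mk(x))
            ratios.append(scale_averaged_power(spec).mean() / x.var())
        assert abs(np.mean(ratios) - 1.0) < 0.15

    def test_burst_fixture_localizes_power_in_time(self):
        n = 30 * 144
        x = np.zeros(n)
        x[n // 2:] = cosine(24.0, n - n // 2)
        sap = scale_averaged_power(cwt_morlet(mk(x)))
        margin = 3 * 144
        first = sap[margin : n // 2 - margin].mean()
        second = sap[n // 2 + margin : -margin].mean()
        assert second >= 5 * first


class TestRednoiseSignificance:
    def test_false_positive_rate_near_alpha(self):
        fracs = []
        for seed in range(15):
            x = ar1_simulate(Ar1Model(0.7, 1.0, 0), 2048, np.random.default_rng(seed))
            s = mk(x)
            spec = cwt_morlet(s)
            ratio = rednoise_significance(spec, ar1_fit(s))
            m = spec.in_coi()
            fracs.append(float((ratio[m] >= 1).mean()))
        assert abs(np.mean(fracs) - 0.05) < 0.03

    def test_strong_diel_signal_significant_across_record(self, rng):
        n = 30 * 144
        x = cosine(24.0, n) + 0.05 * rng.normal(size=n)
        s = mk(x)
        spec = cwt_morlet(s)
        ratio = rednoise_significance(spec, ar1_fit(s))
        j = np.argmin(np.abs(spec.periods - 24.0))
        in_coi = spec.in_coi()[:, j]
        assert (ratio[in_coi, j] >= 1).mean() >= 0.90

    def test_zero_variance_background_rejected(self):
        spec = cwt_morlet(mk(np.random.default_rng(0).normal(size=256)))
        with pytest.raises(DegenerateInputError):
            rednoise_significance(spec, Ar1Model(alpha=0.5, sigma2=0.0, n=256))


class TestCrossWavelet:
    def test_self_cross_power_is_real_power(self, rng):
        s = mk(rng.normal(size=512))
        spec = cwt_morlet(s)
        xw = cross_wavelet(spec, spec)
        assert np.allclose(xw.imag, 0.0, atol=1e-12)
        assert np.allclose(xw.real, spec.power, rtol=1e-12)

    def test_sign_flip_gives_pi_phase(self, rng):
        x = rng.normal(size=512)
        sx, sy = cwt_morlet(mk(x)), cwt_morlet(mk(-x))
        xw = cross_wavelet(sx, sy)
        strong = np.abs(xw) > 1e-3 * np.abs(xw).max()
        assert np.allclose(np.abs(np.angle(xw[strong])), np.pi, atol=1e-9)

    def test_cross_magnitude_bounded_by_auto_powers(self, rng):
        sx = cwt_morlet(mk(rng.normal(size=512)))
        sy = cwt_morlet(mk(rng.normal(size=512)))
        xw = cross_wavelet(sx, sy)
        bound = np.sqrt(sx.power * sy.power)
        assert np.all(np.abs(xw) <= bound * (1 + 1e-12))
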