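"""Burg/maximum-entropy spectral estimation and the sliding HRV indices."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hrvscreen import (
    ARModel,
    Band,
    HF_BAND,
    LF_BAND,
    PowerSpectrum,
    RRSeries,
    SpectralConfig,
    ar_psd,
    band_power,
    fit_burg,
    mean_hr,
    resample_tachogram,
    sliding_hrv,
    simulate_rr,
)
from tests.conftest import stationary_params


def simulate_ar(coeffs, n, sigma=1.0, seed=0, burn=500):
    """Simulate x_t with A(z) x = e, A(z) = 1 + sum a_k z^-k."""
    rng = np.random.default_rng(seed)
    p = len(coeffs)
    x = np.zeros(n + burn)
    e = rng.normal(0, sigma, n + burn)
    for t in range(p, n + burn):
        x[t] = e[t] - sum(coeffs[k] * x[t - 1 - k] for k in range(p))
    return x[burn:]


def reflection_to_ar(ks):
    """Step-up recursion: reflection coefficients -> AR polynomial tail."""
    a = np.zeros(0)
    for k in ks:
        a = np.concatenate([a + k * a[::-1], [k]])
    return a


class TestResample:
    def _rr_sine(self, f0=0.1, amp=50.0, mean=800.0, total=60.0):
        times = [0.0]
        while times[-1] < total:
            t = times[-1]
            rr = mean + amp * np.sin(2 * np.pi * f0 * t)
            times.append(t + rr / 1000.0)
        times = np.asarray(times)
        return RRSeries(beat_times=times, intervals=np.diff(times) * 1000.0)

    def test_constant_series_resamples_to_zeros(self):
        rr = RRSeries.from_intervals([800.0] * 50)
        out = resample_tachogram(rr, (0.0, 30.0))
        assert out.values.size == 121
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_sine_modulation_recovered_within_one_percent_rms(self):
        f0, amp = 0.1, 50.0
        rr = self._rr_sine(f0, amp)
        out = resample_tachogram(rr, (5.0, 55.0))
        grid = out.t0 + np.arange(out.values.size) / out.rate
        truth = amp * np.sin(2 * np.pi * f0 * grid)
        truth = truth - truth.mean()
        rms_err = np.sqrt(np.mean((out.values - truth) ** 2))
        assert rms_err < 0.01 * amp / np.sqrt(2)  # 1% of the sine's RMS

    def test_too_few_beats_rejected(self):
        rr = RRSeries.from_intervals([800.0, 900.0])
        with pytest.raises(ValueError, match="too few beats"):
            resample_tachogram(rr, (0.0, 1.7))

    def test_window_outside_recording_rejected(self):
        rr = RRSeries.from_intervals([800.0] * 10)
        with pytest.raises(ValueError, match="outside recording"):
            resample_tachogram(rr, (0.0, 30.0))


class TestBurg:
    def test_ar1_coefficient_recovered(self):
        x = simulate_ar([-0.5], 2048, seed=1)
        model = fit_burg(x, 1)
        assert model.coefficients[0] == pytest.approx(-0.5, abs=0.05)

    def test_matches_statsmodels_burg(self):
        from statsmodels.regression.linear_model import burg as sm_burg

        x = simulate_ar([-0.6, 0.3], 1024, seed=2)
        model = fit_burg(x, 4)
        rho, _ = sm_burg(x, 4, demean=False)
        np.testing.assert_allclose(model.coefficients, -rho, atol=1e-10)

    def test_white_noise_gives_small_coefficients(self, rng):
        x = rng.normal(0, 1, 4096)
        model = fit_burg(x, 8)
        assert np.max(np.abs(model.coefficients)) < 0.08

    def test_innovation_variance_non_increasing_in_order(self, rng):
        x = simulate_ar([-0.6, 0.3], 1024, seed=3)
        variances = [fit_burg(x, p).innovation_variance for p in range(1, 10)]
        assert np.all(np.diff(variances) <= 1e-12)

    def test_fitted_model_always_stable(self, rng):
        for seed in range(5):
            x = np.random.default_rng(seed).normal(0, 1, 256)
            assert fit_burg(x, 12).is_stable()

    def test_order_too_large_rejected(self):
        with pytest.raises(ValueError, match="order"):
            fit_burg(np.arange(10.0), 10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_burg(np.full(100, 5.0), 4)


class TestARPSD:
    def test_ar0_density_flat_at_one_sided_noise_level(self):
        model = ARModel(order=0, coefficients=[], innovation_variance=2.0)
        spec = ar_psd(model, rate=4.0)
        np.testing.assert_allclose(spec.density, 2.0 * 2.0 / 4.0)

    def test_resonant_ar2_peaks_at_pole_frequency(self):
        # poles at radius 0.98, angle 2*pi*f0/rate -> spectral peak at f0
        f0, rate, r = 0.1, 4.0, 0.98
        theta = 2 * np.pi * f0 / rate
        a = np.array([-2 * r * np.cos(theta), r**2])
        spec = ar_psd(ARModel(order=2, coefficients=a, innovation_variance=1.0), rate)
        f_peak = spec.frequencies[np.argmax(spec.density)]
        assert abs(f_peak - f0) <= 0.001 + 1e-12

    def test_unstable_model_rejected(self):
        bad = ARModel(order=1, coefficients=[-1.1], innovation_variance=1.0)
        with pytest.raises(ValueError, match="unstable"):
            ar_psd(bad, rate=4.0)

    def test_parseval_total_power_matches_variance(self):
        x = simulate_ar([-0.6, 0.3], 4096, seed=4)
        model = fit_burg(x, 2)
        spec = ar_psd(model, rate=4.0)
        assert spec.total_power == pytest.approx(np.var(x), rel=0.05)

    @given(
        ks=st.lists(
            st.floats(min_value=-0.9, max_value=0.9, allow_nan=False),
            min_size=1,
            max_size=8,
        ),
        sigma2=st.floats(min_value=1e-6, max_value=1e3),
    )
    def test_psd_nonnegative_for_any_stable_model(self, ks, sigma2):
        a = reflection_to_ar(ks)
        model = ARModel(order=a.size, coefficients=a, innovation_variance=sigma2)
        assert model.is_stable()
        spec = ar_psd(model, rate=4.0, grid_step=0.01)
        assert np.all(spec.density >= 0)


class TestBandPower:
    def test_zero_spectrum_integrates_to_zero(self):
        spec = PowerSpectrum(np.linspace(0, 2, 201), np.zeros(201))
        assert band_power(spec, LF_BAND) == 0.0

    def test_band_additivity(self):
        x = simulate_ar([-0.5], 1024, seed=5)
        spec = ar_psd(fit_burg(x, 8), rate=4.0)
        total = band_power(spec, Band(0.04, 0.4))
        assert band_power(spec, LF_BAND) + band_power(spec, HF_BAND) == pytest.approx(
            total, rel=1e-9
        )

    def test_band_outside_grid_rejected(self):
        spec = PowerSpectrum(np.linspace(0, 1, 101), np.ones(101))
        with pytest.raises(ValueError, match="outside"):
            band_power(spec, Band(0.5, 1.5))

    def test_lf_sinusoid_lands_in_lf_band_only(self):
        # 0.1 Hz modulation, amplitude 50 ms -> LF ~ 1250 ms^2, HF ~ noise
        rr = simulate_rr(
            stationary_params(lf_amp=50.0, hf_amp=0.0, noise_sd=2.0), seed=6
        )
        out = resample_tachogram(rr, (10.0, 70.0))
        spec = ar_psd(fit_burg(out, 24), out.rate)
        lf = band_power(spec, LF_BAND)
        hf = band_power(spec, HF_BAND)
        assert lf == pytest.approx(50.0**2 / 2, rel=0.2)
        assert lf / max(hf, 1e-12) > 20


class TestMeanHR:
    @pytest.mark.parametrize(
        "intervals,expected",
        [([1000.0] * 10, 60.0), ([800.0] * 10, 75.0), ([750.0, 850.0] * 5, 75.0)],
    )
    def test_mean_hr_from_intervals(self, intervals, expected):
        rr = RRSeries.from_intervals(intervals)
        assert mean_hr(rr, (0.0, rr.beat_times[-1])) == pytest.approx(expected)

    def test_too_few_beats_rejected(self):
        rr = RRSeries.from_intervals([800.0] * 10)
        with pytest.raises(ValueError, match="too few beats"):
            mean_hr(rr, (0.0, 0.5))


class TestSlidingHRV:
    def test_timestamp_grid_every_two_seconds(self):
        rr = RRSeries.from_intervals([1000.0] * 320)  # exactly 320 s
        idx = sliding_hrv(rr, SpectralConfig(ar_order=8))
        np.testing.assert_allclose(idx.timestamps, np.arange(30.0, 321.0, 2.0))
        assert idx.timestamps.size == 146

    def test_stationary_modulation_gives_stable_traces(self):
        rr = simulate_rr(stationary_params(noise_sd=2.0), seed=7)
        idx = sliding_hrv(rr)
        hf = idx.hf[idx.valid]
        lf = idx.lf[idx.valid]
        assert np.std(hf) / np.mean(hf) < 0.10
        assert np.std(lf) / np.mean(lf) < 0.10

    def test_halved_amplitude_quarters_hf_power(self):
        from hrvscreen import ProtocolSchedule
        from hrvscreen.signal_io import ProtocolState
        from hrvscreen import StateProfile, SubjectParams

        # hf_amp drops from 40 to 20 ms at t = 150 s -> HF power drops ~4x
        params = SubjectParams(
            mean_rr=StateProfile(800, 800, 800),
            lf_amp=StateProfile(15, 15, 15),
            hf_amp=StateProfile(40, 20, 20),
            noise_sd=2.0,
        )
        sched = ProtocolSchedule(
            [
                ProtocolState("rest_before", 0, 150),
                ProtocolState("task", 150, 75),
                ProtocolState("rest_after", 225, 75),
            ]
        )
        rr = simulate_rr(params, sched, seed=8)
        idx = sliding_hrv(rr)
        early = idx.valid & (idx.timestamps <= 140)
        late = idx.valid & (idx.timestamps >= 190)  # settled past transition
        ratio = np.mean(idx.hf[early]) / np.mean(idx.hf[late])
        assert ratio == pytest.approx(4.0, rel=0.3)

    def test_short_recording_rejected(self):
        rr = RRSeries.from_intervals([800.0] * 10)
        with pytest.raises(ValueError, match="shorter than one"):
            sliding_hrv(rr)
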