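import math

import numpy as np
import pytest

from cardiovar import (
    BeatSeries,
    SimulationSpec,
    band_power,
    compute_psd,
    compute_spectral_indices,
    normalized_units,
    resample_even,
    simulate_beat_series,
)
from cardiovar.errors import ConfigurationError, LengthError
from cardiovar.spectral import EvenSeries


def _sine_series(freq, amp=10.0, duration=600.0):
    spec = SimulationSpec(
        duration=duration, lf_amp_pi=0, hf_amp_pi=0, lf_amp_sap=0, hf_amp_sap=0,
        noise_sd_pi=0, noise_sd_sap=0,
    )
    if 0.2 <= freq <= 0.75:
        spec = spec.with_overrides(lf_amp_pi=amp, lf_freq=freq)
    else:
        spec = spec.with_overrides(hf_amp_pi=amp, hf_freq=freq)
    beats, _ = simulate_beat_series(spec)
    return beats


class TestResample:
    def test_constant_series_stays_constant(self, quiet_spec):
        beats, _ = simulate_beat_series(quiet_spec)
        even = resample_even(beats, "pi", 10.0)
        np.testing.assert_allclose(even.values, 200.0, rtol=1e-9)

    def test_sinusoid_tracked_by_interpolant(self):
        beats = _sine_series(0.4, duration=120.0)
        even = resample_even(beats, "pi", 10.0)
        grid = even.origin + np.arange(even.values.size) / even.rate
        analytic = 170.0 + 10.0 * np.sin(2 * math.pi * 0.4 * grid)
        r = np.corrcoef(even.values, analytic)[0, 1]
        assert r > 0.999

    def test_three_beats_is_too_short(self):
        beats = BeatSeries(np.array([0.0, 0.17, 0.34]), np.array([120.0] * 3))
        with pytest.raises(LengthError):
            resample_even(beats, "pi", 10.0)

    def test_sub_nyquist_rate_rejected(self, default_series):
        with pytest.raises(ConfigurationError):
            resample_even(default_series[0], "pi", 5.0)


class TestPsd:
    def test_white_noise_parseval(self, rng):
        sigma = 3.0
        x = rng.normal(0, sigma, 6000)
        freqs, psd = compute_psd(EvenSeries(x, 10.0, 0.0))
        total = np.trapezoid(psd, freqs)
        assert total == pytest.approx(sigma**2, rel=0.10)

    def test_sinusoid_power_concentrates_at_its_frequency(self):
        t = np.arange(6000) / 10.0
        amp = 4.0
        x = amp * np.sin(2 * math.pi * 0.4 * t)
        freqs, psd = compute_psd(EvenSeries(x, 10.0, 0.0))
        near = band_power(freqs, psd, (0.35, 0.45))
        assert near == pytest.approx(amp**2 / 2, rel=0.05)

    def test_constant_series_has_no_power(self):
        freqs, psd = compute_psd(EvenSeries(np.full(2000, 170.0), 10.0, 0.0))
        assert np.trapezoid(psd, freqs) < 1e-12

    def test_short_series_falls_back_to_single_segment(self, rng):
        x = rng.normal(0, 1, 100)
        freqs, psd = compute_psd(EvenSeries(x, 10.0, 0.0), segment_len=512)
        assert freqs.size == 51  # 100-sample periodogram


class TestBandPower:
    def test_full_band_equals_total(self, rng):
        x = rng.normal(0, 2, 4000)
        freqs, psd = compute_psd(EvenSeries(x, 10.0, 0.0))
        full = band_power(freqs, psd, (freqs[0], freqs[-1]))
        assert full == pytest.approx(float(np.trapezoid(psd, freqs)), rel=1e-12)

    def test_partition_additivity(self, rng):
        # below-LF + LF + HF tiles [0, 3.0) exactly
        for _ in range(5):
            x = rng.normal(0, 1, 3000)
            freqs, psd = compute_psd(EvenSeries(x, 10.0, 0.0))
            parts = (band_power(freqs, psd, (0.0, 0.2))
                     + band_power(freqs, psd, (0.2, 0.75))
                     + band_power(freqs, psd, (0.75, 3.0)))
            total = band_power(freqs, psd, (0.0, 3.0))
            assert parts == pytest.approx(total, rel=1e-9)

    def test_empty_band_is_zero(self, rng):
        freqs, psd = compute_psd(EvenSeries(rng.normal(0, 1, 1000), 10.0, 0.0))
        assert band_power(freqs, psd, (6.0, 7.0)) == 0.0


class TestNormalizedUnits:
    @pytest.mark.parametrize("lf,hf,expected", [
        (2.0, 2.0, (50.0, 50.0, 1.0)),
        (3.0, 1.0, (75.0, 25.0, 3.0)),
        (0.0, 5.0, (0.0, 100.0, 0.0)),
    ])
    def test_arithmetic(self, lf, hf, expected):
        assert normalized_units(lf, hf) == pytest.approx(expected)

    def test_zero_total_is_undefined(self):
        assert normalized_units(0.0, 0.0) == (None, None, None)

    def test_zero_hf_flags_infinite_ratio(self):
        lf_nu, hf_nu, ratio = normalized_units(5.0, 0.0)
        assert lf_nu == 100.0 and hf_nu == 0.0
        assert math.isinf(ratio)


class TestSpectralChain:
    def test_lf_sinusoid_recovery(self):
        beats = _sine_series(0.4, amp=10.0)
        si = compute_spectral_indices(beats, "pi")
        assert si.lf_power == pytest.approx(50.0, rel=0.05)
        assert si.hf_nu < 5.0
        assert si.lf_nu + si.hf_nu == pytest.approx(100.0, abs=1e-9)

    def test_hf_sinusoid_recovery(self):
        beats = _sine_series(1.5, amp=10.0)
        si = compute_spectral_indices(beats, "pi")
        assert si.hf_nu > 95.0

    @pytest.mark.parametrize("freq,band", [
        (0.3, "lf"), (0.5, "lf"), (1.0, "hf"), (2.0, "hf"), (2.8, "hf"),
    ])
    def test_single_oscillation_lands_in_its_band(self, freq, band):
        si = compute_spectral_indices(_sine_series(freq), "pi")
        total = si.below_lf_power + si.lf_power + si.hf_power
        in_band = si.lf_power if band == "lf" else si.hf_power
        assert in_band / total >= 0.90

    def test_monotone_amplitude_ladder(self):
        powers = []
        for amp in (5.0, 10.0, 20.0):
            si = compute_spectral_indices(_sine_series(0.4, amp=amp), "pi")
            assert si.lf_power == pytest.approx(amp**2 / 2, rel=0.15)
            powers.append(si.lf_power)
        assert powers[0] < powers[1] < powers[2]

    def test_sap_lf_power_monotone_in_injected_amplitude(self):
        powers = []
        for amp in (1.0, 3.0, 6.0):
            spec = SimulationSpec(duration=300, lf_amp_sap=amp, seed=21)
            beats, _ = simulate_beat_series(spec)
            powers.append(compute_spectral_indices(beats, "sap").lf_power)
        assert powers[0] < powers[1] < powers[2]
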