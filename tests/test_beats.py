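import numpy as np
import pytest

from cardiovar import (
    BeatSeries,
    PressureWaveform,
    SimulationSpec,
    compute_map,
    detect_beats,
    select_stable_segment,
    simulate_beat_series,
    simulate_waveform,
)
from cardiovar.errors import DetectionError, LengthError


class TestDetectBeats:
    def test_constant_pressure_has_no_pulsatility(self):
        wf = PressureWaveform(np.full(4000, 120.0), 2000.0)
        with pytest.raises(DetectionError, match="pulse pressure"):
            detect_beats(wf)

    def test_alternating_sap_recovered_within_half_mmhg(self):
        spec = SimulationSpec(duration=60, mean_sap=125.0, pulse_pressure=40.0,
                              noise_sd_pi=0, noise_sd_sap=0,
                              lf_amp_sap=0, hf_amp_sap=0)
        waveform, truth = simulate_waveform(spec, 2000.0)
        # rescale each pulse so SAP alternates 120/130 mmHg around a fixed
        # diastolic floor of 85 mmHg
        idx = np.round(truth.beat_times * 2000).astype(int)
        alt = np.where(np.arange(idx.size) % 2 == 0, 120.0, 130.0)
        samples = waveform.samples.copy()
        onsets = np.maximum(idx - 60, 0)  # pulse onset = peak - upstroke
        bounds = np.concatenate([[0], onsets[1:], [samples.size]])
        floor = 85.0
        for k in range(idx.size):
            seg = slice(bounds[k], bounds[k + 1])
            samples[seg] = floor + (samples[seg] - floor) * (alt[k] - floor) / (125.0 - floor)
        waveform2 = PressureWaveform(samples, 2000.0)
        beats = detect_beats(waveform2)
        assert beats.n_beats == idx.size
        assert np.abs(beats.sap - alt).max() <= 0.5

    def test_beat_count_robust_to_small_noise(self, rng):
        spec = SimulationSpec(duration=60, noise_sd_pi=0, noise_sd_sap=0)
        waveform, truth = simulate_waveform(spec, 2000.0)
        clean = detect_beats(waveform).n_beats
        noisy_samples = waveform.samples + rng.normal(
            0, 0.02 * spec.pulse_pressure, waveform.n_samples
        )
        noisy = detect_beats(PressureWaveform(noisy_samples, 2000.0)).n_beats
        assert noisy == clean

    def test_hr_pi_unit_consistency(self, default_series):
        beats, _ = default_series
        np.testing.assert_allclose(beats.hr * beats.pi, 60000.0, rtol=1e-12)


class TestComputeMap:
    def _waveform_with_beats(self, samples, fs, peak_idx):
        wf = PressureWaveform(samples, fs)
        times = peak_idx / fs
        return wf, BeatSeries(times, samples[peak_idx])

    def test_square_wave_map_is_arithmetic_mean(self):
        # Half the beat at 140, half at 100 -> MAP 120.
        beat = np.concatenate([np.full(100, 140.0), np.full(100, 100.0)])
        samples = np.tile(beat, 5)
        wf, beats = self._waveform_with_beats(samples, 1000.0,
                                              np.arange(5) * 200)
        np.testing.assert_allclose(compute_map(wf, beats), 120.0)

    def test_constant_between_peaks(self):
        samples = np.full(1000, 120.0)
        samples[::200] = 121.0
        wf, beats = self._waveform_with_beats(samples, 1000.0,
                                              np.arange(5) * 200)
        expected = (121.0 + 199 * 120.0) / 200
        np.testing.assert_allclose(compute_map(wf, beats), expected)

    def test_map_bounded_by_beat_extremes(self):
        spec = SimulationSpec(duration=30, noise_sd_pi=0, noise_sd_sap=0)
        waveform, truth = simulate_waveform(spec, 2000.0)
        beats = detect_beats(waveform)
        m = compute_map(waveform, beats)
        diastolic = truth.true_sap[: m.size] - spec.pulse_pressure
        assert np.all(m <= beats.sap[:-1] + 1e-9)
        assert np.all(m >= diastolic - 1e-9)


class TestSelectStableSegment:
    def test_stationary_series_picks_earliest_window(self, quiet_spec):
        beats, _ = simulate_beat_series(quiet_spec)
        sel = select_stable_segment(beats, 30.0)
        assert sel.start_index == 0

    def test_transient_window_is_avoided(self):
        spec = SimulationSpec(duration=300, seed=9)
        beats, _ = simulate_beat_series(spec)
        sap = beats.sap.copy()
        # 30-s pressure transient in the middle of the recording
        hit = (beats.beat_times > 130) & (beats.beat_times < 160)
        sap[hit] += 40.0 * np.sin(np.linspace(0, np.pi, hit.sum()))
        noisy = BeatSeries(beats.beat_times, sap)
        sel = select_stable_segment(noisy, 120.0)
        t0 = noisy.beat_times[sel.start_index]
        t1 = noisy.beat_times[sel.end_index - 1]
        assert t1 < 130 or t0 > 160

    def test_full_series_duration_returns_whole_series(self, quiet_spec):
        beats, _ = simulate_beat_series(quiet_spec)
        sel = select_stable_segment(beats, beats.duration)
        assert sel.start_index == 0
        assert sel.end_index == beats.n_beats
        assert sel.duration == pytest.approx(beats.duration)

    def test_requested_duration_respected_within_tolerance(self, default_series):
        beats, _ = default_series
        sel = select_stable_segment(beats, 120.0)
        assert 0.8 * 120 <= sel.duration <= 1.2 * 120

    def test_too_short_series_raises(self, quiet_spec):
        beats, _ = simulate_beat_series(quiet_spec)
        with pytest.raises(LengthError):
            select_stable_segment(beats, beats.duration + 10)
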