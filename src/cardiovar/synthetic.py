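"""Synthetic rat arterial-pressure recordings with known modulation structure.

The generator emulates a ~10-min beat-to-beat recording from a conscious
rat: a pulse-interval (PI) tachogram and a systolic-pressure (SAP) series
carrying sinusoidal oscillations at chosen LF and HF frequencies, Gaussian
beat-to-beat noise, and optional slow baseline drift.  Beat times accumulate
from the modulated PI itself (an integral-pulse model), so the tachogram is
unevenly sampled exactly as a real one is — this exercises the resampling
stage of the spectral chain.

Because a sinusoid of amplitude A carries analytic power A^2/2, every
injected oscillation is a closed-form oracle for the spectral estimator.

The per-beat series can further be rendered into a full pulsatile pressure
waveform (rapid systolic upstroke, exponential diastolic decay), with the
systolic peak of every pulse at a known, sample-aligned time — the oracle
for beat detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .config import DEFAULT_HF_BAND, DEFAULT_LF_BAND
from .errors import ConfigurationError, SimulationError
from .types import BeatSeries, PressureWaveform

#: Systolic upstroke time of the rendered pulse template, seconds.
UPSTROKE_S = 0.030


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a synthetic recording.

    Defaults mimic a normotensive (Wistar-like) rat: mean PI 170 ms
    (~353 bpm), mean SAP 130 mmHg, modest LF/HF modulation and beat-to-beat
    noise.  Use :func:`shr_like` for a hypertensive-strain preset.

    Attributes
    ----------
    duration : s
    mean_pi : ms
    mean_sap : mmHg
    lf_amp_pi, hf_amp_pi : ms
        Amplitudes of the PI oscillations at ``lf_freq`` / ``hf_freq``.
    lf_amp_sap, hf_amp_sap : mmHg
        Amplitudes of the SAP oscillations at the same frequencies.
    lf_freq, hf_freq : Hz
        Must fall inside the rat LF (0.20-0.75) and HF (>0.75-3.00) bands.
    noise_sd_pi : ms, noise_sd_sap : mmHg
        SD of independent Gaussian beat-to-beat noise.
    drift_amp_sap : mmHg
        Amplitude scale of slow (<0.05 Hz) 1/f-like baseline drift of SAP;
        0 disables it.
    pulse_pressure : mmHg
        SAP minus diastolic pressure of the rendered pulse template.
    seed
        Seeds the noise and the HF phase (the phase is randomized to avoid
        phase-locking artifacts between the two oscillations).
    """

    duration: float = 600.0
    mean_pi: float = 170.0
    mean_sap: float = 130.0
    lf_amp_pi: float = 4.0
    lf_freq: float = 0.4
    hf_amp_pi: float = 6.0
    hf_freq: float = 1.5
    lf_amp_sap: float = 3.0
    hf_amp_sap: float = 1.0
    noise_sd_pi: float = 2.0
    noise_sd_sap: float = 1.5
    drift_amp_sap: float = 0.0
    pulse_pressure: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.mean_pi <= 0 or self.mean_sap <= 0:
            raise SimulationError("duration, mean_pi and mean_sap must be positive")
        if not DEFAULT_LF_BAND[0] <= self.lf_freq <= DEFAULT_LF_BAND[1]:
            raise SimulationError(f"lf_freq {self.lf_freq} Hz outside LF band {DEFAULT_LF_BAND}")
        if not DEFAULT_HF_BAND[0] < self.hf_freq <= DEFAULT_HF_BAND[1]:
            raise SimulationError(f"hf_freq {self.hf_freq} Hz outside HF band {DEFAULT_HF_BAND}")
        for name in ("lf_amp_pi", "hf_amp_pi", "lf_amp_sap", "hf_amp_sap",
                     "noise_sd_pi", "noise_sd_sap", "drift_amp_sap"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.lf_amp_pi + self.hf_amp_pi >= self.mean_pi:
            raise SimulationError("PI oscillation amplitudes reach the mean: negative PIs")
        if self.lf_amp_sap + self.hf_amp_sap + self.drift_amp_sap >= self.mean_sap:
            raise SimulationError("SAP oscillation amplitudes reach the mean")
        if not 0 < self.pulse_pressure < self.mean_sap:
            raise SimulationError("pulse_pressure must lie in (0, mean_sap)")

    def with_overrides(self, **kwargs) -> "SimulationSpec":
        return replace(self, **kwargs)


def shr_like(**overrides) -> SimulationSpec:
    """Preset resembling the spontaneously hypertensive rat (SAP ~180 mmHg)."""
    base = dict(mean_sap=180.0, mean_pi=160.0, lf_amp_sap=4.0, pulse_pressure=50.0)
    base.update(overrides)
    return SimulationSpec(**base)


@dataclass(frozen=True)
class GroundTruth:
    """What was actually injected, for checking what the pipeline recovers.

    ``lf_power_pi`` etc. are the analytic powers A^2/2 of the injected
    sinusoids.  For waveform simulations, ``beat_times`` are the systolic
    *peak* times of the rendered pulses (what a peak detector should find),
    one per rendered pulse.
    """

    beat_times: np.ndarray
    true_pi: np.ndarray
    true_sap: np.ndarray
    lf_power_pi: float
    hf_power_pi: float
    lf_power_sap: float
    hf_power_sap: float


def _drift(times: np.ndarray, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Slow 1/f-like baseline wander: a few sub-0.05 Hz sinusoids."""
    if amp == 0:
        return np.zeros_like(times)
    freqs = np.array([0.005, 0.012, 0.023, 0.041])
    phases = rng.uniform(0, 2 * math.pi, size=freqs.size)
    weights = amp / (1.0 + freqs / freqs[0])
    out = np.zeros_like(times)
    for f, p, w in zip(freqs, phases, weights):
        out += w * np.sin(2 * math.pi * f * times + p)
    return out


def simulate_beat_series(spec: SimulationSpec) -> tuple[BeatSeries, GroundTruth]:
    """Generate a beat series by integral-pulse accumulation.

    Beat k+1 occurs one (modulated) pulse interval after beat k::

        PI_k = mean_pi + lf_amp_pi sin(2 pi f_LF t_k)
                       + hf_amp_pi sin(2 pi f_HF t_k + phi) + noise_k
        t_{k+1} = t_k + PI_k / 1000

    SAP is built analogously at the beat times.  Deterministic given
    ``spec.seed``.

    Returns the series and its :class:`GroundTruth`.  Raises
    :class:`SimulationError` if any generated PI is non-positive.
    """
    rng = np.random.default_rng(spec.seed)
    phi = rng.uniform(0, 2 * math.pi)
    two_pi = 2 * math.pi

    times = [0.0]
    pis: list[float] = []
    t = 0.0
    # Guard: even an all-noise spec cannot emit more beats than this.
    max_beats = int(spec.duration * 1000 / max(spec.mean_pi / 4, 1.0)) + 2
    while len(times) < max_beats:
        pi_ms = (
            spec.mean_pi
            + spec.lf_amp_pi * math.sin(two_pi * spec.lf_freq * t)
            + spec.hf_amp_pi * math.sin(two_pi * spec.hf_freq * t + phi)
        )
        if spec.noise_sd_pi > 0:
            pi_ms += rng.normal(0.0, spec.noise_sd_pi)
        if pi_ms <= 0:
            raise SimulationError(
                f"spec produced non-positive PI ({pi_ms:.3f} ms) at t={t:.3f} s"
            )
        t_next = t + pi_ms / 1000.0
        if t_next > spec.duration + 1e-9:
            break
        times.append(t_next)
        pis.append(pi_ms)
        t = t_next

    if len(times) < 2:
        raise SimulationError("duration too short for even two beats")

    beat_times = np.asarray(times)
    sap = (
        spec.mean_sap
        + spec.lf_amp_sap * np.sin(two_pi * spec.lf_freq * beat_times)
        + spec.hf_amp_sap * np.sin(two_pi * spec.hf_freq * beat_times + phi)
    )
    if spec.noise_sd_sap > 0:
        sap = sap + rng.normal(0.0, spec.noise_sd_sap, size=sap.size)
    sap = sap + _drift(beat_times, spec.drift_amp_sap, rng)
    if np.any(sap <= 0):
        raise SimulationError("spec produced non-positive SAP")

    truth = GroundTruth(
        beat_times=beat_times,
        true_pi=np.asarray(pis),
        true_sap=sap.copy(),
        lf_power_pi=spec.lf_amp_pi**2 / 2,
        hf_power_pi=spec.hf_amp_pi**2 / 2,
        lf_power_sap=spec.lf_amp_sap**2 / 2,
        hf_power_sap=spec.hf_amp_sap**2 / 2,
    )
    return BeatSeries(beat_times, sap), truth


def simulate_waveform(
    spec: SimulationSpec, sampling_rate: float = 2000.0
) -> tuple[PressureWaveform, GroundTruth]:
    """Render the beat series as a pulsatile pressure waveform.

    Each pulse rises over ``UPSTROKE_S`` (half-sine) from the previous
    diastolic level to its SAP, then decays exponentially toward
    ``SAP - pulse_pressure``.  The systolic peak of pulse k is snapped to
    the sample grid and carries exactly ``SAP_k``, so the returned ground
    truth gives peak times a detector must recover to within one sample.
    """
    if sampling_rate < 100:
        raise ConfigurationError("sampling_rate must be >= 100 Hz")
    if sampling_rate * UPSTROKE_S < 3:
        raise ConfigurationError(
            f"sampling_rate {sampling_rate} Hz cannot resolve the "
            f"{UPSTROKE_S * 1000:.0f} ms systolic upstroke"
        )
    beats, truth = simulate_beat_series(spec)
    fs = sampling_rate
    t_last = beats.beat_times[-1]
    n_samples = int(round(t_last * fs))

    diastolic_floor = spec.mean_sap - spec.pulse_pressure
    samples = np.full(n_samples, diastolic_floor)
    n_pulses = beats.n_beats - 1
    peak_times = np.empty(n_pulses)
    prev_end = truth.true_sap[0] - spec.pulse_pressure

    idx = np.arange(n_samples)
    grid_t = idx / fs
    for k in range(n_pulses):
        t0, t1 = beats.beat_times[k], beats.beat_times[k + 1]
        s_k = truth.true_sap[k]
        d_k = s_k - spec.pulse_pressure
        i0 = int(np.ceil(t0 * fs - 1e-9))
        i1 = min(int(np.ceil(t1 * fs - 1e-9)), n_samples)
        if i1 <= i0:
            continue
        tau = grid_t[i0:i1] - t0
        seg = np.empty(i1 - i0)
        rising = tau < UPSTROKE_S
        seg[rising] = prev_end + (s_k - prev_end) * np.sin(
            math.pi * tau[rising] / (2 * UPSTROKE_S)
        )
        tau_c = (t1 - t0) / 3.0
        seg[~rising] = d_k + (s_k - d_k) * np.exp(-(tau[~rising] - UPSTROKE_S) / tau_c)
        samples[i0:i1] = seg
        prev_end = d_k + (s_k - d_k) * math.exp(-((t1 - t0) - UPSTROKE_S) / tau_c)
        peak_idx = min(int(round((t0 + UPSTROKE_S) * fs)), n_samples - 1)
        samples[peak_idx] = s_k
        peak_times[k] = peak_idx / fs

    waveform = PressureWaveform(samples, fs, unit="mmHg")
    wf_truth = GroundTruth(
        beat_times=peak_times,
        true_pi=truth.true_pi,
        true_sap=truth.true_sap[:n_pulses],
        lf_power_pi=truth.lf_power_pi,
        hf_power_pi=truth.hf_power_pi,
        lf_power_sap=truth.lf_power_sap,
        hf_power_sap=truth.hf_power_sap,
    )
    return waveform, wf_truth
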