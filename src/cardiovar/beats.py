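"""Systolic-peak detection and stable-segment selection.

From the pulsatile arterial pressure (PAP) waveform, each cardiac cycle is
reduced to its systolic peak: the peak time is the beat fiducial, the peak
value is the SAP of the beat, and the peak-to-peak interval is the pulse
interval (PI).  Mean arterial pressure (MAP) per beat is the true time
average of the waveform over the beat window.  A stable window of the
requested duration — the quiet stretch an experimenter would pick by eye —
is selected by minimizing rank-normalized rolling variances of PI and SAP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .errors import DetectionError, LengthError
from .types import BeatSeries, PressureWaveform

logger = logging.getLogger(__name__)

#: Adaptive prominence threshold: fraction of the rolling median pulse amplitude.
PROMINENCE_FRACTION = 0.4
#: Window (s) for the rolling median of pulse amplitudes.
PROMINENCE_WINDOW_S = 5.0
#: Minimum resolvable pulse pressure, mmHg.
MIN_PULSE_PRESSURE = 1.0


def detect_beats(
    waveform: PressureWaveform,
    min_rate: float = 200.0,
    max_rate: float = 500.0,
) -> BeatSeries:
    """Detect systolic peaks and build the beat series.

    A refractory period of ``60000/max_rate`` ms is enforced between
    beats.  The prominence threshold adapts to the recording:
    ``PROMINENCE_FRACTION`` times the rolling median pulse amplitude over
    ``PROMINENCE_WINDOW_S``-second windows, so slow drift or a change in
    gain does not require an absolute mmHg constant.

    Raises :class:`DetectionError` if the trace has no resolvable
    pulsatility or no peaks survive thresholding.
    """
    if not 0 < min_rate < max_rate:
        raise DetectionError(f"need 0 < min_rate < max_rate, got {min_rate}, {max_rate}")
    x = waveform.samples
    fs = waveform.sampling_rate
    span = float(np.ptp(x))
    if span < MIN_PULSE_PRESSURE:
        raise DetectionError(
            f"pulse pressure below resolvable threshold ({span:.3f} mmHg peak-to-peak)"
        )
    refractory = int(round(60.0 / max_rate * fs))
    # First pass: permissive prominence to estimate per-beat pulse amplitudes.
    candidates, props = signal.find_peaks(x, distance=max(refractory, 1),
                                          prominence=0.05 * span)
    if candidates.size == 0:
        raise DetectionError("no peaks found")
    prominences = props["prominences"]
    # Rolling median pulse amplitude, evaluated at each candidate peak.
    half = PROMINENCE_WINDOW_S / 2.0
    times = candidates / fs
    thresholds = np.empty(candidates.size)
    for i, t in enumerate(times):
        in_win = (times >= t - half) & (times <= t + half)
        thresholds[i] = PROMINENCE_FRACTION * np.median(prominences[in_win])
    keep = prominences >= thresholds
    peaks = candidates[keep]
    n_rejected = int(candidates.size - peaks.size)
    if peaks.size < 2:
        raise DetectionError("fewer than 2 peaks survive the prominence threshold")
    logger.info("detected %d beats (%d candidates rejected by adaptive prominence)",
                peaks.size, n_rejected)

    beat_times = waveform.start_time + peaks / fs
    sap = x[peaks]
    map_vals = _map_between_peaks(x, peaks)
    return BeatSeries(beat_times, sap, map_vals)


def _map_between_peaks(x: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    cumsum = np.concatenate([[0.0], np.cumsum(x)])
    starts, stops = peaks[:-1], peaks[1:]
    return (cumsum[stops] - cumsum[starts]) / (stops - starts)


def compute_map(waveform: PressureWaveform, beats: BeatSeries) -> np.ndarray:
    """Per-beat mean arterial pressure: time-average over [t_k, t_{k+1}).

    Time averaging the sampled waveform is exact for the data at hand, in
    contrast to the diastolic + pulse-pressure/3 estimator used with cuff
    measurements.
    """
    fs = waveform.sampling_rate
    idx = np.round((beats.beat_times - waveform.start_time) * fs).astype(int)
    if np.any(idx < 0) or np.any(idx >= waveform.n_samples):
        raise IndexError("beat times fall outside the waveform")
    if np.any(np.diff(idx) < 1):
        raise IndexError("empty beat window (beats closer than one sample)")
    return _map_between_peaks(waveform.samples, idx)


@dataclass(frozen=True)
class SegmentSelection:
    """A chosen analysis window: beat indices [start, end), span and score."""

    start_index: int
    end_index: int
    duration: float
    stability_score: float


def select_stable_segment(
    beats: BeatSeries,
    duration: float,
    window_beats: int = 32,
) -> SegmentSelection:
    """Pick the quietest contiguous window of roughly ``duration`` seconds.

    Stability of each beat is scored as the sum of the rank-normalized
    rolling variances (window ``window_beats``) of PI and of SAP; the
    candidate window with the lowest mean beat score wins, earliest window
    on ties.  Rank normalization makes the two channels commensurate
    without unit-dependent weights.

    Raises :class:`LengthError` if the series is shorter than ``duration``.
    """
    if beats.duration < duration - 1e-9:
        raise LengthError(
            f"series spans {beats.duration:.1f} s < requested segment {duration:.1f} s"
        )
    pi = beats.pi
    sap = beats.sap[:-1]
    n = pi.size
    w = min(window_beats, max(2, n // 4))
    roll_pi = _rolling_var(pi, w)
    roll_sap = _rolling_var(sap, w)
    score = _rank_normalize(roll_pi) + _rank_normalize(roll_sap)
    cum = np.concatenate([[0.0], np.cumsum(score)])

    times = beats.beat_times
    # For each start beat i, the first beat j with times[j] - times[i] >= duration
    # closes the window; beats i..j inclusive form the candidate.
    ends = np.searchsorted(times, times + duration - 1e-9, side="left")
    best: tuple[float, int, int] | None = None
    for i in range(beats.n_beats):
        j = ends[i]
        if j >= beats.n_beats:
            if times[-1] - times[i] >= duration - 1e-9:
                j = beats.n_beats - 1
            else:
                break
        mean_score = (cum[j] - cum[i]) / (j - i)
        if best is None or mean_score < best[0] - 1e-12:
            best = (mean_score, i, j)
    if best is None:
        raise LengthError("no candidate window of the requested duration")
    mean_score, i, j = best
    sel = SegmentSelection(int(i), int(j) + 1, float(times[j] - times[i]),
                           float(mean_score))
    logger.info("selected segment beats [%d, %d), %.1f s, score %.4f",
                sel.start_index, sel.end_index, sel.duration, sel.stability_score)
    return sel


def _rolling_var(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling variance, edges clamped."""
    n = x.size
    out = np.empty(n)
    half = window // 2
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    for i in range(n):
        a = max(0, i - half)
        b = min(n, i + half + 1)
        m = b - a
        mean = (c1[b] - c1[a]) / m
        out[i] = max((c2[b] - c2[a]) / m - mean * mean, 0.0)
    return out


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average") / x.size
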