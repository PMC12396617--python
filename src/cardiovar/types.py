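"""Core in-memory containers for arterial-pressure variability analysis.

Two objects flow through the pipeline:

``PressureWaveform``
    The uniformly sampled pulsatile arterial pressure (PAP) trace, in mmHg,
    as acquired from an indwelling catheter.

``BeatSeries``
    The per-beat series derived from it: systolic-peak times, systolic
    arterial pressure (SAP, mmHg) per beat, and the pulse interval
    (PI, ms) between successive systolic peaks — the blood-pressure
    analogue of the RR interval.  Heart rate follows as HR = 60000/PI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError


@dataclass(frozen=True)
class PressureWaveform:
    """Uniformly sampled arterial pressure trace.

    Parameters
    ----------
    samples
        Pressure samples in ``unit`` (mmHg by default).
    sampling_rate
        Sampling rate in Hz; the study's acquisition convention is 2 kHz.
    start_time
        Time of the first sample, seconds.
    unit
        Pressure unit tag.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    unit: str = "mmHg"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise DataError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if samples.ndim != 1 or samples.size < 2:
            raise DataError("waveform needs at least 2 samples in a 1-D array")
        bad = np.flatnonzero(~np.isfinite(samples))
        if bad.size:
            raise DataError(f"non-finite sample at index {bad[0]}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Span from first to last sample, seconds."""
        return (self.n_samples - 1) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class BeatSeries:
    """Per-beat series extracted from a pressure waveform.

    ``beat_times`` are systolic-peak times (s); ``sap`` is the systolic
    pressure at each peak (mmHg).  ``pi`` is derived: ``pi[k] =
    (beat_times[k+1] - beat_times[k]) * 1000`` ms, so ``len(pi) ==
    len(beat_times) - 1``.  ``map_mmhg``, when available (waveform input),
    is the per-interval time-average pressure.
    """

    beat_times: np.ndarray
    sap: np.ndarray
    map_mmhg: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        times = np.asarray(self.beat_times, dtype=float)
        sap = np.asarray(self.sap, dtype=float)
        object.__setattr__(self, "beat_times", times)
        object.__setattr__(self, "sap", sap)
        if times.size != sap.size:
            raise DataError("beat_times and sap must have equal length")
        if times.size < 2:
            raise DataError("a beat series needs at least 2 beats")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(sap)):
            raise DataError("beat series contains non-finite values")
        dt = np.diff(times)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            raise DataError(
                f"beat times must be strictly increasing; violation at beat {bad[0] + 1}"
            )
        if np.any(sap <= 0):
            raise DataError("SAP values must be positive")
        if self.map_mmhg is not None:
            m = np.asarray(self.map_mmhg, dtype=float)
            object.__setattr__(self, "map_mmhg", m)
            if m.size != times.size - 1:
                raise DataError("map_mmhg must have one value per pulse interval")

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)

    @property
    def pi(self) -> np.ndarray:
        """Pulse intervals in ms, one per pair of successive beats."""
        return np.diff(self.beat_times) * 1000.0

    @property
    def hr(self) -> np.ndarray:
        """Instantaneous heart rate, beats/min, one per pulse interval."""
        return 60000.0 / self.pi

    @property
    def duration(self) -> float:
        """Span from first to last beat, seconds."""
        return float(self.beat_times[-1] - self.beat_times[0])

    def slice_beats(self, start: int, stop: int) -> "BeatSeries":
        """Contiguous sub-series of beats ``start:stop`` (python slice bounds)."""
        m = None
        if self.map_mmhg is not None:
            m = self.map_mmhg[start : stop - 1]
        return BeatSeries(self.beat_times[start:stop], self.sap[start:stop], m)
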