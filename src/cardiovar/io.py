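"""Reading and writing the pipeline's plain-text file formats.

Two open dialects are used (acquisition-software exports are proprietary,
so a minimal text form suffices):

Waveform files
    One pressure sample per line (a single comma-separated line is also
    accepted), preceded by a two-line header::

        # sampling_rate_hz: 2000
        # unit: mmHg

Beat-series files
    Comma-delimited with header ``time_s,sap_mmhg,pi_ms``.  ``pi_ms`` of a
    row is the pulse interval closing at that beat, so the first row's PI
    field is empty (no preceding beat).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .types import BeatSeries, PressureWaveform

logger = logging.getLogger(__name__)

_WAVEFORM_RATE_KEY = "sampling_rate_hz"
_WAVEFORM_UNIT_KEY = "unit"

#: Canonical numeric formatting: shortest repr that round-trips a float64.
def _fmt(value: float) -> str:
    return np.format_float_positional(value, trim="0", unique=True)


def read_waveform(path: str | Path) -> PressureWaveform:
    """Parse a waveform file into a :class:`PressureWaveform`.

    Raises
    ------
    FormatError
        If the two-line header (sampling rate, unit) is missing or garbled.
    DataError
        If any sample is non-finite; the message names the first offending
        sample index.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    header: dict[str, str] = {}
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        try:
            key, value = line.lstrip("#").split(":", 1)
        except ValueError:
            raise FormatError(f"{path}: garbled header line {body_start}: {line!r}")
        header[key.strip()] = value.strip()
    if _WAVEFORM_RATE_KEY not in header or _WAVEFORM_UNIT_KEY not in header:
        raise FormatError(
            f"{path}: header must declare '{_WAVEFORM_RATE_KEY}' and '{_WAVEFORM_UNIT_KEY}'"
        )
    try:
        rate = float(header[_WAVEFORM_RATE_KEY])
    except ValueError:
        raise FormatError(f"{path}: unparsable sampling rate {header[_WAVEFORM_RATE_KEY]!r}")
    tokens: list[str] = []
    for line in lines[body_start:]:
        line = line.strip()
        if line:
            tokens.extend(t for t in line.split(",") if t.strip())
    try:
        samples = np.array([float(t) for t in tokens], dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: unparsable sample: {exc}")
    bad = np.flatnonzero(~np.isfinite(samples))
    if bad.size:
        raise DataError(f"{path}: non-finite sample at index {bad[0]}")
    try:
        return PressureWaveform(samples, rate, unit=header[_WAVEFORM_UNIT_KEY])
    except DataError as exc:
        raise DataError(f"{path}: {exc}")


def write_waveform(waveform: PressureWaveform, path: str | Path) -> None:
    """Write a waveform in the canonical dialect (round-trip lossless)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {_WAVEFORM_RATE_KEY}: {_fmt(waveform.sampling_rate)}\n")
        fh.write(f"# {_WAVEFORM_UNIT_KEY}: {waveform.unit}\n")
        for v in waveform.samples:
            fh.write(_fmt(v) + "\n")
    logger.info("wrote waveform: %d samples @ %g Hz -> %s", waveform.n_samples,
                waveform.sampling_rate, path)


BEAT_HEADER = ("time_s", "sap_mmhg", "pi_ms")


def read_beat_series(path: str | Path) -> BeatSeries:
    """Parse a beat-series CSV into a :class:`BeatSeries`.

    Beat times must be strictly increasing; a decreasing or duplicated time
    raises :class:`DataError` naming the offending (1-based, post-header)
    row.  The ``pi_ms`` column is redundant with the times and is checked
    only for gross inconsistency.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise FormatError(f"{path}: could not parse CSV: {exc}")
    if tuple(frame.columns[:3]) != BEAT_HEADER:
        raise FormatError(
            f"{path}: expected header {','.join(BEAT_HEADER)}, got {','.join(frame.columns)}"
        )
    times = frame["time_s"].to_numpy(dtype=float)
    sap = frame["sap_mmhg"].to_numpy(dtype=float)
    if times.size < 2:
        raise DataError(f"{path}: need at least 2 beats")
    if not np.all(np.isfinite(times)) or not np.all(np.isfinite(sap)):
        row = int(np.flatnonzero(~(np.isfinite(times) & np.isfinite(sap)))[0]) + 1
        raise DataError(f"{path}: non-finite time/SAP value at row {row}")
    dt = np.diff(times)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise DataError(
            f"{path}: beat times must be strictly increasing; row {bad[0] + 2} "
            f"(t={times[bad[0] + 1]}) does not advance"
        )
    if np.any(sap <= 0):
        row = int(np.flatnonzero(sap <= 0)[0]) + 1
        raise DataError(f"{path}: non-positive SAP at row {row}")
    pi_col = frame["pi_ms"].to_numpy(dtype=float)
    derived = dt * 1000.0
    stated = pi_col[1:]
    mism = np.isfinite(stated) & (np.abs(stated - derived) > 1.0)
    if np.any(mism):
        logger.warning("%s: %d pi_ms entries differ from time differences by >1 ms; "
                       "times take precedence", path, int(mism.sum()))
    return BeatSeries(times, sap)


def write_beat_series(beats: BeatSeries, path: str | Path) -> None:
    """Write a beat series as CSV (round-trip lossless for times and SAP)."""
    path = Path(path)
    pi = beats.pi
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(BEAT_HEADER) + "\n")
        for k in range(beats.n_beats):
            pi_field = "" if k == 0 else _fmt(pi[k - 1])
            fh.write(f"{_fmt(beats.beat_times[k])},{_fmt(beats.sap[k])},{pi_field}\n")
    logger.info("wrote beat series: %d beats -> %s", beats.n_beats, path)
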