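"""End-to-end analysis: waveform or beat series in, index report out.

``run_pipeline`` mirrors the study's processing chain: select a stable
~10-min segment of the beat series (extracted from the waveform first, if
that is the input), then compute, per channel,

* time domain — mean, SD, variance for SAP; those plus RMSSD for PI;
* frequency domain — LF/HF absolute powers, normalized units, LF/HF ratio
  for both PI and SAP (LF of SAP in mmHg^2 is the vascular sympathetic
  index);
* symbolic dynamics — 0V/1V/2LV/2UV/2V occurrence rates, PI only.

The report is a plain nested dict, JSON-serializable and byte-stable:
identical input and config give identical serialized reports.
"""

from __future__ import annotations

import json
import logging

import numpy as np

from .beats import detect_beats, select_stable_segment
from .config import PipelineConfig
from .errors import ConfigurationError
from .spectral import compute_spectral_indices
from .symbolic import analyze_symbolic
from .timedomain import compute_time_domain
from .types import BeatSeries, PressureWaveform

logger = logging.getLogger(__name__)


def _artifact_filter(beats: BeatSeries, threshold: float = 0.3) -> BeatSeries:
    """Reposition displaced (extrasystole-like) beats.

    A beat whose two adjacent pulse intervals both deviate from the median
    PI by more than ``threshold`` while their sum stays normal is a
    short-long couplet: the fiducial fired early (or late) but the rhythm
    is intact.  Such beats are moved to the midpoint of their neighbors.
    Other deviant intervals (missed or spurious detections) are only
    logged.  Off by default; enabled by ``config.artifact_correction``.
    """
    times = beats.beat_times.copy()
    pi = beats.pi
    med = float(np.median(pi))
    dev = np.abs(pi - med) > threshold * med
    moved = 0
    for k in range(1, times.size - 1):
        if dev[k - 1] and dev[k]:
            pair_sum = (times[k + 1] - times[k - 1]) * 1000.0
            if abs(pair_sum - 2 * med) <= threshold * 2 * med:
                times[k] = 0.5 * (times[k - 1] + times[k + 1])
                dev[k - 1] = dev[k] = False
                moved += 1
    if moved:
        logger.info("artifact correction repositioned %d displaced beats", moved)
    remaining = int(np.sum(dev))
    if remaining:
        logger.warning("%d deviant pulse intervals left uncorrected", remaining)
    if not moved:
        return beats
    return BeatSeries(times, beats.sap, beats.map_mmhg)


def run_pipeline(
    data: PressureWaveform | BeatSeries,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full variability analysis and return the report dict."""
    cfg = config or PipelineConfig()
    if isinstance(data, PressureWaveform):
        beats = detect_beats(data, cfg.min_rate, cfg.max_rate)
    elif isinstance(data, BeatSeries):
        beats = data
    else:
        raise TypeError(f"expected PressureWaveform or BeatSeries, got {type(data)}")

    if cfg.artifact_correction:
        beats = _artifact_filter(beats)

    if beats.duration < cfg.min_segment_duration:
        raise ConfigurationError(
            f"series spans {beats.duration:.1f} s, below the minimum analyzable "
            f"segment of {cfg.min_segment_duration:.1f} s"
        )
    target = min(cfg.segment_duration, beats.duration)
    sel = select_stable_segment(beats, target)
    segment = beats.slice_beats(sel.start_index, sel.end_index)
    logger.info("analyzing %d beats over %.1f s", segment.n_beats, segment.duration)

    pi = segment.pi
    sap = segment.sap
    spectral_pi = compute_spectral_indices(segment, "pi", cfg)
    spectral_sap = compute_spectral_indices(segment, "sap", cfg)
    symbolic = analyze_symbolic(pi, cfg.n_levels, cfg.pattern_length)

    report = {
        "segment": {
            "start_index": sel.start_index,
            "end_index": sel.end_index,
            "n_beats": segment.n_beats,
            "duration_s": round(segment.duration, 6),
            "mean_hr_bpm": float(np.mean(segment.hr)),
            "mean_map_mmhg": (
                float(np.mean(segment.map_mmhg)) if segment.map_mmhg is not None else None
            ),
        },
        "time_domain": {
            "sap": compute_time_domain(sap).as_dict(),
            "pi": compute_time_domain(pi, include_rmssd=True).as_dict(),
        },
        "spectral": {
            "sap": spectral_sap.as_dict(),
            "pi": spectral_pi.as_dict(),
        },
        "symbolic": {
            "pi": symbolic.as_dict(),
        },
    }
    return report


def report_to_json(report: dict) -> str:
    """Canonical serialization: sorted keys, fixed float repr."""
    return json.dumps(report, sort_keys=True, indent=2, allow_nan=True)
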