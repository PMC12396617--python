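"""Pipeline configuration.

Every analysis parameter lives here rather than as a hidden constant.  The
rat-specific spectral bands (LF 0.20-0.75 Hz, HF >0.75-3.00 Hz), the 6-level
3-symbol symbolic scheme, and the 0.05 significance level are the study
conventions; resampling and Welch parameters are the package's explicit
defaults (see docs/methods.md for rationale).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

from .errors import ConfigurationError

#: Rat LF band: predominantly sympathetic (with parasympathetic) modulation.
DEFAULT_LF_BAND = (0.20, 0.75)
#: Rat HF band: parasympathetic (vagal) modulation.
DEFAULT_HF_BAND = (0.75, 3.00)


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters controlling the whole variability analysis.

    Attributes
    ----------
    lf_band, hf_band
        Half-open frequency intervals [low, high) in Hz.  The HF lower edge
        abuts the LF upper edge, so the partition of the spectrum is exact.
    resample_rate
        Rate (Hz) of the evenly resampled beat series fed to the FFT;
        must exceed twice the HF upper edge.
    welch_segment
        Welch segment length in resampled samples (512 @ 10 Hz = 51.2 s).
    welch_overlap
        Fractional overlap between Welch segments.
    n_levels, pattern_length
        Symbolic quantization levels and pattern window length.
    segment_duration
        Target duration (s) of the stable analysis segment (the study
        analyses ~10-min windows).
    min_segment_duration
        Shortest segment that is considered analyzable, seconds.
    min_rate, max_rate
        Physiological heart-rate bounds (beats/min) for beat detection;
        defaults cover the anesthetized/conscious rat.
    artifact_correction
        Whether to interpolate over ectopic/artifact intervals before
        analysis (off by default; the upstream software's behaviour on
        this point is undocumented).
    alpha
        Two-sided significance level for group comparisons.
    seed
        Seed for any stochastic step (None = nondeterministic).
    """

    lf_band: tuple[float, float] = DEFAULT_LF_BAND
    hf_band: tuple[float, float] = DEFAULT_HF_BAND
    resample_rate: float = 10.0
    welch_segment: int = 512
    welch_overlap: float = 0.5
    n_levels: int = 6
    pattern_length: int = 3
    segment_duration: float = 600.0
    min_segment_duration: float = 60.0
    min_rate: float = 200.0
    max_rate: float = 500.0
    artifact_correction: bool = False
    alpha: float = 0.05
    seed: int | None = None
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        lf, hf = self.lf_band, self.hf_band
        if not (0 <= lf[0] < lf[1] <= hf[0] < hf[1]):
            raise ConfigurationError(
                f"bands must be positive, ordered and non-overlapping: LF {lf}, HF {hf}"
            )
        if self.resample_rate <= 0:
            raise ConfigurationError("resample_rate must be positive")
        if hf[1] > self.resample_rate / 2:
            raise ConfigurationError(
                f"HF upper edge {hf[1]} Hz exceeds Nyquist "
                f"{self.resample_rate / 2} Hz of resample_rate"
            )
        if self.n_levels < 2:
            raise ConfigurationError("n_levels must be >= 2")
        if self.pattern_length < 2:
            raise ConfigurationError("pattern_length must be >= 2")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not 0 <= self.welch_overlap < 1:
            raise ConfigurationError("welch_overlap must lie in [0, 1)")
        if self.welch_segment < 8:
            raise ConfigurationError("welch_segment must be >= 8 samples")
        if not 0 < self.min_rate < self.max_rate:
            raise ConfigurationError("need 0 < min_rate < max_rate")
        if self.min_segment_duration <= 0 or self.segment_duration <= 0:
            raise ConfigurationError("segment durations must be positive")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a TOML file; unknown keys are kept in ``extra``."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)} - {"extra"}
        kwargs = {}
        extra = {}
        for key, value in raw.items():
            if key in ("lf_band", "hf_band"):
                value = tuple(float(v) for v in value)
            if key in known:
                kwargs[key] = value
            else:
                extra[key] = value
        return cls(extra=extra, **kwargs)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
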