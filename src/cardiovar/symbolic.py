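"""Symbolic-dynamics analysis of the pulse-interval series.

The nonlinear counterpart to spectral analysis: the PI series is quantized
into ``n_levels`` uniform levels over its observed range (6 levels, 0-5, by
convention), scanned with overlapping windows of 3 consecutive symbols, and
each pattern classified by its number and concordance of variations:

* ``0V`` — no variation (both differences zero): sympathetic marker;
* ``1V`` — exactly one variation: no specific autonomic association;
* ``2LV`` — two like variations (both rising or both falling) and
* ``2UV`` — two unlike variations (one rising, one falling): both
  parasympathetic markers; ``2V = 2LV + 2UV``.

Occurrence rates of the families are reported as percentages of all
patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import LengthError

logger = logging.getLogger(__name__)

FAMILIES = ("0V", "1V", "2LV", "2UV")


@dataclass(frozen=True)
class SymbolicIndices:
    p0v: float
    p1v: float
    p2lv: float
    p2uv: float
    pattern_count: int

    @property
    def p2v(self) -> float:
        return self.p2lv + self.p2uv

    def as_dict(self) -> dict:
        return {
            "p0v": self.p0v, "p1v": self.p1v, "p2lv": self.p2lv,
            "p2uv": self.p2uv, "p2v": self.p2v,
            "pattern_count": self.pattern_count,
        }


def quantize(series: np.ndarray, n_levels: int = 6) -> np.ndarray:
    """Uniform quantization of a series into integer levels 0..n_levels-1.

    Bins are equal-width over the observed [min, max]; the maximum maps to
    the top level.  A constant series (max == min) maps to all zeros with a
    logged note — the downstream analysis then reports 0V% = 100, which is
    the correct description of a variation-free series.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise LengthError("quantization needs at least 3 values")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        logger.info("constant series: all symbols set to level 0")
        return np.zeros(x.size, dtype=np.int64)
    symbols = np.floor(n_levels * (x - lo) / (hi - lo)).astype(np.int64)
    return np.minimum(symbols, n_levels - 1)


def classify_pattern(pattern) -> str:
    """Family of one 3-symbol pattern.

    With d1 = s2-s1 and d2 = s3-s2: 0V if both zero; 1V if exactly one is
    zero; 2LV if they share a sign; 2UV if the signs oppose.
    """
    s1, s2, s3 = pattern
    d1 = s2 - s1
    d2 = s3 - s2
    if d1 == 0 and d2 == 0:
        return "0V"
    if d1 == 0 or d2 == 0:
        return "1V"
    return "2LV" if d1 * d2 > 0 else "2UV"


def symbolic_indices(symbols: np.ndarray, pattern_length: int = 3) -> SymbolicIndices:
    """Family occurrence rates over all overlapping patterns (stride 1)."""
    if pattern_length != 3:
        raise ValueError("the 0V/1V/2V family scheme is defined for 3-symbol patterns")
    s = np.asarray(symbols, dtype=np.int64)
    if s.size < pattern_length:
        raise LengthError(
            f"need at least {pattern_length} symbols, got {s.size}"
        )
    d1 = s[1:-1] - s[:-2]
    d2 = s[2:] - s[1:-1]
    n = d1.size
    zeros = (d1 == 0).astype(int) + (d2 == 0).astype(int)
    n0v = int(np.sum(zeros == 2))
    n1v = int(np.sum(zeros == 1))
    prod = d1 * d2
    n2lv = int(np.sum(prod > 0))
    n2uv = int(np.sum(prod < 0))
    return SymbolicIndices(
        p0v=100.0 * n0v / n,
        p1v=100.0 * n1v / n,
        p2lv=100.0 * n2lv / n,
        p2uv=100.0 * n2uv / n,
        pattern_count=n,
    )


def analyze_symbolic(pi_series: np.ndarray, n_levels: int = 6,
                     pattern_length: int = 3) -> SymbolicIndices:
    """Quantize the PI series and compute family occurrence rates."""
    return symbolic_indices(quantize(pi_series, n_levels), pattern_length)
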