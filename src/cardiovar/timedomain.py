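"""Time-domain variability indices.

SAP variability uses mean, SD and variance; PI (heart-rate) variability
additionally uses RMSSD, the root mean square of successive interval
differences — the classical time-domain index of parasympathetic (vagal)
modulation:

    RMSSD = sqrt( mean_k (x_{k+1} - x_k)^2 )

Variance uses the unbiased (n-1) denominator, matching the descriptive
convention of commercial HRV software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LengthError


@dataclass(frozen=True)
class TimeDomainIndices:
    mean: float
    sd: float
    variance: float
    rmssd: float | None = None

    def as_dict(self) -> dict:
        out = {"mean": self.mean, "sd": self.sd, "variance": self.variance}
        if self.rmssd is not None:
            out["rmssd"] = self.rmssd
        return out


def rmssd(series: np.ndarray) -> float:
    """Root mean square of successive differences, in the series' unit."""
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise LengthError("RMSSD needs at least 3 values (2 successive differences)")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d * d)))


def compute_time_domain(series: np.ndarray, include_rmssd: bool = False) -> TimeDomainIndices:
    """Mean, SD, variance (n-1 denominator) and optionally RMSSD of a series."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise LengthError("time-domain indices need at least 2 values")
    var = float(np.var(x, ddof=1))
    return TimeDomainIndices(
        mean=float(np.mean(x)),
        sd=float(np.sqrt(var)),
        variance=var,
        rmssd=rmssd(x) if include_rmssd else None,
    )
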