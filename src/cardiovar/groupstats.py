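"""Two-group comparison statistics for variability indices.

The study convention: screen each group with Shapiro-Wilk; if both groups
look normal, compare with the unpaired two-sided Student's t-test (pooled
variance), otherwise with the two-sided Mann-Whitney U test.  Results are
summarized as means +/- SEM (SEM = SD/sqrt(n)) and flagged significant at
P < alpha.  No multiple-testing correction is applied by default, matching
the per-index P < 0.05 convention; a Holm option is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError


@dataclass(frozen=True)
class GroupData:
    """One index measured across the animals of one group."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise InsufficientDataError(f"group {self.label!r} has non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sem(self) -> float | None:
        """SD/sqrt(n); undefined (None) for a single observation."""
        if self.n < 2:
            return None
        return float(np.std(self.values, ddof=1) / np.sqrt(self.n))


@dataclass(frozen=True)
class ComparisonResult:
    index_name: str
    label_a: str
    label_b: str
    mean_a: float
    sem_a: float | None
    mean_b: float
    sem_b: float | None
    test_used: str  # "t-test" or "mann-whitney"
    statistic: float
    p_value: float
    significant: bool
    shapiro_p_a: float
    shapiro_p_b: float

    def as_dict(self) -> dict:
        return {
            "index": self.index_name,
            "group_a": self.label_a, "group_b": self.label_b,
            "mean_a": self.mean_a, "sem_a": self.sem_a,
            "mean_b": self.mean_b, "sem_b": self.sem_b,
            "test": self.test_used, "statistic": self.statistic,
            "p_value": self.p_value, "significant": self.significant,
        }


def dispatch_test(a: GroupData, b: GroupData, alpha: float = 0.05,
                  index_name: str = "", welch: bool = False) -> ComparisonResult:
    """Shapiro-dispatched two-group comparison.

    Both groups must pass Shapiro-Wilk at ``alpha`` for the parametric
    path; this conjunction is the conservative reading of the
    dispatch-by-normality rule.  ``welch=True`` swaps the pooled-variance
    t-test for Welch's unequal-variance variant.
    """
    if a.n < 3 or b.n < 3:
        raise InsufficientDataError(
            f"need n >= 3 per group for testing, got {a.n} and {b.n}"
        )
    sw_a = stats.shapiro(a.values).pvalue
    sw_b = stats.shapiro(b.values).pvalue
    if sw_a >= alpha and sw_b >= alpha:
        res = stats.ttest_ind(a.values, b.values, equal_var=not welch)
        test_used = "welch-t-test" if welch else "t-test"
    else:
        res = stats.mannwhitneyu(a.values, b.values, alternative="two-sided")
        test_used = "mann-whitney"
    p = float(res.pvalue)
    return ComparisonResult(
        index_name=index_name,
        label_a=a.label, label_b=b.label,
        mean_a=a.mean, sem_a=a.sem, mean_b=b.mean, sem_b=b.sem,
        test_used=test_used, statistic=float(res.statistic),
        p_value=p, significant=bool(p < alpha),
        shapiro_p_a=float(sw_a), shapiro_p_b=float(sw_b),
    )


def summarize_groups(groups: list[GroupData]) -> list[dict]:
    """Per-group n, mean and SEM, in input order."""
    if not groups:
        raise InsufficientDataError("no groups to summarize")
    out = []
    for g in groups:
        if g.n == 0:
            raise InsufficientDataError(f"group {g.label!r} is empty")
        out.append({"label": g.label, "n": g.n, "mean": g.mean, "sem": g.sem})
    return out


def holm_correct(results: list[ComparisonResult], alpha: float = 0.05
                 ) -> list[ComparisonResult]:
    """Holm step-down significance flags over a family of comparisons."""
    order = np.argsort([r.p_value for r in results])
    m = len(results)
    out = list(results)
    still_rejecting = True
    for rank, idx in enumerate(order):
        r = results[idx]
        threshold = alpha / (m - rank)
        reject = still_rejecting and r.p_value < threshold
        if not reject:
            still_rejecting = False
        out[idx] = ComparisonResult(**{**r.__dict__, "significant": reject})
    return out
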