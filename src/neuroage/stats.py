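"""Brain-age-gap computation and pooled-variance group comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


def brain_age_gap(predicted, age) -> np.ndarray | float:
    """Gap = predicted - chronological age (positive = older-appearing)."""
    return np.subtract(predicted, age)


@dataclass
class GroupSummary:
    n: int
    mean_gap: float
    sd_gap: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary requires n >= 2")
        if self.sd_gap < 0:
            raise ValueError("sd_gap must be >= 0")

    @classmethod
    def from_gaps(cls, gaps) -> "GroupSummary":
        gaps = np.asarray(gaps, dtype=float)
        return cls(n=len(gaps), mean_gap=float(gaps.mean()), sd_gap=float(gaps.std(ddof=1)))


@dataclass
class GapComparison:
    t: float
    df: float
    p: float
    mean_difference: float


def compare_groups_from_summary(a: GroupSummary, b: GroupSummary) -> GapComparison:
    """Two-sample pooled-variance (Student) t-test from (n, mean, sd)."""
    df = a.n + b.n - 2
    pooled_var = ((a.n - 1) * a.sd_gap**2 + (b.n - 1) * b.sd_gap**2) / df
    if pooled_var == 0:
        raise ValueError("zero pooled variance; t statistic is undefined")
    se = np.sqrt(pooled_var * (1.0 / a.n + 1.0 / b.n))
    diff = a.mean_gap - b.mean_gap
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return GapComparison(t=float(t), df=float(df), p=float(p), mean_difference=float(diff))


def compare_groups(gaps_a, gaps_b) -> GapComparison:
    """Pooled-variance independent t-test on two raw gap samples."""
    gaps_a = np.asarray(gaps_a, dtype=float)
    gaps_b = np.asarray(gaps_b, dtype=float)
    if len(gaps_a) < 2 or len(gaps_b) < 2:
        raise ValueError("each group needs n >= 2")
    return compare_groups_from_summary(
        GroupSummary.from_gaps(gaps_a), GroupSummary.from_gaps(gaps_b)
    )
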