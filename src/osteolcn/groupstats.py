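"""Two-group comparison and reporting: mean +/- SD, pooled-variance
Student's t-test (two-tailed), percent change and significance stars.

The pooled (classic Student's) test rather than Welch's is used because
groups are small and the software the study design mirrors defaults to
it; Welch's variant is available via ``equal_var=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class GroupComparison:
    """Result of comparing a reference ('naive') and a test ('tumor') group."""

    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    percent_change: float  # 100 * (b - a) / a; NaN if mean_a == 0
    t: float
    p: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p)

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["stars"] = self.stars
        return d


def compare_groups(
    a,
    b,
    metric: str = "",
    labels: tuple[str, str] = ("naive", "tumor"),
    equal_var: bool = True,
) -> GroupComparison:
    """Compare two independent groups; ``a`` is the reference group.

    Uses the classic pooled-variance two-tailed Student's t-test. The t
    statistic is signed as ``b`` minus ``a`` (positive when the test group
    is higher), so it is antisymmetric under a group swap while p is
    invariant. Degenerate zero-variance groups are handled explicitly:
    identical constants give t = 0, p = 1; different constants give p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))
    if sd_a == 0.0 and sd_b == 0.0:
        if mean_a == mean_b:
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, mean_b - mean_a), 0.0
    else:
        t, p = stats.ttest_ind(b, a, equal_var=equal_var)
        t, p = float(t), float(p)
    pct = 100.0 * (mean_b - mean_a) / mean_a if mean_a != 0 else float("nan")
    return GroupComparison(
        metric=metric,
        group_a=labels[0],
        group_b=labels[1],
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=mean_a,
        mean_b=mean_b,
        sd_a=sd_a,
        sd_b=sd_b,
        percent_change=pct,
        t=t,
        p=p,
    )


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation.

    Thresholds .05 / .01 / .001 / .0001, half-open intervals
    (p = .05 itself is 'ns').
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
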