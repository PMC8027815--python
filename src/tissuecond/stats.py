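"""Group summaries, Welch's unpaired t-test, and the caliper transform.

Two entry points to the same test: :func:`welch_from_values` for raw
measurements and :func:`welch_from_summary` for printed "mean ± SD (n)"
summaries, which is how published comparison groups usually arrive.  The
from-values route is defined as from-summary applied to the computed
summaries, so the two can never disagree.

Published "±" dispersions are sometimes SEM rather than SD;
:meth:`GroupSummary.from_sem` converts (SD = SEM * sqrt(n)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateVarianceError, DomainError

__all__ = [
    "GroupSummary",
    "WelchResult",
    "summarize",
    "welch_from_summary",
    "welch_from_values",
    "caliper_diameter",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SD summary of one group of measurements."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError(f"n must be >= 1, got {self.n}")
        if self.sd < 0:
            raise DomainError(f"sd must be >= 0, got {self.sd}")
        if self.n == 1 and self.sd != 0:
            raise DomainError("a single observation has no dispersion; sd must be 0")

    @property
    def degenerate(self) -> bool:
        """True when the SD is undefined (n = 1) and reported as 0."""
        return self.n == 1

    @property
    def sem(self) -> float:
        return self.sd / math.sqrt(self.n)

    @classmethod
    def from_sem(cls, label: str, n: int, mean: float, sem: float) -> "GroupSummary":
        """Build from a mean ± SEM summary (SD = SEM * sqrt(n))."""
        return cls(label=label, n=n, mean=mean, sd=sem * math.sqrt(n))


@dataclass(frozen=True)
class WelchResult:
    """Welch's unpaired t-test: statistic, Welch–Satterthwaite df, two-sided p."""

    t_statistic: float
    degrees_of_freedom: float
    p_value: float


def summarize(values: Sequence[float], label: str = "") -> GroupSummary:
    """Mean and sample SD (n - 1 denominator) of a group of measurements.

    A single value yields sd = 0, flagged degenerate on the summary.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DomainError("cannot summarize an empty group")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(label=label, n=int(arr.size), mean=float(arr.mean()), sd=sd)


def welch_from_summary(a: GroupSummary, b: GroupSummary) -> WelchResult:
    """Welch's t-test from two mean ± SD (n) summaries.

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with degrees of freedom
    from the Welch–Satterthwaite approximation and a two-sided p from the
    t distribution.  Requires n >= 2 and sd > 0 in both groups.
    """
    for g in (a, b):
        if g.n < 2 or g.sd <= 0:
            raise DegenerateVarianceError(
                f"group {g.label!r}: Welch test needs n >= 2 and sd > 0 (n={g.n}, sd={g.sd})"
            )
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    t = (a.mean - b.mean) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return WelchResult(t_statistic=t, degrees_of_freedom=df, p_value=min(p, 1.0))


def welch_from_values(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's t-test from raw per-sample values.

    Defined as :func:`welch_from_summary` on the two computed summaries, so
    the two routes agree to round-off by construction.
    """
    return welch_from_summary(summarize(a, "a"), summarize(b, "b"))


def caliper_diameter(widest_cm: float, perpendicular_cm: float) -> float:
    """Effective tumor diameter from two caliper readings.

    The geometric mean ``sqrt(d1 * d2)`` of the widest diameter and the
    diameter perpendicular to it; symmetric in its arguments and bounded by
    them.
    """
    if widest_cm <= 0 or perpendicular_cm <= 0:
        raise DomainError("caliper readings must be > 0")
    return math.sqrt(widest_cm * perpendicular_cm)
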