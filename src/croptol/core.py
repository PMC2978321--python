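"""Order-statistic (distribution-free) tolerance-interval mathematics.

A two-sided distribution-free tolerance interval takes its endpoints from
the order statistics of an i.i.d. continuous sample.  The probability
("certainty", gamma) that the interval between the l-th and u-th order
statistics contains at least a proportion p ("coverage") of the parent
population is an exact binomial quantity that depends only on
``(n, u - l, p)`` — never on the parent distribution:

    gamma = P[ Binomial(n, p) <= u - l - 1 ]

This module provides that certainty, the trim-plan search that picks the
ranks achieving a requested (coverage, certainty) pair, the certainty of
the full sample range, the minimum sample size at which the requested
pair is attainable at all, and the interval constructor that applies a
trim plan to data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import binom

__all__ = [
    "ToleranceSpec",
    "TrimPlan",
    "RankInterval",
    "ToleranceResult",
    "InfeasiblePlanError",
    "rank_interval_certainty",
    "range_certainty",
    "trim_plan",
    "tolerance_interval",
    "min_sample_size",
    "certainty_percent",
]


@dataclass(frozen=True)
class ToleranceSpec:
    """The (coverage, certainty) pair governing interval construction.

    coverage
        Proportion p of the population the interval is designed to
        contain (the operating point used for crop composition is 0.99).
    certainty
        Probability gamma that the interval truly attains its coverage
        over repeated sampling (operating point 0.95).
    """

    coverage: float = 0.99
    certainty: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.coverage < 1.0:
            raise ValueError(f"coverage must be in (0, 1), got {self.coverage}")
        if not 0.0 < self.certainty < 1.0:
            raise ValueError(f"certainty must be in (0, 1), got {self.certainty}")


@dataclass(frozen=True)
class TrimPlan:
    """Counts and order-statistic ranks selected by the trim search.

    ``u1`` is the number of points the cumulative-binomial search says
    must lie strictly inside the interval; ``v = n - u1`` points are
    trimmed, split as ``v1`` from the bottom and ``v2`` from the top
    (the odd point goes to the top).  ``lower_rank``/``upper_rank`` are
    the 1-based order-statistic indices of the interval endpoints after
    clamping degenerate indices to 1 and n.
    """

    n: int
    u1: int
    v: int
    v1: int
    v2: int
    lower_rank: int
    upper_rank: int
    feasible: bool

    def __post_init__(self) -> None:
        if self.v1 + self.v2 != self.v or self.v != self.n - self.u1:
            raise ValueError("inconsistent trim counts")
        if not 1 <= self.lower_rank <= self.upper_rank <= self.n:
            raise ValueError("ranks out of order or out of range")


@dataclass(frozen=True)
class RankInterval:
    """A rank pair together with its exact coverage certainty."""

    lower_rank: int
    upper_rank: int
    certainty: float


@dataclass(frozen=True)
class ToleranceResult:
    """Outcome of applying a tolerance spec to one analyte dataset.

    When ``calculable`` is True, ``lower``/``upper`` are the tolerance
    interval endpoints and ``certainty`` the certainty it achieves.
    When False (sample too small for the requested spec) the endpoints
    fall back to the data range and ``certainty`` is the certainty with
    which that range attains the requested coverage — the quantity
    reported in place of a tolerance interval for small samples.
    """

    n: int
    lower: float
    upper: float
    certainty: float
    calculable: bool
    plan: TrimPlan | None
    spec: ToleranceSpec


class InfeasiblePlanError(ValueError):
    """Raised when no trim achieves the requested certainty at this n."""


def _validate_rank_args(n: int, lower_rank: int, upper_rank: int, coverage: float) -> None:
    for name, val in (("n", n), ("lower_rank", lower_rank), ("upper_rank", upper_rank)):
        if not float(val).is_integer():
            raise ValueError(f"{name} must be an integer, got {val!r}")
    if not 0.0 < coverage < 1.0:
        raise ValueError(f"coverage must be in (0, 1), got {coverage}")
    if not (1 <= lower_rank < upper_rank <= n):
        raise ValueError(
            f"require 1 <= lower_rank < upper_rank <= n, got ({lower_rank}, {upper_rank}) with n={n}"
        )


def rank_interval_certainty(
    n: int, lower_rank: int, upper_rank: int, coverage: float
) -> float:
    """Exact certainty that [X(lower_rank), X(upper_rank)] covers ``coverage``.

    For an i.i.d. sample of size ``n`` from any continuous distribution,
    the population mass between the two order statistics is distributed
    Beta(u - l, n - u + l + 1), so the probability that the mass is at
    least ``coverage`` equals the binomial CDF
    ``P[Binomial(n, coverage) <= u - l - 1]`` (computed via the
    regularised incomplete beta function, stable to n >= 1e5).
    """
    _validate_rank_args(n, lower_rank, upper_rank, coverage)
    return float(binom.cdf(upper_rank - lower_rank - 1, int(n), coverage))


def range_certainty(n: int, coverage: float = 0.99) -> float:
    """Certainty that the sample range (min..max) covers ``coverage``.

    Equals ``rank_interval_certainty(n, 1, n, coverage)``; the closed
    form is ``1 - n p^(n-1) (1-p) - p^n``.  A single observation (n=1)
    is a degenerate interval of zero width, whose certainty is exactly 0.
    """
    if not float(n).is_integer() or n < 1:
        raise ValueError(f"n must be an integer >= 1, got {n!r}")
    if n == 1:
        if not 0.0 < coverage < 1.0:
            raise ValueError(f"coverage must be in (0, 1), got {coverage}")
        return 0.0
    return rank_interval_certainty(int(n), 1, int(n), coverage)


def trim_plan(n: int, spec: ToleranceSpec) -> TrimPlan:
    """Select order-statistic ranks achieving ``spec`` at sample size n.

    Search: u1 is the first k in 0..n at which the cumulative binomial
    P[Binomial(n, coverage) <= k] strictly exceeds the certainty; then
    v = n - u1 points are trimmed, v1 = floor(v/2) from the bottom and
    v2 = v - v1 from the top, and the endpoint ranks are l = v1 and
    u = n - v2 + 1 (clamped into 1..n).  The lower endpoint rank is v1
    itself, not v1 + 1 — this literal indexing is what makes the
    tolerance interval coincide with the data range at the smallest
    feasible sample sizes, as the published composition tables show.

    The plan is flagged infeasible when even the full range fails the
    strict certainty condition, i.e. range_certainty(n) <= certainty;
    callers decide whether that means "not calculable".
    """
    if not float(n).is_integer() or n < 1:
        raise ValueError(f"n must be an integer >= 1, got {n!r}")
    n = int(n)
    feasible = n >= 2 and range_certainty(n, spec.coverage) > spec.certainty
    ks = np.arange(0, n + 1)
    cdf = binom.cdf(ks, n, spec.coverage)
    hits = np.nonzero(cdf > spec.certainty)[0]
    # P[B <= n] = 1 > certainty always, so the search cannot come up empty.
    u1 = int(hits[0])
    v = n - u1
    v1 = v // 2
    v2 = v - v1
    lower = max(v1, 1)
    upper = min(n - v2 + 1, n)
    return TrimPlan(
        n=n, u1=u1, v=v, v1=v1, v2=v2,
        lower_rank=lower, upper_rank=upper, feasible=feasible,
    )


def min_sample_size(spec: ToleranceSpec) -> int:
    """Smallest n at which the full sample range attains the spec.

    Returns the least n with ``range_certainty(n, coverage) >=
    certainty``.  Found by doubling to bracket then bisecting; the
    certainty is strictly increasing in n and tends to 1, so the search
    always terminates.  At the (0.99, 0.95) operating point this is 473.
    """
    p, g = spec.coverage, spec.certainty
    hi = 2
    while range_certainty(hi, p) < g:
        hi *= 2
    lo = hi // 2  # range_certainty(lo) < g unless hi == 2
    if hi == 2:
        return 2 if range_certainty(1, p) < g else 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if range_certainty(mid, p) >= g:
            hi = mid
        else:
            lo = mid
    return hi


def tolerance_interval(
    values: Sequence[float], spec: ToleranceSpec = ToleranceSpec()
) -> ToleranceResult:
    """Construct the distribution-free tolerance interval for ``values``.

    Values are sorted ascending (a stable sort; ties are permitted and
    make the stated certainty conservative) and the trim-plan ranks
    index into the sorted data.  If the plan is infeasible or n is below
    ``min_sample_size(spec)``, the result is flagged not calculable and
    reports the data range with its range certainty instead — the
    small-sample fallback used in the published composition tables.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("values must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("values must all be finite")
    srt = np.sort(arr, kind="stable")
    n = int(arr.size)
    plan = trim_plan(n, spec)
    if plan.feasible and n >= min_sample_size(spec):
        lower = float(srt[plan.lower_rank - 1])
        upper = float(srt[plan.upper_rank - 1])
        if plan.upper_rank > plan.lower_rank:
            cert = rank_interval_certainty(
                n, plan.lower_rank, plan.upper_rank, spec.coverage
            )
        else:  # degenerate: all mass at one rank
            cert = 0.0
        return ToleranceResult(
            n=n, lower=lower, upper=upper, certainty=cert,
            calculable=True, plan=plan, spec=spec,
        )
    return ToleranceResult(
        n=n,
        lower=float(srt[0]),
        upper=float(srt[-1]),
        certainty=range_certainty(n, spec.coverage),
        calculable=False,
        plan=plan,
        spec=spec,
    )


def certainty_percent(certainty: float, decimals: int = 3) -> str:
    """Format a certainty as a percent string, half-even at ``decimals``.

    Table convention: three decimals, e.g. 0.73417... -> '73.417%'.
    """
    q = np.round(certainty * 100.0, decimals)
    return f"{q:.{decimals}f}%"
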