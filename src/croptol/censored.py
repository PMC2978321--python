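"""Below-LOQ measurement semantics and per-analyte summary statistics.

Analyte panels routinely report some measurements only as "below the
limit of quantification" (<LOQ).  The convention adopted here, matching
standard crop-composition reporting practice, is:

* computation (ranking, means, medians, interval construction) uses an
  *effective value* of half the LOQ for each censored measurement;
* display of an interval endpoint that happens to be a censored point
  shows ``<LOQ`` at that point's own, actual LOQ — a report never
  prints the half-LOQ stand-in.

Mixed LOQs within one analyte are allowed: each censored value is
substituted at half its own LOQ and displayed at its own LOQ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["CensoredValue", "SummaryStats", "effective_value", "summarize"]


@dataclass(frozen=True)
class CensoredValue:
    """One analyte measurement, possibly known only as below-LOQ.

    For censored entries ``value`` is the LOQ itself.
    """

    value: float
    is_below_loq: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"value must be finite, got {self.value!r}")
        if self.is_below_loq and self.value <= 0:
            raise ValueError("an LOQ must be positive")

    @property
    def effective(self) -> float:
        return effective_value(self)

    @property
    def display(self) -> str:
        """'<LOQ' form for censored values, plain repr otherwise."""
        return f"<{_fmt(self.value)}" if self.is_below_loq else _fmt(self.value)


def _fmt(x: float) -> str:
    """Echo a number compactly without trailing float noise."""
    if float(x).is_integer():
        return str(int(x))
    return f"{x:g}"


def effective_value(v: CensoredValue) -> float:
    """Half the LOQ when censored, the measurement itself otherwise."""
    return v.value / 2.0 if v.is_below_loq else v.value


@dataclass(frozen=True)
class SummaryStats:
    """Mean/median/range/CI summary of one analyte dataset.

    ``range_low_display`` / ``range_high_display`` carry the '<LOQ'
    string form when the corresponding extreme is a censored point.
    """

    n: int
    mean: float
    median: float
    range_low: float
    range_high: float
    range_low_display: str
    range_high_display: str
    mean_ci_low: float
    mean_ci_high: float

    @property
    def range_display(self) -> str:
        return f"{self.range_low_display}–{self.range_high_display}"


def summarize(
    values: Sequence[CensoredValue],
    certainty: float = 0.95,
    conventional_ci: bool = False,
) -> SummaryStats:
    """Summary statistics on effective (half-LOQ-substituted) values.

    The confidence interval for the mean is ``mean +/- t_q(n-1) s/sqrt(n)``
    where, as published in the original analysis listing, ``q`` is the
    certainty level itself — giving a two-sided interval of coverage
    ``2*certainty - 1``.  Pass ``conventional_ci=True`` for the usual
    two-sided interval at level ``certainty`` (q = (1+certainty)/2).

    Range endpoints are the extremes on the effective scale; their
    display strings report the actual LOQ ('<LOQ') when the extreme is
    a censored point.
    """
    if len(values) == 0:
        raise ValueError("values must be non-empty")
    eff = np.array([effective_value(v) for v in values], dtype=float)
    n = eff.size
    mean = float(eff.mean())
    median = float(np.median(eff))
    i_lo = int(np.argmin(eff))
    i_hi = int(np.argmax(eff))
    if n >= 2:
        q = (1.0 + certainty) / 2.0 if conventional_ci else certainty
        half = float(stats.t.ppf(q, n - 1) * eff.std(ddof=1) / np.sqrt(n))
        ci = (mean - half, mean + half)
    else:
        ci = (float("nan"), float("nan"))
    return SummaryStats(
        n=n,
        mean=mean,
        median=median,
        range_low=float(eff[i_lo]),
        range_high=float(eff[i_hi]),
        range_low_display=values[i_lo].display,
        range_high_display=values[i_hi].display,
        mean_ci_low=ci[0],
        mean_ci_high=ci[1],
    )
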