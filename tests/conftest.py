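from fractions import Fraction
from math import comb

import numpy as np
import pytest

from croptol import AnalyteRecord, CensoredValue


def exact_binom_cdf(k: int, n: int, p: Fraction) -> Fraction:
    """Exact rational binomial CDF (oracle; direct summation)."""
    q = 1 - p
    return sum((comb(n, i) * p**i * q ** (n - i) for i in range(0, k + 1)), Fraction(0))


def exact_u1(n: int, p: Fraction, g: Fraction) -> int:
    """Oracle for the trim search: smallest k in 0..n with CDF(k) > g.

    Works from the upper tail so only O(n - u1) exact terms are needed:
    CDF(k) > g  <=>  P[B >= k+1] < 1 - g.
    """
    thresh = 1 - g
    q = 1 - p
    tail = Fraction(0)  # P[B >= k+1] at k = n
    k = n
    while k > 0:
        tail_next = tail + comb(n, k) * p**k * q ** (n - k)  # P[B >= k]
        if tail_next >= thresh:
            return k
        tail = tail_next
        k -= 1
    return 0


def exact_range_certainty(n: int, p: Fraction) -> Fraction:
    """Closed form 1 - n p^(n-1)(1-p) - p^n as an exact rational."""
    return 1 - n * p ** (n - 1) * (1 - p) - p**n


def mc_rank_certainty(
    n: int, lower: int, upper: int, p: float, draws: int, seed: int
) -> tuple[float, float]:
    """Monte-Carlo oracle: frequency that [X(l), X(u)] of a Uniform(0,1)
    sample covers mass >= p, plus its standard error."""
    rng = np.random.default_rng(seed)
    freq_sum = 0
    # chunked to bound memory
    left = draws
    while left > 0:
        m = min(left, 50_000)
        u = rng.random((m, n))
        u.sort(axis=1)
        freq_sum += int(np.sum(u[:, upper - 1] - u[:, lower - 1] >= p))
        left -= m
    phat = freq_sum / draws
    se = np.sqrt(max(phat * (1 - phat), 1.0 / draws) / draws)
    return phat, se


def make_records(
    values, crop="corn", analyte="ash", category="proximates", units="% DW"
):
    """Uncensored AnalyteRecords from a sequence of floats."""
    return [
        AnalyteRecord(crop, analyte, category, units, CensoredValue(float(v)))
        for v in values
    ]


@pytest.fixture
def records_factory():
    return make_records
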