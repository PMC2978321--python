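"""Order-statistic tolerance-interval math against independent oracles."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from croptol import (
    ToleranceSpec,
    min_sample_size,
    range_certainty,
    rank_interval_certainty,
    tolerance_interval,
    trim_plan,
    certainty_percent,
)

from conftest import (
    exact_range_certainty,
    exact_u1,
    mc_rank_certainty,
)

P99 = Fraction(99, 100)
G95 = Fraction(95, 100)


class TestRankIntervalCertainty:
    def test_closed_form_full_range(self):
        """CDF route equals 1 - n p^(n-1)(1-p) - p^n across n and p."""
        for n in [2, 3, 10, 77, 260, 323, 473, 596, 1410, 2000]:
            for p in [0.5, 0.9, 0.95, 0.99]:
                closed = 1 - n * p ** (n - 1) * (1 - p) - p**n
                assert rank_interval_certainty(n, 1, n, p) == pytest.approx(
                    closed, abs=1e-12
                )

    def test_minimal_sample_closed_form(self):
        """n=2 full range: certainty is (1-p)^2; 1e-4 at p=0.99."""
        assert rank_interval_certainty(2, 1, 2, 0.99) == pytest.approx(1e-4, rel=1e-9)
        for p in (0.3, 0.9):
            assert rank_interval_certainty(2, 1, 2, p) == pytest.approx((1 - p) ** 2)

    def test_monte_carlo_interior_ranks(self):
        """Matches the simulated coverage frequency for interior ranks."""
        exact = rank_interval_certainty(40, 3, 37, 0.90)
        phat, se = mc_rank_certainty(40, 3, 37, 0.90, draws=200_000, seed=20260926)
        assert abs(exact - phat) <= 3 * se

    def test_monotone_in_width(self):
        certs = [rank_interval_certainty(50, 10, u, 0.9) for u in range(12, 51)]
        assert all(b > a for a, b in zip(certs, certs[1:]))

    @pytest.mark.parametrize(
        "args",
        [
            (10, 0, 5, 0.9),     # rank below 1
            (10, 5, 5, 0.9),     # not strictly increasing
            (10, 5, 11, 0.9),    # rank above n
            (10, 2.5, 5, 0.9),   # non-integer rank
            (10, 1, 10, 0.0),    # coverage at boundary
            (10, 1, 10, 1.0),
        ],
    )
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            rank_interval_certainty(*args)


class TestRangeCertainty:
    def test_single_point_has_zero_certainty(self):
        assert range_certainty(1, 0.99) == 0.0

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            range_certainty(0, 0.99)

    def test_strictly_increasing_in_n(self):
        vals = [range_certainty(n, 0.99) for n in range(2, 800)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_strictly_decreasing_in_coverage(self):
        # below p ~ 0.95 at n=300 the certainty saturates to 1 in float64
        ps = np.linspace(0.95, 0.999, 40)
        vals = [range_certainty(300, p) for p in ps]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_exact_rational_agreement(self):
        for n in (2, 50, 323, 473, 1410):
            exact = float(exact_range_certainty(n, P99))
            assert range_certainty(n, 0.99) == pytest.approx(exact, abs=1e-12)


class TestTrimPlan:
    @pytest.mark.parametrize("n", [473, 505, 596, 1410, 1434])
    def test_u1_matches_exact_oracle(self, n):
        """Cumulative-binomial search agrees with exact rational arithmetic."""
        plan = trim_plan(n, ToleranceSpec(0.99, 0.95))
        assert plan.u1 == exact_u1(n, P99, G95)
        assert plan.v == n - plan.u1
        assert plan.v1 + plan.v2 == plan.v
        assert plan.v2 - plan.v1 in (0, 1)

    def test_n1410_achieves_certainty_and_next_narrower_fails(self):
        plan = trim_plan(1410, ToleranceSpec(0.99, 0.95))
        achieved = rank_interval_certainty(
            1410, plan.lower_rank, plan.upper_rank, 0.99
        )
        assert achieved > 0.95
        # one more symmetric trim on each side must fall below the certainty
        narrower = rank_interval_certainty(
            1410, plan.lower_rank + 1, plan.upper_rank - 1, 0.99
        )
        assert narrower <= 0.95

    @pytest.mark.parametrize("n,expect_ranks", [(473, (1, 473)), (505, (1, 505)), (596, (1, 596))])
    def test_boundary_plans_keep_full_range(self, n, expect_ranks):
        """Near the minimum feasible n the selected ranks are (1, n)."""
        plan = trim_plan(n, ToleranceSpec(0.99, 0.95))
        assert (plan.lower_rank, plan.upper_rank) == expect_ranks
        assert plan.feasible

    def test_infeasible_below_minimum(self):
        plan = trim_plan(300, ToleranceSpec(0.99, 0.95))
        assert not plan.feasible

    @given(n=st.integers(min_value=1, max_value=400))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_rank_invariants(self, n):
        plan = trim_plan(n, ToleranceSpec(0.99, 0.95))
        assert 1 <= plan.lower_rank <= plan.upper_rank <= n
        assert plan.v1 + plan.v2 == plan.v == n - plan.u1
        assert plan.v2 - plan.v1 in (0, 1)
        unclamped = plan.v1 >= 1 and plan.n - plan.v2 + 1 <= n
        if unclamped:
            assert plan.upper_rank - plan.lower_rank - 1 == plan.u1


class TestMinSampleSize:
    def test_operating_point_boundary(self):
        """473 is the threshold for 99% coverage / 95% certainty."""
        assert min_sample_size(ToleranceSpec(0.99, 0.95)) == 473
        assert range_certainty(472, 0.99) < 0.95 <= range_certainty(473, 0.99)

    @pytest.mark.parametrize(
        "spec,expected",
        [
            (ToleranceSpec(0.95, 0.95), 93),
            (ToleranceSpec(0.99, 0.0001), 2),
            (ToleranceSpec(0.90, 0.95), 46),
        ],
    )
    def test_matches_exact_scan(self, spec, expected):
        """Agrees with a brute-force scan of the exact closed form."""
        p = Fraction(spec.coverage).limit_denominator(10**6)
        g = Fraction(spec.certainty).limit_denominator(10**6)
        n = 1
        while exact_range_certainty(n, p) < g:
            n += 1
        assert n == expected
        assert min_sample_size(spec) == expected


class TestToleranceInterval:
    def test_full_range_at_boundary_n(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=596)
        res = tolerance_interval(data, ToleranceSpec(0.99, 0.95))
        assert res.calculable
        assert res.lower == data.min()
        assert res.upper == data.max()
        assert res.certainty > 0.95

    def test_small_sample_falls_back_to_range(self):
        rng = np.random.default_rng(11)
        data = rng.normal(size=300)
        res = tolerance_interval(data, ToleranceSpec(0.99, 0.95))
        assert not res.calculable
        assert (res.lower, res.upper) == (data.min(), data.max())
        assert res.certainty == pytest.approx(range_certainty(300, 0.99))

    def test_consecutive_integers_match_oracle_ranks(self):
        values = np.arange(1, 1001, dtype=float)
        spec = ToleranceSpec(0.90, 0.95)
        u1 = exact_u1(1000, Fraction(9, 10), G95)
        v = 1000 - u1
        v1, v2 = v // 2, v - v // 2
        lo_rank, hi_rank = max(v1, 1), min(1000 - v2 + 1, 1000)
        res = tolerance_interval(values, spec)
        assert res.lower == float(lo_rank)
        assert res.upper == float(hi_rank)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(size=700)
        res1 = tolerance_interval(values, ToleranceSpec(0.99, 0.95))
        res2 = tolerance_interval(rng.permutation(values), ToleranceSpec(0.99, 0.95))
        assert (res1.lower, res1.upper, res1.certainty) == (
            res2.lower, res2.upper, res2.certainty,
        )

    @given(
        data=st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=12, max_size=80,
        ),
        slope=st.floats(min_value=0.01, max_value=100),
        intercept=st.floats(min_value=-1e3, max_value=1e3),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_equivariance_under_increasing_affine_maps(self, data, slope, intercept):
        """Rank-based endpoints commute with strictly increasing transforms."""
        spec = ToleranceSpec(0.7, 0.8)  # attainable at small n
        arr = np.asarray(data)
        res = tolerance_interval(arr, spec)
        res_g = tolerance_interval(slope * arr + intercept, spec)
        assert res_g.lower == pytest.approx(slope * res.lower + intercept, rel=1e-12, abs=1e-9)
        assert res_g.upper == pytest.approx(slope * res.upper + intercept, rel=1e-12, abs=1e-9)
        assert res_g.calculable == res.calculable

    def test_empty_and_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            tolerance_interval([], ToleranceSpec())
        with pytest.raises(ValueError):
            tolerance_interval([1.0, float("nan")], ToleranceSpec())


def test_certainty_percent_formatting():
    """Three-decimal half-even percent, the reference-table convention."""
    assert certainty_percent(0.734170001) == "73.417%"
    assert certainty_percent(range_certainty(323, 0.99)) == "83.410%"
    assert certainty_percent(0.5, decimals=1) == "50.0%"
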