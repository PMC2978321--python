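# Methods

## The statistical model

Let X₁, …, Xₙ be an i.i.d. sample from an arbitrary **continuous** parent
distribution F, and let X₍₁₎ ≤ … ≤ X₍ₙ₎ be its order statistics. The
population mass captured by the random interval \[X₍ₗ₎, X₍ᵤ₎\],
W = F(X₍ᵤ₎) − F(X₍ₗ₎), is distributed Beta(u − l, n − u + l + 1)
regardless of F. The probability that the interval contains at least a
proportion p of the population is therefore

    γ(n, l, u, p) = P[W ≥ p] = P[Binomial(n, p) ≤ u − l − 1],

computed here through SciPy's binomial CDF (regularised incomplete beta,
numerically stable to n well beyond 10⁵; verified against the closed form
1 − n·pⁿ⁻¹(1−p) − pⁿ for the full range to 1e−12 across n = 2…2000).
Because the result never involves F, the interval is *distribution-free*:
the guarantee holds for any continuous parent.

Two quantities drive everything else:

- **Range certainty** γ(n, 1, n, p): the certainty with which the sample
  range (min…max) covers at least p of the population. This is the value
  reported, as a three-decimal percent, for every crop–analyte group, and
  it is the quantity that determines feasibility. A single observation
  (n = 1) is a zero-width interval and is assigned certainty exactly 0.
- **Minimum sample size** n\*(p, γ): the least n with range certainty ≥ γ,
  found by bracketing/bisection on the strictly increasing certainty
  curve. At the operating point (p = 0.99, γ = 0.95), n\* = 473
  (certainty 95.020% at 473, 94.979% at 472).

## The trim-plan algorithm

Given (n, p, γ), the plan selects how many extreme points the interval may
exclude while keeping certainty above γ:

1. u1 = the first k in 0…n with P[Binomial(n, p) ≤ k] **strictly greater**
   than γ — the number of points that must lie strictly inside the interval;
2. v = n − u1 points are trimmed, v1 = ⌊v/2⌋ associated with the bottom
   and v2 = v − v1 with the top (the odd point goes to the top);
3. endpoint ranks are l = v1 and u = n − v2 + 1, clamped into 1…n.

Two aspects of step 3 are deliberate and load-bearing:

- **The lower endpoint rank is v1 itself, not v1 + 1.** A naive reading of
  "trim v1 points from the bottom" would put the endpoint at rank v1 + 1.
  The v1 indexing is what the published composition tables embody — at
  n = 596 and n = 505 (v = 2, v1 = v2 = 1) it yields ranks (1, n), making
  the tolerance interval coincide exactly with the data range, as those
  table rows print. The realised interval satisfies
  u − l − 1 = u1, so its certainty is exactly the searched-for
  P[Binomial ≤ u1] > γ. This package reproduces that indexing
  bit-for-bit; it is slightly conservative (one extra sample point sits on
  each endpoint) rather than anti-conservative.
- **Feasibility.** The binomial CDF equals 1 at k = n, so the search never
  comes up empty; but when u1 ≥ n − 1 the clamped ranks degrade to (1, n)
  whose certainty is the range certainty, which may be below γ. The plan
  is therefore flagged infeasible exactly when the full range fails the
  strict condition, i.e. range certainty ≤ γ. `tolerance_interval`
  reports `calculable=False` whenever the plan is infeasible or
  n < n\*(p, γ), and falls back to the data range annotated with its range
  certainty — the "not calculable" convention of the reference tables.

Ties in the data are permitted: sorting is stable and endpoints are data
values, so ties cannot break the construction. Under a discrete or tied
parent the stated certainty is conservative (the interval is closed, so
mass sitting on the endpoints only helps). Certainties are displayed as
percents rounded **half-even to three decimals** (`numpy.round`); internal
values are full precision.

## Below-LOQ measurements

A measurement known only as "below the limit of quantification" is carried
as the pair (LOQ, censored-flag). All computation — ranking, means,
medians, interval endpoints — uses the **effective value** LOQ/2; any
displayed endpoint that is a censored point prints `<LOQ` at that point's
own, actual LOQ. Mixed LOQs within one analyte are allowed; each censored
value substitutes half its own LOQ. This is a reporting convention, not a
censored-likelihood estimator: for the rank-based interval itself the
substitution is innocuous so long as all censored values fall below the
uncensored ones, but means of heavily censored analytes inherit the usual
half-LOQ bias, and no Kaplan–Meier or MLE alternative is attempted.

## Summary statistics and the CI of the mean

Group summaries report n, mean, median (even-length median is the midpoint
of the two central effective values), range, and a t-interval for the
mean. The t-interval replicates the original published analysis code
verbatim: the quantile level is the certainty γ itself, i.e.
mean ± t_γ(n−1)·s/√n, which is a two-sided interval of coverage 2γ − 1
rather than γ. This "as-published" behaviour is the default;
`summarize(..., conventional_ci=True)` switches to the standard two-sided
(1+γ)/2 quantile. The original listing also contains a trivially
unbalanced closing brace; it is treated as a typesetting artifact.

## Reports and screening

`build_report` groups records by (crop, analyte), enforces unit
consistency within a group (mixed units raise, naming the group),
suppresses groups with n < 75 (`min_report_n`, the reporting floor used in
the published tables), and orders rows by crop, then the table category
sequence (proximates, fiber, minerals, amino acids, fatty acids, vitamins,
bio-actives, other metabolites), then input order. Values echo input
precision; no attempt is made to reproduce heterogeneous source rounding.

`screen_test_variety` compares each test measurement, on the effective
scale, against the reference tolerance interval when calculable and the
reference range otherwise. Concurrently grown reference lines widen the
screen bounds to their min/max — supplementing the database-derived range
exactly as equivalence studies use concurrent comparators. Each test
sample is screened independently (point values); a per-analyte
count-of-outside summary is emitted for multi-sample test sets, since no
multi-sample decision rule is standard. How replicate samples from a
multi-location trial should be weighted before screening is an open
question; this package treats each sample as one observation.

## Synthetic data and the coverage experiment

`AnalyteModel` draws i.i.d. values from a normal, lognormal, uniform, or
two-component normal-mixture parent; the mixture emulates analytes whose
database distribution is bimodal because two analytical methods or
germplasm pools feed it (defaults: equal-weight components; callers set
separation). Draws below a model LOQ are emitted as censored records at
that LOQ, as a laboratory would report them. Generation is deterministic
given a seed.

`coverage_experiment` validates the construction's defining guarantee: for
each replicate it draws n values, builds the interval, and measures the
TRUE parent mass inside it via the model's analytic CDF (never a second
sample); the empirical confidence is the fraction of replicates with mass
≥ p. Replicate streams are spawned from one root `SeedSequence`, so runs
are reproducible and order-independent. The test suite runs this at
n = 500, 5000 replicates, for normal, lognormal and uniform parents — the
three estimates must each clear γ minus three Monte-Carlo standard errors
and agree with one another, demonstrating distribution-freeness. The
generator is i.i.d. by design; real composition databases contain
correlated samples (shared trials, years, germplasm), which makes
real-data intervals conservative in coverage but is not modelled here.
Passing tests therefore certify the mathematics of the construction, not
the sampling properties of any particular database.

## Numerical and design choices

- Binomial CDF via `scipy.stats.binom.cdf` (incomplete beta), never naive
  summation; exact-rational oracles in the test suite cross-check it.
- The trim search uses the strict inequality `CDF > γ`; the minimum-n rule
  uses `≥`. At the boundary n = 473 both agree (certainty 0.95020 > 0.95).
- Percent formatting: half-even, three decimals by default; the CLI
  `--precision` flag exposes other precisions.
- Degenerate inputs: empty datasets and non-finite values are rejected;
  n = 1 has range certainty 0; clamped ranks never leave 1…n.
- The CLI is a thin layer over the library; exit codes distinguish usage
  errors (2), malformed input (3) and unit conflicts (4).

## Problem sizes used in the checked examples

The Monte-Carlo validation uses 5000 replicates at n = 500 for the
coverage guarantee and 200 000 uniform draws per configuration (20 random
configurations, n ≤ 50) for the rank-certainty oracle — sizes at which
three Monte-Carlo standard errors resolve the quantities being checked to
well under one percentage point.

## Known limitations

- Two-sided intervals only; one-sided tolerance bounds, parametric
  (normal-theory) intervals and prediction intervals are out of scope.
- Half-LOQ substitution, not censored maximum likelihood; a single
  censoring threshold per value (no LOD/LOQ distinction).
- No variance-component or correlation modelling between varieties,
  sites, or seasons; all records in a group are pooled and treated as
  exchangeable.
- No statistical difference testing (ANOVA) between test and comparator
  lines; screening is interval containment only.
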