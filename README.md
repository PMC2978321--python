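# croptol

Distribution-free tolerance intervals for assessing the **substantial
equivalence** of crop composition.

When a new (typically transgenic) crop variety is evaluated for safety, its
compositional profile — proximates, fiber, minerals, amino acids, fatty
acids, vitamins, anti-nutrients — is compared against the natural variation
of conventional varieties with a history of safe consumption. Because no
single variety is the benchmark, equivalence limits centred on a population
mean are a poor fit: many perfectly safe varieties would fall outside them.
The appropriate clinical-medicine analogue is the **reference interval**: a
tolerance interval built from a large heterogeneous population of safe
varieties, against which an individual test result is screened.

`croptol` implements the nonparametric (order-statistic) version of that
workflow for long-format analyte data such as exports from the ILSI Crop
Composition Database:

- exact certainty that an order-statistic interval \[X₍ₗ₎, X₍ᵤ₎\] of an
  i.i.d. sample of size *n* covers at least a proportion *p* of any
  continuous population:

  γ = P\[ Binomial(n, p) ≤ u − l − 1 \]

- the trim-plan search selecting ranks that attain a requested
  (coverage *p*, certainty γ) pair — the operating point used throughout is
  **99% coverage, 95% certainty**, attainable only for *n* ≥ 473;
- the small-sample fallback: when *n* < 473 the interval is reported
  "not calculable" and the *certainty of the data range*,
  1 − n·pⁿ⁻¹(1−p) − pⁿ, is reported instead;
- below-LOQ (limit of quantification) measurements: ranked and averaged at
  half their LOQ, displayed as `<LOQ`;
- reference-table reports (one row per crop–analyte: N, mean, median,
  range, range certainty, tolerance interval) and screening of
  test-variety values against the resulting intervals, optionally widened
  by concurrently grown reference lines;
- a synthetic-data generator and Monte-Carlo machinery that validate the
  defining guarantee of the construction on normal, lognormal, uniform and
  bimodal-mixture parents.

## Worked example

```python
from croptol import (AnalyteModel, AnalyteRecord, CensoredValue, ToleranceSpec,
                     build_report, generate, report_to_frame, screen_test_variety)

model = AnalyteModel(name="ash", crop="corn", category="proximates",
                     units="% DW", family="lognormal", loc=0.36, scale=0.17)
records = generate(model, 1410, seed=42)          # synthetic reference data
rows = build_report(records, ToleranceSpec(0.99, 0.95))
print(report_to_frame(rows).to_string(index=False))

test = AnalyteRecord("corn", "ash", "proximates", "% DW", CensoredValue(1.52))
[finding] = screen_test_variety([test], rows)
print(finding.verdict, finding.interval_low, finding.interval_high)
```

prints

```
crop analyte   category    n units     mean   median           range certainty_of_range tolerance_interval
corn     ash proximates 1410  % DW 1.447909 1.434171 0.770874–2.4606            99.999%   0.880382–2.31074
within 0.8803820287426496 2.310735440579176
```

At *n* = 1410 the trim plan allocates 4 trimmed points to each tail and
places the endpoints at the 4th and 1407th order statistics, so the
tolerance interval (0.880–2.311 % DW) sits strictly inside the range; the range itself would cover ≥99% of the parent population with
99.999% certainty. The test value 1.52 % DW lies inside the interval, so
the screen returns `within` — no compositional flag for this analyte.

The same operations are available from a shell:

```
$ croptol certainty --n 323      # certainty the range of 323 samples covers 99%
83.410%
$ croptol min-n                  # minimum n for a 99%/95% tolerance interval
473
$ croptol report --input analytes.csv --output report.csv
$ croptol screen --input test.csv --reference ref.csv --output findings.json
$ croptol simulate --n 500 --reps 5000 --family lognormal
```

Input files are headered CSV/TSV with columns
`crop, analyte, category, units, value, below_loq, loq`.

## Documentation

See `docs/methods.md` for the statistical model, its assumptions, the
trim-plan algorithm, LOQ and tie handling, and known limitations.
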