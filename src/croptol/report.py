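"""Composition reports and test-variety screening.

Turns long-format analyte records into the reference-table layout used
for crop-composition substantial-equivalence work — one row per
(crop, analyte) with N, mean, median, range, the certainty that the
range covers >=99% of the population, and the 99%/95% tolerance
interval (or "not calculable" when the sample is too small) — and
screens measurements from a test (e.g. transgenic) variety against the
resulting reference intervals.

Input schema (headered CSV or TSV): ``crop, analyte, category, units,
value, below_loq, loq``.  For censored rows ``below_loq`` is true and
``loq`` carries the limit of quantification; the ``value`` cell is
ignored for those rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .censored import CensoredValue, effective_value, summarize
from .core import (
    ToleranceSpec,
    certainty_percent,
    min_sample_size,
    range_certainty,
    trim_plan,
)

__all__ = [
    "AnalyteRecord",
    "AnalyteReportRow",
    "EquivalenceFinding",
    "UnitConflictError",
    "read_records",
    "build_report",
    "report_to_frame",
    "write_report",
    "render_markdown",
    "screen_test_variety",
    "findings_to_json",
]

NOT_CALCULABLE = "not calculable"

# Category sequence of the reference tables; unknown categories sort after.
CATEGORY_ORDER = (
    "proximates",
    "fiber",
    "minerals",
    "amino acids",
    "fatty acids",
    "vitamins",
    "bio-actives",
    "other metabolites",
)

_TRUTHY = {"true", "t", "1", "yes", "y"}
_FALSY = {"false", "f", "0", "no", "n", ""}


class UnitConflictError(ValueError):
    """Mixed units within one (crop, analyte) group, or test vs reference."""


@dataclass(frozen=True)
class AnalyteRecord:
    """One measurement of one analyte in one crop sample."""

    crop: str
    analyte: str
    category: str
    units: str
    measurement: CensoredValue


@dataclass(frozen=True)
class AnalyteReportRow:
    """One reference-table row for a (crop, analyte) group."""

    crop: str
    analyte: str
    category: str
    n: int
    units: str
    mean: float
    median: float
    range_display: str
    range_certainty: str          # percent, 3 decimals, e.g. '83.410%'
    tolerance_interval: str       # 'low–high' or 'not calculable'
    # numeric endpoints on the effective (half-LOQ) scale, for screening
    range_low: float = field(repr=False, default=float("nan"))
    range_high: float = field(repr=False, default=float("nan"))
    ti_low: float | None = field(repr=False, default=None)
    ti_high: float | None = field(repr=False, default=None)


@dataclass(frozen=True)
class EquivalenceFinding:
    """Verdict for one test-variety measurement against the reference."""

    crop: str
    analyte: str
    test_value: float             # effective scale
    test_display: str
    interval_low: float | None
    interval_high: float | None
    interval_source: str          # 'tolerance_interval' | 'range' | 'none'
    supplemented: bool
    verdict: str                  # 'within' | 'outside' | 'no-reference'


def _parse_bool(x: object, line: int) -> bool:
    s = str(x).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"line {line}: cannot interpret below_loq value {x!r}")


def read_records(path: str | Path) -> list[AnalyteRecord]:
    """Read analyte records from a headered CSV/TSV file.

    Raises ValueError with a line number on malformed rows.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"crop", "analyte", "category", "units", "value", "below_loq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    has_loq = "loq" in df.columns
    records: list[AnalyteRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        censored = _parse_bool(getattr(row, "below_loq"), line)
        try:
            if censored:
                if not has_loq or str(getattr(row, "loq")).strip() == "":
                    raise ValueError("below_loq row without an loq value")
                cv = CensoredValue(float(getattr(row, "loq")), True)
            else:
                cv = CensoredValue(float(getattr(row, "value")), False)
        except ValueError as e:
            raise ValueError(f"line {line}: {e}") from e
        records.append(
            AnalyteRecord(
                crop=str(row.crop),
                analyte=str(row.analyte),
                category=str(row.category),
                units=str(row.units),
                measurement=cv,
            )
        )
    return records


def _group(records: Iterable[AnalyteRecord]) -> dict[tuple[str, str], list[AnalyteRecord]]:
    groups: dict[tuple[str, str], list[AnalyteRecord]] = {}
    for rec in records:
        groups.setdefault((rec.crop, rec.analyte), []).append(rec)
    return groups


def _check_units(key: tuple[str, str], recs: Sequence[AnalyteRecord]) -> str:
    units = {r.units for r in recs}
    if len(units) > 1:
        raise UnitConflictError(
            f"mixed units {sorted(units)} within group crop={key[0]!r} analyte={key[1]!r}"
        )
    return recs[0].units


def _interval_displays(
    values: Sequence[CensoredValue], lower_rank: int, upper_rank: int
) -> tuple[str, str, float, float]:
    """Endpoint display strings and effective values at the given ranks.

    Sorting is stable on the effective (half-LOQ) scale so a censored
    endpoint keeps its identity and is displayed at its own LOQ.
    """
    eff = np.array([effective_value(v) for v in values], dtype=float)
    order = np.argsort(eff, kind="stable")
    lo = values[int(order[lower_rank - 1])]
    hi = values[int(order[upper_rank - 1])]
    return lo.display, hi.display, lo.effective, hi.effective


def build_report(
    records: Iterable[AnalyteRecord],
    spec: ToleranceSpec = ToleranceSpec(),
    min_report_n: int = 75,
    min_ti_n: int | None = None,
) -> list[AnalyteReportRow]:
    """Build reference-table rows from long-format records.

    Groups by (crop, analyte); groups with fewer than ``min_report_n``
    samples are suppressed entirely; groups with fewer than ``min_ti_n``
    (default: the minimum sample size for ``spec``) report
    'not calculable' in the tolerance-interval cell, alongside the range
    and its certainty.  Rows are ordered crop, then category (reference-
    table sequence), then input order.
    """
    records = list(records)
    if not records:
        raise ValueError("records must be non-empty")
    if min_ti_n is None:
        min_ti_n = min_sample_size(spec)
    groups = _group(records)

    cat_rank = {c: i for i, c in enumerate(CATEGORY_ORDER)}
    rows: list[AnalyteReportRow] = []
    for key, recs in groups.items():
        units = _check_units(key, recs)
        n = len(recs)
        if n < min_report_n:
            continue
        values = [r.measurement for r in recs]
        stats = summarize(values, certainty=spec.certainty)
        plan = trim_plan(n, spec)
        rc = range_certainty(n, spec.coverage)
        if plan.feasible and n >= min_ti_n:
            lo_disp, hi_disp, lo_eff, hi_eff = _interval_displays(
                values, plan.lower_rank, plan.upper_rank
            )
            ti_display = f"{lo_disp}–{hi_disp}"
            ti_low, ti_high = lo_eff, hi_eff
        else:
            ti_display = NOT_CALCULABLE
            ti_low = ti_high = None
        rows.append(
            AnalyteReportRow(
                crop=key[0],
                analyte=key[1],
                category=recs[0].category,
                n=n,
                units=units,
                mean=stats.mean,
                median=stats.median,
                range_display=stats.range_display,
                range_certainty=certainty_percent(rc),
                tolerance_interval=ti_display,
                range_low=stats.range_low,
                range_high=stats.range_high,
                ti_low=ti_low,
                ti_high=ti_high,
            )
        )

    order_index = {key: i for i, key in enumerate(groups)}
    rows.sort(
        key=lambda r: (
            r.crop,
            cat_rank.get(r.category, len(CATEGORY_ORDER)),
            order_index[(r.crop, r.analyte)],
        )
    )
    return rows


_REPORT_COLUMNS = [
    "crop",
    "analyte",
    "category",
    "n",
    "units",
    "mean",
    "median",
    "range",
    "certainty_of_range",
    "tolerance_interval",
]


def report_to_frame(rows: Sequence[AnalyteReportRow]) -> pd.DataFrame:
    """Display-oriented DataFrame with the reference-table columns."""
    return pd.DataFrame(
        [
            {
                "crop": r.crop,
                "analyte": r.analyte,
                "category": r.category,
                "n": r.n,
                "units": r.units,
                "mean": r.mean,
                "median": r.median,
                "range": r.range_display,
                "certainty_of_range": r.range_certainty,
                "tolerance_interval": r.tolerance_interval,
            }
            for r in rows
        ],
        columns=_REPORT_COLUMNS,
    )


def render_markdown(rows: Sequence[AnalyteReportRow]) -> str:
    """Render the report as a GitHub-style pipe table."""
    df = report_to_frame(rows)
    cells = df.astype(str)
    header = "| " + " | ".join(df.columns) + " |"
    rule = "| " + " | ".join("---" for _ in df.columns) + " |"
    body = ["| " + " | ".join(row) + " |" for row in cells.itertuples(index=False)]
    return "\n".join([header, rule, *body]) + "\n"


def write_report(
    rows: Sequence[AnalyteReportRow], path: str | Path, fmt: str | None = None
) -> int:
    """Write the report as csv, tsv or md; returns the row count."""
    path = Path(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".md": "md"}.get(path.suffix.lower(), "csv")
    df = report_to_frame(rows)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "tsv":
        df.to_csv(path, index=False, sep="\t")
    elif fmt == "md":
        path.write_text(render_markdown(rows), encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return len(rows)


def screen_test_variety(
    test: Iterable[AnalyteRecord],
    report: Sequence[AnalyteReportRow],
    supplemental_reference: Iterable[AnalyteRecord] | None = None,
) -> list[EquivalenceFinding]:
    """Screen test-variety measurements against reference intervals.

    Each test measurement is compared, on the effective (half-LOQ)
    scale, against the reference tolerance interval when calculable and
    against the reference range otherwise.  Concurrently grown reference
    lines (``supplemental_reference``) widen the interval: the screen
    bound becomes the min/max of the reference interval and the
    supplemental values for that (crop, analyte).  Analytes with no
    reference row yield a 'no-reference' finding.
    """
    by_key: dict[tuple[str, str], AnalyteReportRow] = {
        (r.crop, r.analyte): r for r in report
    }
    supp: dict[tuple[str, str], list[AnalyteRecord]] = (
        _group(supplemental_reference) if supplemental_reference else {}
    )

    findings: list[EquivalenceFinding] = []
    for rec in test:
        key = (rec.crop, rec.analyte)
        row = by_key.get(key)
        x = rec.measurement.effective
        if row is None:
            findings.append(
                EquivalenceFinding(
                    crop=rec.crop,
                    analyte=rec.analyte,
                    test_value=x,
                    test_display=rec.measurement.display,
                    interval_low=None,
                    interval_high=None,
                    interval_source="none",
                    supplemented=False,
                    verdict="no-reference",
                )
            )
            continue
        if rec.units != row.units:
            raise UnitConflictError(
                f"test units {rec.units!r} != reference units {row.units!r} "
                f"for crop={rec.crop!r} analyte={rec.analyte!r}"
            )
        if row.ti_low is not None:
            lo, hi, source = row.ti_low, row.ti_high, "tolerance_interval"
        else:
            lo, hi, source = row.range_low, row.range_high, "range"
        supplemented = False
        for srec in supp.get(key, []):
            if srec.units != row.units:
                raise UnitConflictError(
                    f"supplemental units {srec.units!r} != reference units "
                    f"{row.units!r} for crop={rec.crop!r} analyte={rec.analyte!r}"
                )
            s = srec.measurement.effective
            if s < lo:
                lo, supplemented = s, True
            if s > hi:
                hi, supplemented = s, True
        verdict = "within" if lo <= x <= hi else "outside"
        findings.append(
            EquivalenceFinding(
                crop=rec.crop,
                analyte=rec.analyte,
                test_value=x,
                test_display=rec.measurement.display,
                interval_low=float(lo),
                interval_high=float(hi),
                interval_source=source,
                supplemented=supplemented,
                verdict=verdict,
            )
        )
    return findings


def findings_to_json(findings: Sequence[EquivalenceFinding]) -> str:
    """Serialise findings, with a per-analyte count-of-outside summary."""
    items = [
        {
            "crop": f.crop,
            "analyte": f.analyte,
            "test_value": f.test_value,
            "test_display": f.test_display,
            "interval_low": f.interval_low,
            "interval_high": f.interval_high,
            "interval_source": f.interval_source,
            "supplemented": f.supplemented,
            "verdict": f.verdict,
        }
        for f in findings
    ]
    summary: dict[str, dict[str, int]] = {}
    for f in findings:
        key = f"{f.crop}/{f.analyte}"
        s = summary.setdefault(key, {"n": 0, "outside": 0, "no_reference": 0})
        s["n"] += 1
        if f.verdict == "outside":
            s["outside"] += 1
        elif f.verdict == "no-reference":
            s["no_reference"] += 1
    return json.dumps({"findings": items, "per_analyte": summary}, indent=2)
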