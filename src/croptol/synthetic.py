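"""Synthetic analyte data and Monte-Carlo coverage validation.

Stands in for a real composition database download in tests and
examples.  Models are i.i.d. draws from a normal, lognormal, or
two-component normal mixture parent — the mixture emulates analytes
whose measurements are bimodal because two analytical methods (or two
germplasm pools) feed the database.  Values falling below a model LOQ
are emitted as censored records, exactly as a laboratory would report
them.

``coverage_experiment`` validates the defining guarantee of the
distribution-free construction: the fraction of replicate datasets whose
computed tolerance interval truly contains at least the target coverage
of the parent (measured through the model's analytic CDF) must be at
least the nominal certainty, for any continuous parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .censored import CensoredValue
from .core import ToleranceSpec, min_sample_size, tolerance_interval, trim_plan
from .report import AnalyteRecord

__all__ = ["AnalyteModel", "generate", "coverage_experiment", "CoverageResult"]


@dataclass(frozen=True)
class AnalyteModel:
    """Parametric parent distribution for one synthetic analyte.

    family
        'normal', 'lognormal', 'uniform', or 'mixture' (two normal
        components).
    loc, scale
        Location/scale of the single component (mean/sd for normal;
        log-mean/log-sd for lognormal; lower edge/width for uniform).
    mixture_weight, loc2, scale2
        Weight of the first component and parameters of the second, for
        the mixture family.
    loq
        Limit of quantification; draws strictly below it are emitted as
        censored at the LOQ.  Zero disables censoring.
    """

    name: str = "analyte"
    crop: str = "synthetic"
    category: str = "proximates"
    units: str = "% DW"
    family: str = "normal"
    loc: float = 0.0
    scale: float = 1.0
    mixture_weight: float = 0.5
    loc2: float = 0.0
    scale2: float = 1.0
    loq: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in {"normal", "lognormal", "uniform", "mixture"}:
            raise ValueError(f"unknown family {self.family!r}")
        if self.scale <= 0 or (self.family == "mixture" and self.scale2 <= 0):
            raise ValueError("scales must be positive")
        if self.family == "mixture" and not 0.0 < self.mixture_weight < 1.0:
            raise ValueError("mixture_weight must be in (0, 1)")
        if self.loq < 0:
            raise ValueError("loq must be >= 0")

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "normal":
            return rng.normal(self.loc, self.scale, n)
        if self.family == "lognormal":
            return rng.lognormal(self.loc, self.scale, n)
        if self.family == "uniform":
            return rng.uniform(self.loc, self.loc + self.scale, n)
        comp = rng.random(n) < self.mixture_weight
        draws = np.where(
            comp,
            rng.normal(self.loc, self.scale, n),
            rng.normal(self.loc2, self.scale2, n),
        )
        return draws

    def cdf(self, x: np.ndarray | float) -> np.ndarray | float:
        """Analytic parent CDF (used to measure true interval coverage)."""
        if self.family == "normal":
            return stats.norm.cdf(x, self.loc, self.scale)
        if self.family == "lognormal":
            return stats.lognorm.cdf(x, s=self.scale, scale=np.exp(self.loc))
        if self.family == "uniform":
            return stats.uniform.cdf(x, self.loc, self.scale)
        w = self.mixture_weight
        return w * stats.norm.cdf(x, self.loc, self.scale) + (1 - w) * stats.norm.cdf(
            x, self.loc2, self.scale2
        )


def generate(model: AnalyteModel, n: int, seed: int = 0) -> list[AnalyteRecord]:
    """Draw ``n`` records from ``model``; deterministic given ``seed``.

    Draws below the model LOQ become censored records carrying the LOQ.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    draws = model.rvs(n, rng)
    records = []
    for x in draws:
        if model.loq > 0 and x < model.loq:
            cv = CensoredValue(model.loq, True)
        else:
            cv = CensoredValue(float(x), False)
        records.append(
            AnalyteRecord(
                crop=model.crop,
                analyte=model.name,
                category=model.category,
                units=model.units,
                measurement=cv,
            )
        )
    return records


@dataclass(frozen=True)
class CoverageResult:
    """Outcome of a Monte-Carlo coverage experiment."""

    n: int
    reps: int
    seed: int
    spec: ToleranceSpec
    empirical_confidence: float
    mean_true_coverage: float = field(repr=False, default=float("nan"))


def coverage_experiment(
    model: AnalyteModel,
    n: int,
    spec: ToleranceSpec = ToleranceSpec(),
    reps: int = 5000,
    seed: int = 0,
) -> CoverageResult:
    """Estimate the realised certainty of the tolerance-interval rule.

    For each replicate, draws ``n`` values from the model, constructs
    the tolerance interval, and computes the TRUE parent mass inside it
    via the model CDF; returns the fraction of replicates whose mass is
    at least ``spec.coverage``.  Distribution-freeness means the result
    depends only on (n, spec), not on the model, up to Monte-Carlo
    error.

    Replicate streams derive from one root seed through
    ``np.random.SeedSequence(seed).spawn`` so the experiment is
    reproducible and order-independent.
    """
    if n < min_sample_size(spec):
        plan = trim_plan(n, spec)
        raise ValueError(
            f"n={n} is below the minimum sample size {min_sample_size(spec)} for "
            f"coverage={spec.coverage}, certainty={spec.certainty} "
            f"(trim plan feasible={plan.feasible})"
        )
    if reps < 1:
        raise ValueError("reps must be >= 1")
    children = np.random.SeedSequence(seed).spawn(reps)
    hits = 0
    masses = np.empty(reps)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sample = model.rvs(n, rng)
        res = tolerance_interval(sample, spec)
        mass = float(model.cdf(res.upper) - model.cdf(res.lower))
        masses[i] = mass
        if mass >= spec.coverage:
            hits += 1
    return CoverageResult(
        n=n,
        reps=reps,
        seed=seed,
        spec=spec,
        empirical_confidence=hits / reps,
        mean_true_coverage=float(masses.mean()),
    )
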