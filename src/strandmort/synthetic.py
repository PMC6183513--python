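"""Synthetic stranding scenarios with known ground truth.

Every estimator in this package is exercised against data whose generating
process is known exactly.  A scenario mimics how a stranding record with
bycatch arises: natural deaths drawn from a Siler age-at-death distribution
(the baseline mortality of a long-lived coastal dolphin population), plus a
pulse of bycaught animals whose ages are normally distributed with mode
before maturity, optionally thinned at the youngest ages to mimic the
under-detection of calf carcasses.

The default scenario sizes follow the bottlenose dolphin worked example:
220 natural strandings with 80 bycaught animals added (mean age 3 yr,
sd 1.5 yr), ages up to 30.  Cause-of-death labels are carried on the
records for diagnostics but are never given to the estimators -- the whole
point of the method is to work without cause-resolved data.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from ._util import substream
from .life_tables import AgeSample
from .siler import SilerParams, siler_age_distribution

__all__ = ["ScenarioSpec", "DEFAULT_SILER", "simulate_natural",
           "simulate_bycatch", "thin_young", "simulate_scenario",
           "simulate_from_qx", "true_total_qx"]

#: Baseline natural mortality: high first-year mortality (~24%), a small
#: constant background risk, and senescence taking hold past ~20 yr, so
#: that survival to age 30 is below 0.1% -- a realistic schedule for a
#: coastal bottlenose dolphin population.
DEFAULT_SILER = SilerParams(a1=0.25, b1=0.6, a2=0.02, a3=0.004, b3=0.19)


@dataclass(frozen=True)
class ScenarioSpec:
    """Generating process for one synthetic stranding dataset."""

    siler: SilerParams = DEFAULT_SILER
    n_natural: int = 220
    n_bycatch: int = 80
    bycatch_mean_age: float = 3.0
    bycatch_sd: float = 1.5
    retention: dict[int, float] | None = None  # per-age keep probability
    max_age: int = 30
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_natural < 0 or self.n_bycatch < 0:
            raise ValueError("counts must be >= 0")
        if self.bycatch_sd <= 0:
            raise ValueError("bycatch_sd must be > 0")
        if self.max_age < 1:
            raise ValueError("max_age must be >= 1")
        if self.retention is not None:
            for age, r in self.retention.items():
                if not 0 <= r <= 1:
                    raise ValueError(f"retention[{age}] outside [0, 1]")


def simulate_natural(spec: ScenarioSpec) -> AgeSample:
    """Natural deaths: one multinomial draw from the Siler age-at-death pmf."""
    rng = substream(spec.seed, "natural")
    f = siler_age_distribution(spec.siler, spec.max_age)
    counts = rng.multinomial(spec.n_natural, f)
    ages = np.repeat(np.arange(spec.max_age + 1, dtype=float), counts)
    return AgeSample(ages, np.full(ages.size, "natural", dtype=object))


def simulate_bycatch(spec: ScenarioSpec) -> AgeSample:
    """Bycaught animals: truncated-normal ages rounded to integer classes."""
    rng = substream(spec.seed, "bycatch")
    lo = (0.0 - spec.bycatch_mean_age) / spec.bycatch_sd
    hi = (spec.max_age - spec.bycatch_mean_age) / spec.bycatch_sd
    raw = truncnorm.rvs(lo, hi, loc=spec.bycatch_mean_age,
                        scale=spec.bycatch_sd, size=spec.n_bycatch,
                        random_state=rng)
    ages = np.clip(np.rint(raw), 0, spec.max_age).astype(float)
    return AgeSample(ages, np.full(ages.size, "anthropogenic", dtype=object))


def thin_young(sample: AgeSample, retention: dict[int, float],
               seed: int | None = 0) -> AgeSample:
    """Keep each record of age x independently with probability retention[x].

    Ages absent from ``retention`` are always kept.  Models the lower
    recovery probability of young carcasses.
    """
    rng = substream(seed, "thinning")
    p_keep = np.array([retention.get(int(np.floor(a)), 1.0)
                       for a in sample.ages])
    keep = rng.random(len(sample)) < p_keep
    cause = sample.cause[keep] if sample.cause is not None else None
    return AgeSample(sample.ages[keep], cause)


def simulate_scenario(spec: ScenarioSpec) -> AgeSample:
    """Full scenario: natural + bycatch deaths, then optional thinning."""
    combined = simulate_natural(spec).concat(simulate_bycatch(spec))
    if spec.retention:
        combined = thin_young(combined, spec.retention, seed=spec.seed)
    return combined


def simulate_from_qx(q, n: int, seed: int | None = 0) -> AgeSample:
    """Ages at death drawn from an arbitrary death-probability schedule.

    The cohort pmf is f(x) = l(x) - l(x+1) with l from the q-recursion and
    all survivors past the last class lumped into it (cohort closure); one
    multinomial draw of size ``n`` gives the sample.  Lets any fitted or
    hand-built q(x) curve -- e.g. an adapted Heligman-Pollard schedule --
    act as a generating truth.
    """
    from .life_tables import cumulative_survival
    q = np.asarray(q, dtype=float)
    l = cumulative_survival(np.append(q, 1.0))
    f = np.append(l[:-1] - l[1:], l[-1])
    rng = substream(seed, "natural")
    counts = rng.multinomial(n, f / f.sum())
    ages = np.repeat(np.arange(f.size, dtype=float), counts)
    return AgeSample(ages)


def _bycatch_pmf(spec: ScenarioSpec) -> np.ndarray:
    """Exact pmf of the rounded, truncated-normal bycatch age."""
    lo = (0.0 - spec.bycatch_mean_age) / spec.bycatch_sd
    hi = (spec.max_age - spec.bycatch_mean_age) / spec.bycatch_sd
    dist = truncnorm(lo, hi, loc=spec.bycatch_mean_age, scale=spec.bycatch_sd)
    edges = np.arange(spec.max_age + 2) - 0.5  # rint bin edges
    cdf = dist.cdf(np.clip(edges, 0.0, spec.max_age))
    return np.diff(cdf)


def true_total_qx(spec: ScenarioSpec) -> np.ndarray:
    """Exact total death probability q(x) implied by the scenario mixture.

    The combined age-at-death pmf mixes the Siler pmf and the discretised
    bycatch pmf in proportion to the expected sample composition; q(x) is
    that mixture's discrete hazard.  This is the ground truth the aHP total
    curve is judged against.
    """
    n_tot = spec.n_natural + spec.n_bycatch
    if n_tot == 0:
        raise ValueError("empty scenario")
    f = (spec.n_natural * siler_age_distribution(spec.siler, spec.max_age)
         + spec.n_bycatch * _bycatch_pmf(spec)) / n_tot
    S = np.cumsum(f[::-1])[::-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(S > 0, f / np.where(S > 0, S, 1.0), 1.0)
    return q
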