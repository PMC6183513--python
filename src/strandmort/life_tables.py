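"""Cohort life tables built from ages-at-death of stranded animals.

A stranding record gives one age at death per carcass.  Treating the whole
sample as a single synthetic cohort (stationary age structure assumed), the
number still alive at the start of age class x is the count of deaths at age
x or older, and the usual life-table columns follow.  Tables can also be
rebuilt from a model-estimated death-probability schedule q(x), which is how
fitted Siler or Heligman-Pollard curves are turned back into survivorship
and life expectancy.

Columns
-------
x : age class start (years)
N : observed deaths in the class
S : number alive entering the class, scaled to the radix
l : survivorship proportion, l(0) = 1
d : proportion of the cohort dying in the class, d(x) = l(x) - l(x+1)
q : probability of dying in [x, x+1) given alive at x
e : remaining life expectancy at x (years), person-years by the midpoint
    convention L(x) = (l(x) + l(x+1)) / 2
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AgeSample", "LifeTable", "build_life_table", "life_table_from_qx",
           "cumulative_survival"]

VALID_CAUSES = ("natural", "anthropogenic", "unknown")


@dataclass(frozen=True)
class AgeSample:
    """Observed ages at death, optionally labelled with a cause of death.

    Ages may be fractional; all table construction bins them to integer
    classes by truncation (ages read from tooth growth layers are whole
    years; fractional calf ages fall into class 0).
    """

    ages: np.ndarray
    cause: np.ndarray | None = None

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        if ages.ndim != 1:
            raise ValueError("ages must be one-dimensional")
        if ages.size and (not np.all(np.isfinite(ages)) or np.any(ages < 0)):
            raise ValueError("invalid age: ages must be finite and >= 0")
        object.__setattr__(self, "ages", ages)
        if self.cause is not None:
            cause = np.asarray(self.cause, dtype=object)
            if cause.shape != ages.shape:
                raise ValueError("cause must align with ages")
            bad = set(cause) - set(VALID_CAUSES)
            if bad:
                raise ValueError(f"unknown cause labels: {sorted(map(str, bad))}")
            object.__setattr__(self, "cause", cause)

    def __len__(self) -> int:
        return self.ages.size

    def binned_counts(self, max_age: int | None = None) -> np.ndarray:
        """Deaths per integer age class 0..max_age (floor binning)."""
        if len(self) == 0:
            raise ValueError("no ages")
        classes = np.floor(self.ages).astype(int)
        top = int(classes.max()) if max_age is None else int(max_age)
        if top < classes.max():
            raise ValueError("max_age below the oldest observed age")
        return np.bincount(classes, minlength=top + 1)

    def concat(self, other: "AgeSample") -> "AgeSample":
        ages = np.concatenate([self.ages, other.ages])
        if self.cause is None and other.cause is None:
            return AgeSample(ages)
        mine = self.cause if self.cause is not None else np.full(len(self), "unknown", object)
        theirs = other.cause if other.cause is not None else np.full(len(other), "unknown", object)
        return AgeSample(ages, np.concatenate([mine, theirs]))


@dataclass(frozen=True)
class LifeTable:
    x: np.ndarray
    N: np.ndarray
    S: np.ndarray
    l: np.ndarray
    d: np.ndarray
    q: np.ndarray
    e: np.ndarray
    radix: float = field(default=1000.0)

    def __post_init__(self) -> None:
        n = self.x.size
        for name in ("N", "S", "l", "d", "q", "e"):
            if getattr(self, name).size != n:
                raise ValueError(f"column {name} has wrong length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.x, "N": self.N, "S": self.S, "l": self.l,
             "d": self.d, "q": self.q, "e": self.e}
        )


def _columns_from_l(l: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """d, q, e from a survivorship vector with implicit l beyond the end = 0."""
    l_next = np.append(l[1:], 0.0)
    d = l - l_next
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(l > 0, d / l, 1.0)
    L = (l + l_next) / 2.0
    T = np.cumsum(L[::-1])[::-1]
    e = np.where(l > 0, T / np.where(l > 0, l, 1.0), 0.0)
    return d, q, e


def build_life_table(sample: AgeSample, radix: float = 1000.0) -> LifeTable:
    """Cohort life table from observed ages at death.

    S(x) counts deaths at age x or older; q(x) = N(x)/S(x); the oldest
    observed class closes the cohort with q = 1.
    """
    if len(sample) == 0:
        raise ValueError("no ages")
    if radix <= 0:
        raise ValueError("radix must be positive")
    N = sample.binned_counts().astype(float)
    S = np.cumsum(N[::-1])[::-1]
    l = S / S[0]
    d, q, e = _columns_from_l(l)
    x = np.arange(N.size)
    return LifeTable(x=x, N=N, S=radix * l, l=l, d=d, q=q, e=e, radix=radix)


def life_table_from_qx(q, radix: float = 1000.0) -> LifeTable:
    """Life table implied by a death-probability schedule q(0..omega).

    q at the final class is forced to 1 (cohort closure); everything else
    follows from l(x+1) = l(x)(1 - q(x)).
    """
    q = np.asarray(q, dtype=float).copy()
    if q.ndim != 1 or q.size == 0:
        raise ValueError("q must be a non-empty vector")
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("q values must lie in [0, 1]")
    if q[-1] != 1.0:
        q = np.append(q, 1.0)
    l = cumulative_survival(q)
    d, q_out, e = _columns_from_l(l)
    x = np.arange(q.size)
    N = radix * d
    return LifeTable(x=x, N=N, S=radix * l, l=l, d=d, q=q_out, e=e, radix=radix)


def cumulative_survival(q) -> np.ndarray:
    """Survivorship at the start of each class: l(x) = prod_{y<x} (1 - q(y)).

    Same length as q, with l(0) = 1; q at the last class only closes the
    cohort and does not open a further class.  This is the vector a Leslie
    matrix is assembled from.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 1 or q.size == 0:
        raise ValueError("q must be a non-empty vector")
    if np.any(q < 0) or np.any(q > 1) or not np.all(np.isfinite(q)):
        raise ValueError("q values must lie in [0, 1]")
    return np.concatenate([[1.0], np.cumprod(1.0 - q[:-1])])
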