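"""Five-parameter Siler competing-risk mortality model.

The Siler model writes survivorship as the product of three independent
competing risks

    l(x) = l_j(x) * l_c(x) * l_s(x)

with a juvenile risk that decays exponentially with age, a constant risk
felt by every age class, and a senescent risk that grows exponentially:

    l_j(x) = exp((-a1/b1) (1 - exp(-b1 x)))
    l_c(x) = exp(-a2 x)
    l_s(x) = exp(( a3/b3) (1 - exp( b3 x)))

equivalently a total hazard mu(x) = a1 exp(-b1 x) + a2 + a3 exp(b3 x).
It fits long-lived mammals well but cannot separate natural from
anthropogenic mortality; for that, see :mod:`strandmort.heligman_pollard`.

Fitting maximises the multinomial likelihood of the observed age-at-death
frequencies under the discrete age-at-death distribution implied by l(x).
Stranding samples often under-represent the youngest classes (calves are
eaten, decompose fast, or are missed); the ``rm`` argument drops the first
age classes from the likelihood, renormalising over the retained ones, and
the fitted curve then predicts mortality for *all* ages including the
removed classes.
"""
from __future__ import annotations

from dataclasses import dataclass, astuple

import numpy as np
from scipy.optimize import minimize

from .life_tables import AgeSample

__all__ = ["SilerParams", "MortalitySchedule", "siler_survivorship",
           "siler_hazard", "siler_qx", "siler_age_distribution", "fit_siler",
           "SilerFitError", "DEFAULT_INIT"]

N_SILER_PARAMS = 5


@dataclass(frozen=True)
class SilerParams:
    """Siler hazard parameters (all per-year rates, all >= 0)."""

    a1: float  # juvenile hazard scale
    b1: float  # juvenile decline rate
    a2: float  # constant hazard
    a3: float  # senescent hazard scale
    b3: float  # senescent increase rate

    def __post_init__(self) -> None:
        vals = astuple(self)
        if not all(np.isfinite(v) and v >= 0 for v in vals):
            raise ValueError("Siler parameters must be finite and >= 0")

    def as_array(self) -> np.ndarray:
        return np.array(astuple(self), dtype=float)


@dataclass(frozen=True)
class MortalitySchedule:
    """Per-age mortality split into components; ``kind`` is 'hazard' or 'qx'."""

    ages: np.ndarray
    components: dict[str, np.ndarray]
    total: np.ndarray
    kind: str


DEFAULT_INIT = SilerParams(a1=0.1, b1=0.5, a2=0.05, a3=0.01, b3=0.1)


class SilerFitError(RuntimeError):
    """Optimisation failed; carries the best parameters found so far."""

    def __init__(self, message: str, best_params: SilerParams | None = None,
                 objective: float = np.inf):
        super().__init__(message)
        self.best_params = best_params
        self.objective = objective


def _check_ages(ages) -> np.ndarray:
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < 0) or not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite and >= 0")
    return ages


def siler_survivorship(p: SilerParams, ages) -> np.ndarray:
    """l(x) as the product of the three competing-risk survivorships."""
    x = _check_ages(ages)
    if p.b1 > 0:
        log_lj = (-p.a1 / p.b1) * (1.0 - np.exp(-p.b1 * x))
    else:  # b1 -> 0 limit: constant juvenile hazard a1
        log_lj = -p.a1 * x
    log_lc = -p.a2 * x
    if p.b3 > 0:
        log_ls = (p.a3 / p.b3) * (1.0 - np.exp(p.b3 * x))
    else:
        log_ls = -p.a3 * x
    return np.exp(log_lj + log_lc + log_ls)


def siler_hazard(p: SilerParams, ages) -> MortalitySchedule:
    """Component hazards mu_j, mu_c, mu_s and their sum."""
    x = _check_ages(ages)
    mu_j = p.a1 * np.exp(-p.b1 * x)
    mu_c = np.full_like(x, p.a2, dtype=float)
    mu_s = p.a3 * np.exp(p.b3 * x)
    comps = {"juvenile": mu_j, "constant": mu_c, "senescent": mu_s}
    return MortalitySchedule(ages=x, components=comps,
                             total=mu_j + mu_c + mu_s, kind="hazard")


def siler_qx(p: SilerParams, ages) -> np.ndarray:
    """Annual death probability q(x) = 1 - l(x+1)/l(x)."""
    x = _check_ages(ages)
    l_x = siler_survivorship(p, x)
    l_next = siler_survivorship(p, x + 1.0)
    with np.errstate(invalid="ignore"):
        q = np.where(l_x > 0, 1.0 - l_next / l_x, 1.0)
    return q


def siler_age_distribution(p: SilerParams, max_age: int) -> np.ndarray:
    """Discrete age-at-death pmf over classes 0..max_age.

    f(x) = l(x) - l(x+1) for x < max_age, with the whole tail l(max_age)
    lumped into the terminal class so the pmf sums to one exactly.
    """
    if max_age < 1:
        raise ValueError("max_age must be >= 1")
    l = siler_survivorship(p, np.arange(max_age + 1))
    f = np.empty(max_age + 1)
    f[:-1] = l[:-1] - l[1:]
    f[-1] = l[-1]
    return f


def _neg_loglik_multinomial(p: SilerParams, counts: np.ndarray, rm: int,
                            max_age: int) -> float:
    f = siler_age_distribution(p, max_age)[rm:]
    total = f.sum()
    if total <= 0 or np.any(f < 0):
        return np.inf
    f = f / total
    n = counts[rm:]
    with np.errstate(divide="ignore"):
        terms = np.where(n > 0, n * np.log(np.where(f > 0, f, 1.0)), 0.0)
    if np.any((n > 0) & (f <= 0)):
        return np.inf
    return -float(terms.sum())


def _neg_ss_log_hazard(p: SilerParams, counts: np.ndarray, rm: int,
                       max_age: int) -> float:
    # Least-squares on log hazard, the alternative objective: empirical
    # hazard from the cohort table, mu_hat = -ln(1 - q_hat), terminal class
    # (q_hat = 1) excluded.
    S = np.cumsum(counts[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        q_hat = np.where(S > 0, counts / np.where(S > 0, S, 1), np.nan)
    x = np.arange(counts.size)
    keep = (x >= rm) & (q_hat > 0) & (q_hat < 1)
    if keep.sum() < N_SILER_PARAMS:
        return np.inf
    mu_hat = -np.log(1.0 - q_hat[keep])
    mu = siler_hazard(p, x[keep]).total
    if np.any(mu <= 0):
        return np.inf
    return float(np.sum((np.log(mu) - np.log(mu_hat)) ** 2))


def fit_siler(sample: AgeSample, rm: int = 0,
              init: SilerParams = DEFAULT_INIT, max_age: int | None = None,
              objective: str = "multinomial", n_restarts: int = 10,
              seed: int = 0) -> tuple[SilerParams, float]:
    """Fit the Siler model to ages at death by Nelder-Mead.

    Parameters are optimised on the log scale (positivity for free); the
    default objective is the multinomial negative log-likelihood of the
    binned age frequencies, with the first ``rm`` classes excluded and the
    pmf renormalised over the retained classes.  ``n_restarts`` jittered
    starts guard against the flat ridges typical of this surface.

    Returns the fitted parameters and the objective value at the optimum.
    """
    if len(sample) == 0:
        raise ValueError("no ages")
    counts = sample.binned_counts(max_age=max_age).astype(float)
    if max_age is None:
        max_age = counts.size  # max observed age + 1
        counts = np.append(counts, 0.0)
    if rm >= np.count_nonzero(counts[: counts.size]):
        raise ValueError("rm leaves no observed age classes")
    if np.count_nonzero(counts[rm:]) < 2:
        raise ValueError("need at least two observed age classes to fit")

    obj_fun = {"multinomial": _neg_loglik_multinomial,
               "log_hazard_ls": _neg_ss_log_hazard}.get(objective)
    if obj_fun is None:
        raise ValueError(f"unknown objective {objective!r}")

    def wrapped(log_theta: np.ndarray) -> float:
        p = SilerParams(*np.exp(log_theta))
        val = obj_fun(p, counts, rm, max_age)
        return val if np.isfinite(val) else 1e12  # keep the simplex finite

    rng = np.random.default_rng(seed)
    theta0 = np.log(np.maximum(init.as_array(), 1e-8))
    starts = [theta0] + [theta0 + rng.normal(0, 0.5, size=5)
                         for _ in range(n_restarts)]
    best = None
    for s in starts:
        res = minimize(wrapped, s, method="Nelder-Mead",
                       options={"maxiter": 4000, "maxfev": 4000,
                                "xatol": 1e-8, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        p = SilerParams(*np.exp(best.x)) if best is not None else None
        raise SilerFitError("Siler fit did not converge", best_params=p,
                            objective=best.fun if best else np.inf)
    return SilerParams(*np.exp(best.x)), float(best.fun)
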