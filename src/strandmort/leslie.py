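"""Leslie matrix projections and demographic eigen-analysis.

A Leslie matrix A carries per-class fertilities on its top row and annual
survival probabilities on the subdiagonal; iterating N_{t+1} = A N_t
projects the female population forward.  Its dominant (Perron) eigenvalue
lambda is the asymptotic annual growth factor, the right eigenvector the
stable age distribution, the left eigenvector the reproductive values, and
the sensitivity/elasticity matrices say which vital rates drive lambda.

The census convention is post-breeding birth-pulse: a female counted in
class i at time t must survive the year (P_i = 1 - q_i) and then, entering
class i+1, produce m_{i+1} calves of which a fraction ``sex_ratio`` are
female, so F_i = P_i * sex_ratio * m_{i+1} and the terminal class has
F_omega = 0.  Only female offspring are counted (males are assumed never
limiting).

Derived population parameters: net production R0 = sum_x l(x) F_x (female
calves per average female lifetime, l from cumulative survival), and
generation time T = ln(R0)/ln(lambda), with the cohort formula
sum_x x l(x) F_x / R0 as the stationary-population (lambda = 1) fallback.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .life_tables import cumulative_survival

__all__ = ["LeslieMatrix", "DemographicStats", "build_leslie", "project",
           "eigen_analysis", "DEFAULT_PROJECTION_YEARS"]

DEFAULT_PROJECTION_YEARS = 100


@dataclass(frozen=True)
class LeslieMatrix:
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("Leslie matrix must be square")
        if np.any(m < 0):
            raise ValueError("Leslie matrix must be non-negative")
        sub = np.diag(m, -1)
        if np.any(sub > 1):
            raise ValueError("survival probabilities must be <= 1")
        object.__setattr__(self, "matrix", m)

    @property
    def fertilities(self) -> np.ndarray:
        return self.matrix[0]

    @property
    def survival(self) -> np.ndarray:
        return np.diag(self.matrix, -1)

    @property
    def order(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class DemographicStats:
    lambda_: float                # annual multiplicative growth
    r: float                      # intrinsic rate of increase, ln(lambda)
    stable_age: np.ndarray        # right eigenvector, proportions
    repro_value: np.ndarray       # left eigenvector, v_0 = 1
    sensitivity: np.ndarray
    elasticity: np.ndarray
    R0: float                     # net production
    generation_time: float        # ln(R0)/ln(lambda); cohort form at lambda=1
    generation_time_cohort: float


def build_leslie(q, m, sex_ratio: float = 0.5) -> LeslieMatrix:
    """Assemble a Leslie matrix from q(x) and a maternity schedule m(x).

    ``m`` is calves (both sexes) per female per year, typically a pregnancy
    rate; only the female fraction enters the top row.
    """
    q = np.asarray(q, dtype=float)
    m = np.asarray(m, dtype=float)
    if q.shape != m.shape or q.ndim != 1:
        raise ValueError("q and m must be equal-length vectors")
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("q values must lie in [0, 1]")
    if np.any(m < 0):
        raise ValueError("maternity values must be >= 0")
    if not 0 <= sex_ratio <= 1:
        raise ValueError("sex_ratio must lie in [0, 1]")
    n = q.size
    P = 1.0 - q
    F = np.zeros(n)
    F[:-1] = P[:-1] * sex_ratio * m[1:]
    A = np.zeros((n, n))
    A[0] = F
    A[np.arange(1, n), np.arange(n - 1)] = P[:-1]
    return LeslieMatrix(A)


def project(A: LeslieMatrix, n0, years: int = DEFAULT_PROJECTION_YEARS
            ) -> np.ndarray:
    """Iterate N_{t+1} = A N_t; returns a (years+1, order) trajectory."""
    n0 = np.asarray(n0, dtype=float)
    if n0.shape != (A.order,):
        raise ValueError("n0 length must match the matrix order")
    if np.any(n0 < 0):
        raise ValueError("n0 must be non-negative")
    out = np.empty((years + 1, A.order))
    out[0] = n0
    for t in range(years):
        out[t + 1] = A.matrix @ out[t]
    return out


def _dominant_eigen(m: np.ndarray):
    vals, vecs = np.linalg.eig(m)
    top = np.max(np.abs(vals))
    # the Perron root: real, positive, of maximal modulus
    cand = [i for i in range(vals.size)
            if abs(abs(vals[i]) - top) < 1e-9 * max(top, 1.0)
            and abs(vals[i].imag) < 1e-9 * max(top, 1.0)
            and vals[i].real >= 0]
    if not cand:
        raise ValueError("no Perron root")
    i = max(cand, key=lambda j: vals[j].real)
    lam = float(vals[i].real)
    w = np.abs(np.real(vecs[:, i]))
    lvals, lvecs = np.linalg.eig(m.T)
    j = int(np.argmin(np.abs(lvals - lam)))
    v = np.abs(np.real(lvecs[:, j]))
    return lam, w, v


def eigen_analysis(A: LeslieMatrix) -> DemographicStats:
    """Demographic parameters of a Leslie matrix.

    Trailing post-reproductive classes (zero fertility beyond the last
    fertile age) make the matrix reducible; they are trimmed before the
    eigendecomposition and the eigenvectors padded back, extending the
    stable age structure by w_{i+1} = P_i w_i / lambda and assigning those
    classes zero reproductive value.
    """
    F = A.fertilities
    P_full = A.survival
    fertile = np.nonzero(F > 0)[0]
    k = int(fertile[-1]) if fertile.size else A.order - 1
    m = A.matrix[: k + 1, : k + 1]
    lam, w, v = _dominant_eigen(m)

    # pad back to the full order
    w_full = np.zeros(A.order)
    w_full[: k + 1] = w
    for i in range(k, A.order - 1):
        w_full[i + 1] = P_full[i] * w_full[i] / lam if lam > 0 else 0.0
    v_full = np.zeros(A.order)
    v_full[: k + 1] = v
    stable_age = w_full / w_full.sum()
    if v_full[0] <= 0:
        raise ValueError("no Perron root")
    repro_value = v_full / v_full[0]

    sens = np.zeros((A.order, A.order))
    denom = float(v_full[: k + 1] @ w_full[: k + 1])
    if denom > 0:
        sens[: k + 1, : k + 1] = np.outer(v_full[: k + 1],
                                          w_full[: k + 1]) / denom
    with np.errstate(invalid="ignore", divide="ignore"):
        elas = np.where(A.matrix > 0, (A.matrix / lam) * sens, 0.0) \
            if lam > 0 else np.zeros_like(sens)

    l = cumulative_survival(np.append(1.0 - P_full, 1.0))
    R0 = float(np.sum(l * F))
    ages = np.arange(A.order)
    T_cohort = float(np.sum(ages * l * F) / R0) if R0 > 0 else np.nan
    if R0 > 0 and abs(lam - 1.0) > 1e-9:
        T = float(np.log(R0) / np.log(lam))
    else:
        T = T_cohort
    return DemographicStats(lambda_=lam, r=float(np.log(lam)) if lam > 0 else -np.inf,
                            stable_age=stable_age, repro_value=repro_value,
                            sensitivity=sens, elasticity=elas, R0=R0,
                            generation_time=T, generation_time_cohort=T_cohort)
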