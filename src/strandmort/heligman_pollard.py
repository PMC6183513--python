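"""Adapted Heligman-Pollard (aHP) mortality model and its Bayesian fit.

The classical Heligman-Pollard model describes the probability of dying
q(x) as the sum of three terms: a rapidly declining infant-mortality curve
A^((x+B)^C), a lognormal "accident hump" D exp(-E (ln(x/F))^2) concentrated
around age F, and a logistic (Gompertz-like) adult rise G H^x / (1 + G H^x).
In human demography the hump captures an external shock (war, epidemic); for
cetaceans it captures bycatch, which strikes mostly young animals.  Because
bycatch of age-0 animals is real, the classical hump -- which vanishes at
x = 0 -- is too rigid, and a ninth parameter I lifts the hump's baseline:

    q(x) = A^((x+B)^C) + [ I + D exp(-E (ln(x/F))^2) ] + G H^x / (1 + G H^x)

The natural component is the infant + adult terms; the anthropogenic
component is the bracketed hump.  Fitting only needs aged strandings -- no
fishery observer data.

Inference is Bayesian melding: uniform box priors on the nine parameters, a
binomial likelihood for deaths-given-at-risk per age class (at-risk counts
from the observed cohort's cumulative survival), posterior explored with
Incremental Mixture Importance Sampling (IMIS).  IMIS seeds the posterior
modes with a round of derivative-free optimisation, surrounds each mode and
each subsequent highest-weight point with a multivariate-normal mixture
component, and reweights the growing pool by prior x likelihood / envelope
until the importance weights are reasonably uniform (expected unique
fraction of the final resample >= 1 - 1/e), then resamples parameter sets
in proportion to weight.
"""
from __future__ import annotations

from dataclasses import dataclass, astuple, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import multivariate_normal, multivariate_t

from .life_tables import AgeSample
from .siler import MortalitySchedule

__all__ = ["AHPParams", "PriorSpec", "PosteriorSample", "DeathsAtAge",
           "AHP_PARAM_NAMES", "HP_PARAM_NAMES", "IMIS_STOP_FRACTION",
           "ahp_qx", "hp_qx", "decompose", "draw_priors", "ahp_loglik",
           "deaths_at_age", "fit_ahp", "predict_ahp", "hump_peak_age",
           "DEFAULT_PRIOR_BOUNDS"]

AHP_PARAM_NAMES = ("A", "B", "C", "D", "E", "F", "G", "H", "I")
HP_PARAM_NAMES = AHP_PARAM_NAMES[:-1]  # the unadapted 8-parameter model

#: IMIS stops early once the expected fraction of unique rows in the final
#: resample reaches 1 - 1/e.
IMIS_STOP_FRACTION = 1.0 - 1.0 / np.e

#: Wide default prior boxes; real analyses should narrow these from biology.
DEFAULT_PRIOR_BOUNDS = {
    "A": (1e-5, 0.5),   # infant mortality level
    "B": (1e-3, 2.0),   # age shift of the infant decline (yr)
    "C": (1e-3, 2.0),   # rate of decline of infant mortality
    "D": (0.0, 0.5),    # hump severity
    "E": (1e-3, 10.0),  # hump spread (larger = narrower)
    "F": (0.5, 15.0),   # hump location (yr)
    "G": (1e-6, 0.1),   # base adult mortality level
    "H": (1.0, 1.5),    # rate of increase of adult mortality
    "I": (0.0, 0.5),    # hump baseline offset
}


@dataclass(frozen=True)
class AHPParams:
    A: float
    B: float
    C: float
    D: float
    E: float
    F: float
    G: float
    H: float
    I: float

    def __post_init__(self) -> None:
        v = self.as_array()
        if not np.all(np.isfinite(v)):
            raise ValueError("aHP parameters must be finite")
        if min(self.A, self.B, self.C, self.D, self.E, self.G, self.I) < 0:
            raise ValueError("aHP parameters must be >= 0")
        if self.A >= 1:
            raise ValueError("A must be < 1")
        if self.F <= 0:
            raise ValueError("F must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array(astuple(self), dtype=float)


@dataclass(frozen=True)
class PriorSpec:
    """Uniform box prior: per-parameter (low, high) bounds and a pool size.

    ``n_draws`` sizes the initial importance pool; the default works out to
    roughly two thousand draws per free dimension of the nine-parameter
    box, below which the optimizer starts and mixture neighbourhoods get
    too sparse to tile the posterior ridge reliably.
    """

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PRIOR_BOUNDS))
    n_draws: int = 20_000

    def __post_init__(self) -> None:
        missing = set(AHP_PARAM_NAMES) - set(self.bounds)
        if missing:
            raise ValueError(f"missing prior bounds for {sorted(missing)}")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior for {name}: lower must be < upper")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[k][0] for k in AHP_PARAM_NAMES])
        hi = np.array([self.bounds[k][1] for k in AHP_PARAM_NAMES])
        return lo, hi


@dataclass(frozen=True)
class DeathsAtAge:
    """Deaths M(x) and number at risk S(x) per age class (likelihood data)."""

    ages: np.ndarray
    deaths: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.deaths < 0) or np.any(self.deaths > self.at_risk):
            raise ValueError("need 0 <= deaths <= at_risk at every age")
        if np.any(np.diff(self.at_risk) > 0):
            raise ValueError("at_risk must be non-increasing")


@dataclass(frozen=True)
class PosteriorSample:
    """Final IMIS resample: K rows of the nine aHP parameters."""

    params: np.ndarray              # K x 9 resampled rows
    weights: np.ndarray             # importance weights of the pool
    unique_fraction: float          # expected unique fraction at stopping
    n_imis_used: int
    seed: int | None
    pool: np.ndarray | None = None  # pre-resample pool, aligned with weights
    param_names: tuple[str, ...] = AHP_PARAM_NAMES
    unique_fraction_trace: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.params.ndim != 2 or self.params.shape[1] != 9:
            raise ValueError("params must be K x 9")
        if self.params.shape[0] < 1:
            raise ValueError("empty posterior")

    def __len__(self) -> int:
        return self.params.shape[0]

    def posterior_mean(self) -> np.ndarray:
        """Importance-weighted posterior mean of the nine parameters.

        Uses the full weighted pool when available (lower Monte-Carlo error
        than averaging the resample), else the resample average.
        """
        if self.pool is not None:
            return self.weights @ self.pool
        return self.params.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.params, columns=list(self.param_names))


def _check_positive_ages(ages) -> np.ndarray:
    x = np.asarray(ages, dtype=float)
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("ages must be finite and >= 0")
    return x


def _raw_components(theta: np.ndarray, ages: np.ndarray):
    """Vectorised aHP terms for a (n, 9) parameter block over an age grid.

    The hump needs x > 0; age class 0 is evaluated at its midpoint 0.5 (the
    only class whose label makes ln(x/F) blow up), all other classes at
    their integer label so the hump still peaks exactly at x = F.
    """
    A, B, C, D, E, F, G, H, I = (theta[:, i:i + 1] for i in range(9))
    x = ages[None, :]
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        infant = A ** ((x + B) ** C)
        xh = np.where(x > 0, x, 0.5)
        hump = I + D * np.exp(-E * np.log(xh / F) ** 2)
        gh = G * H ** x
        adult = gh / (1.0 + gh)
    return infant, hump, adult


def ahp_qx(p: AHPParams, ages, strict: bool = True) -> MortalitySchedule:
    """Evaluate the nine-parameter curve, split into its three terms.

    Components are reported unclamped; the total is their sum clamped to
    [0, 1].  With ``strict`` (the default) an unclamped total above 1
    anywhere raises -- during fitting such parameter vectors are instead
    silently assigned zero likelihood.
    """
    x = _check_positive_ages(ages)
    infant, hump, adult = _raw_components(p.as_array()[None, :], x)
    total_raw = (infant + hump + adult)[0]
    if strict and np.any(total_raw > 1.0):
        raise ValueError("q(x) exceeds 1 in the requested age range")
    comps = {"infant": infant[0], "hump": hump[0], "adult": adult[0]}
    return MortalitySchedule(ages=x, components=comps,
                             total=np.clip(total_raw, 0.0, 1.0), kind="qx")


def hp_qx(p: AHPParams, ages, strict: bool = True) -> MortalitySchedule:
    """The unadapted eight-parameter Heligman-Pollard curve (I forced to 0)."""
    base = AHPParams(**{**{k: getattr(p, k) for k in HP_PARAM_NAMES}, "I": 0.0})
    return ahp_qx(base, ages, strict=strict)


def decompose(p_or_post, ages) -> dict[str, np.ndarray]:
    """Natural, anthropogenic and total mortality-at-age.

    natural = infant + adult terms; anthropogenic = the hump term.  For a
    :class:`PosteriorSample` the pointwise posterior median of each
    component is returned.
    """
    x = _check_positive_ages(ages)
    if isinstance(p_or_post, PosteriorSample):
        infant, hump, adult = _raw_components(p_or_post.params, x)
        natural = np.median(infant + adult, axis=0)
        anthropogenic = np.median(hump, axis=0)
        return {"natural": natural, "anthropogenic": anthropogenic,
                "total": natural + anthropogenic}
    sched = ahp_qx(p_or_post, x)
    natural = sched.components["infant"] + sched.components["adult"]
    anthropogenic = sched.components["hump"]
    return {"natural": natural, "anthropogenic": anthropogenic,
            "total": natural + anthropogenic}


def hump_peak_age(p_or_post, ages) -> float:
    """Age at which the anthropogenic (hump) component is largest."""
    x = _check_positive_ages(ages)
    hump = decompose(p_or_post, x)["anthropogenic"]
    return float(x[int(np.argmax(hump))])


def draw_priors(spec: PriorSpec, seed: int | None = None,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Independent uniform draws within the prior box (n_draws x 9)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = spec.arrays()
    return rng.uniform(lo, hi, size=(spec.n_draws, 9))


def deaths_at_age(sample: AgeSample) -> DeathsAtAge:
    """Binomial likelihood data from the observed cohort.

    At-risk counts are the reverse-cumulative death counts: everyone who
    died at age x or older was alive entering class x.
    """
    counts = sample.binned_counts().astype(float)
    at_risk = np.cumsum(counts[::-1])[::-1]
    return DeathsAtAge(ages=np.arange(counts.size, dtype=float),
                       deaths=counts, at_risk=at_risk)


def _loglik_block(theta: np.ndarray, data: DeathsAtAge) -> np.ndarray:
    """Binomial log-likelihood for each row of an (n, 9) parameter block.

    Rows whose curve leaves (0, 1) anywhere, or whose parameters violate the
    model's own constraints, get -inf (zero posterior mass) rather than an
    exception: IMIS must be free to propose them.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    infant, hump, adult = _raw_components(theta, data.ages)
    q = infant + hump + adult
    ok = np.all(np.isfinite(q) & (q > 0.0) & (q < 1.0), axis=1)
    ok &= (theta[:, 0] < 1) & (theta[:, 5] > 0) & np.all(theta >= 0, axis=1)
    q_safe = np.where((q > 0) & (q < 1), q, 0.5)
    M, S = data.deaths[None, :], data.at_risk[None, :]
    ll = np.sum(M * np.log(q_safe) + (S - M) * np.log1p(-q_safe), axis=1)
    return np.where(ok, ll, -np.inf)


def ahp_loglik(p: AHPParams, data: DeathsAtAge) -> float:
    """Binomial log-likelihood (constants dropped); -inf for invalid curves."""
    return float(_loglik_block(p.as_array()[None, :], data)[0])


def expected_unique_fraction(weights: np.ndarray, k: int) -> float:
    """Expected fraction of unique pool rows in a size-k weighted resample."""
    w = weights[weights > 0]
    return float(np.sum(1.0 - (1.0 - w) ** k) / k)


def _neighbourhood_cov(pool: np.ndarray, centre: np.ndarray, w: np.ndarray,
                       b: int, span: np.ndarray) -> np.ndarray:
    """Covariance for an incremental mixture component.

    The B pool points nearest the centre (Mahalanobis distance under the
    prior covariance, diag(span^2/12) for a uniform box) are collected and
    their weighted scatter about the centre -- weights the average of the
    importance weight and a uniform 1/N, so zero-weight neighbours still
    contribute spread -- is inflated x1.2 and jittered to stay SPD."""
    d2 = np.sum(((pool - centre) / span) ** 2, axis=1)
    idx = np.argsort(d2, kind="stable")[:max(b, pool.shape[1] + 2)]
    wn = (w[idx] + 1.0 / w.size) / 2.0
    wn = wn / wn.sum()
    dev = pool[idx] - centre
    cov = 1.2 * (dev * wn[:, None]).T @ dev
    return cov + 1e-10 * np.diag(span ** 2) + 1e-12 * np.eye(pool.shape[1])


#: Optimizer-stage clouds are multivariate-t with this many degrees of
#: freedom, scaled by the inverse Hessian at the mode.  A Gaussian envelope
#: at the mode is overconfident for the skewed, banana-shaped marginals
#: typical of this model (G and H trade off along a curved ridge) and
#: biases importance estimates of the tails; the t keeps the Gaussian core
#: (so efficiency survives nine dimensions) while its tails stay heavy.
MODE_CLOUD_DF = 5.0


def _hessian_cov(post: "_Posterior", theta: np.ndarray) -> np.ndarray:
    """Scale matrix for an optimizer-stage cloud: inverse of the negative
    finite-difference Hessian of the log posterior at the mode, with small
    or negative curvature directions clipped (flat ridges would otherwise
    give unbounded variance) and the spread capped at the prior box scale."""
    span = post.hi - post.lo
    h = 1e-4 * span
    centre = np.clip(theta, post.lo + 2 * h, post.hi - 2 * h)
    d = centre.size

    def f(x):
        val = post.loglik(x)[0]
        return val if np.isfinite(val) else -1e12

    f0 = f(centre)
    H = np.empty((d, d))
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        H[i, i] = (f(centre + ei) - 2 * f0 + f(centre - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(centre + ei + ej) - f(centre + ei - ej)
                - f(centre - ei + ej) + f(centre - ei - ej)
            ) / (4 * h[i] * h[j])
    neg = -(H + H.T) / 2.0
    vals, vecs = np.linalg.eigh(neg)
    floor = max(np.max(vals), 1e-12) * 1e-8
    vals = np.maximum(vals, floor)
    cov = (vecs / vals) @ vecs.T
    # cap any direction at the prior box scale
    sd_cap = span / 2.0
    d_sd = np.sqrt(np.diag(cov))
    shrink = np.minimum(1.0, sd_cap / np.maximum(d_sd, 1e-300))
    cov = cov * np.outer(shrink, shrink)
    return cov + 1e-12 * np.diag(span ** 2)


class _Posterior:
    """Log prior + log likelihood over the free coordinates, with fixed
    parameters spliced back in."""

    def __init__(self, data: DeathsAtAge, lo: np.ndarray, hi: np.ndarray,
                 free: np.ndarray, fixed_full: np.ndarray):
        self.data = data
        self.lo, self.hi = lo[free], hi[free]
        self.free = free
        self.fixed_full = fixed_full
        self.log_prior_const = -float(np.sum(np.log(self.hi - self.lo)))

    @property
    def dim(self) -> int:
        return self.free.size

    def full(self, theta_free: np.ndarray) -> np.ndarray:
        theta_free = np.atleast_2d(theta_free)
        full = np.tile(self.fixed_full, (theta_free.shape[0], 1))
        full[:, self.free] = theta_free
        return full

    def loglik(self, theta_free: np.ndarray) -> np.ndarray:
        return _loglik_block(self.full(theta_free), self.data)

    def log_prior(self, theta_free: np.ndarray) -> np.ndarray:
        theta_free = np.atleast_2d(theta_free)
        inside = np.all((theta_free >= self.lo) & (theta_free <= self.hi),
                        axis=1)
        return np.where(inside, self.log_prior_const, -np.inf)


def _optimise_from(post: _Posterior, start: np.ndarray) -> tuple[np.ndarray, float]:
    """Nelder-Mead on logit-transformed coordinates inside the prior box."""
    lo, hi = post.lo, post.hi
    span = hi - lo

    def to_z(theta):
        u = np.clip((theta - lo) / span, 1e-9, 1 - 1e-9)
        return np.log(u / (1 - u))

    def to_theta(z):
        from scipy.special import expit
        return lo + span * expit(z)

    def negpost(z):
        ll = post.loglik(to_theta(z))[0]
        return -ll if np.isfinite(ll) else 1e12

    res = minimize(negpost, to_z(start), method="Nelder-Mead",
                   options={"maxfev": 1000, "xatol": 1e-8, "fatol": 1e-8})
    theta = to_theta(res.x)
    return theta, float(post.loglik(theta)[0])


def _refined_mode_cov(post: "_Posterior", centre: np.ndarray,
                      cov: np.ndarray, rng: np.random.Generator,
                      n_pilot: int, n_refine: int = 3) -> np.ndarray:
    """Refine a mode component's scale by pilot reweighting.

    The curvature at a mode understates the spread of skewed or curved
    posterior ridges, so the Hessian-based scale is adapted: draw a pilot
    cloud from the current t proposal, weight it by posterior / proposal,
    and widen the scale by the weighted scatter about the mode (x1.2).
    The update is expansion-only -- the base curvature scale is kept as a
    floor, because with many free parameters the pilot weights degenerate
    and a raw weighted scatter would collapse.  Three rounds suffice in
    practice; the pilot draws are discarded and never enter the
    importance-sampling pool.
    """
    span = post.hi - post.lo
    jitter = 1e-12 * np.diag(span ** 2)
    base = cov.copy()
    for _ in range(n_refine):
        draws = np.atleast_2d(multivariate_t.rvs(
            loc=centre, shape=cov, df=MODE_CLOUD_DF, size=n_pilot,
            random_state=rng))
        if post.dim == 1:
            draws = draws.reshape(n_pilot, 1)
        logw = post.loglik(draws) + post.log_prior(draws) \
            - multivariate_t.logpdf(draws, loc=centre, shape=cov,
                                    df=MODE_CLOUD_DF)
        if not np.any(np.isfinite(logw)):
            break
        w = np.exp(logw - np.max(logw[np.isfinite(logw)]))
        w[~np.isfinite(w)] = 0.0
        w = w / w.sum()
        dev = draws - centre
        scatter = 1.2 * (dev * w[:, None]).T @ dev
        cov = base + scatter + jitter
    return cov


def fit_ahp(sample: AgeSample, spec: PriorSpec | None = None,
            n_imis: int = 10, n_opt: int = 10, n_resample: int = 500,
            seed: int | None = None,
            fixed: dict[str, float] | None = None) -> PosteriorSample:
    """Fit the aHP model by Bayesian melding with IMIS.

    Stages: (i) a pool of uniform prior draws is scored by the binomial
    likelihood; (ii) local optimisation from the ``n_opt`` highest-weight
    points seeds Gaussian clouds around every optimum that beats the prior
    pool's best likelihood; (iii) up to ``n_imis`` incremental rounds each
    add a multivariate-normal component at the current highest-weight point
    and reweight the whole pool by prior x likelihood / mixture envelope,
    stopping once the expected unique fraction of the final resample
    reaches 1 - 1/e; (iv) ``n_resample`` rows are drawn with replacement in
    proportion to weight.  Bit-reproducible for a given ``seed``.

    ``fixed`` pins named parameters (e.g. ``{"D": 0, "I": 0}``) and runs the
    sampler over the remaining free coordinates only.
    """
    if spec is None:
        spec = PriorSpec()
    if len(sample) == 0:
        raise ValueError("no ages")
    data = deaths_at_age(sample)
    lo_all, hi_all = spec.arrays()
    fixed = dict(fixed or {})
    for name in fixed:
        if name not in AHP_PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}")
    free = np.array([i for i, k in enumerate(AHP_PARAM_NAMES)
                     if k not in fixed], dtype=int)
    if free.size == 0:
        raise ValueError("at least one parameter must be free")
    fixed_full = np.zeros(9)
    for i, k in enumerate(AHP_PARAM_NAMES):
        if k in fixed:
            fixed_full[i] = fixed[k]
    post = _Posterior(data, lo_all, hi_all, free, fixed_full)
    span = post.hi - post.lo

    from ._util import substream
    rng_prior = substream(seed, "priors")
    rng_clouds = substream(seed, "clouds")
    rng_resample = substream(seed, "resample")

    # -- stage (i): prior pool ------------------------------------------------
    n0 = spec.n_draws
    pool = rng_prior.uniform(post.lo, post.hi, size=(n0, post.dim))
    ll = post.loglik(pool)
    if not np.any(np.isfinite(ll)):
        raise ValueError("priors incompatible with data")
    max_prior_ll = float(np.max(ll))
    b = max(n0 // n_opt, post.dim + 2)  # cloud size per mixture component

    comps: list[tuple[np.ndarray, np.ndarray, float | None]] = []
    comp_logpdf: list[np.ndarray] = []  # per-component logpdf of the pool

    def _comp_logpdf(x, mean, cov, df):
        if df is None:
            out = multivariate_normal.logpdf(x, mean=mean, cov=cov,
                                             allow_singular=True)
        else:
            out = multivariate_t.logpdf(x, loc=mean, shape=cov, df=df)
        return np.atleast_1d(out)

    def add_component(centre: np.ndarray, cov: np.ndarray,
                      df: float | None = None) -> None:
        nonlocal pool, ll
        if df is None:
            draws = rng_clouds.multivariate_normal(centre, cov, size=b,
                                                   method="svd")
        else:
            draws = multivariate_t.rvs(loc=centre, shape=cov, df=df, size=b,
                                       random_state=rng_clouds)
            draws = np.atleast_2d(draws)
            if post.dim == 1:
                draws = draws.reshape(b, 1)
        pool = np.vstack([pool, draws])
        ll = np.concatenate([ll, post.loglik(draws)])
        comps.append((centre, cov, df))
        for k, (m, c, d_) in enumerate(comps[:-1]):
            comp_logpdf[k] = np.concatenate([comp_logpdf[k],
                                             _comp_logpdf(draws, m, c, d_)])
        comp_logpdf.append(_comp_logpdf(pool, centre, cov, df))

    def weights() -> np.ndarray:
        log_prior = post.log_prior(pool)
        if comps:
            # envelope: (n0 * prior + b * sum_k phi_k) / (n0 + b*K)
            stack = np.vstack([log_prior + np.log(n0)] +
                              [lp + np.log(b) for lp in comp_logpdf])
            log_env = np.logaddexp.reduce(stack, axis=0) \
                - np.log(n0 + b * len(comps))
        else:
            log_env = log_prior
        logw = ll + log_prior - log_env
        logw[~np.isfinite(logw)] = -np.inf
        if np.all(np.isinf(logw)):
            raise ValueError("priors incompatible with data")
        w = np.exp(logw - np.max(logw[np.isfinite(logw)]))
        return w / w.sum()

    # -- stage (ii): optimiser step -------------------------------------------
    order = np.lexsort((np.arange(n0), -ll))  # by loglik desc, index asc
    for start_idx in order[:n_opt]:
        centre, opt_ll = _optimise_from(post, pool[start_idx])
        if opt_ll > max_prior_ll:
            cov = _refined_mode_cov(post, centre, _hessian_cov(post, centre),
                                    rng_clouds, n_pilot=b)
            add_component(centre, cov, df=MODE_CLOUD_DF)

    # -- stage (iii): incremental mixture rounds ------------------------------
    trace: list[float] = []
    n_used = 0
    w = weights()
    for _ in range(n_imis):
        frac = expected_unique_fraction(w, n_resample)
        trace.append(frac)
        if frac >= IMIS_STOP_FRACTION:
            break
        n_used += 1
        top = np.lexsort((np.arange(w.size), -w))[0]
        add_component(pool[top],
                      _neighbourhood_cov(pool, pool[top], w, b, span),
                      df=MODE_CLOUD_DF)
        w = weights()
    else:
        trace.append(expected_unique_fraction(w, n_resample))

    # -- stage (iv): final resample -------------------------------------------
    idx = rng_resample.choice(w.size, size=n_resample, replace=True, p=w)
    params = post.full(pool[idx])
    return PosteriorSample(params=params, weights=w,
                           unique_fraction=trace[-1], n_imis_used=n_used,
                           seed=seed, pool=post.full(pool),
                           unique_fraction_trace=tuple(trace))


def predict_ahp(post: PosteriorSample, ages, level: float = 0.90
                ) -> pd.DataFrame:
    """Pointwise posterior median and credible band for each component.

    Returns a frame with, per component in {natural, anthropogenic, total},
    columns ``<comp>_lower``, ``<comp>_median``, ``<comp>_upper`` at the
    (1-level)/2, 0.5 and 1-(1-level)/2 quantiles across posterior rows.
    """
    if not 0 <= level < 1:
        raise ValueError("level must lie in [0, 1)")
    x = _check_positive_ages(ages)
    infant, hump, adult = _raw_components(post.params, x)
    natural = infant + adult
    total = np.clip(natural + hump, 0.0, 1.0)
    alpha = (1.0 - level) / 2.0
    out = {"age": x}
    for name, mat in (("natural", natural), ("anthropogenic", hump),
                      ("total", total)):
        qs = np.quantile(mat, [alpha, 0.5, 1.0 - alpha], axis=0)
        out[f"{name}_lower"], out[f"{name}_median"], out[f"{name}_upper"] = qs
    return pd.DataFrame(out)
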