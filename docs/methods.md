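# Methods

## Data model

The raw observation is a set of ages at death from stranded animals. Under
the stationarity assumption (the population's age structure is in
equilibrium over the collection period), these ages are treated as a single
synthetic cohort. Ages are binned to integer classes by truncation, since
growth-layer ages are read in whole years; fractional calf ages fall into
class 0.

From the binned counts N(x), the number at risk entering class x is the
reverse cumulative sum S(x) = Σ_{y≥x} N(y), giving the cohort life table:
l(x) = S(x)/S(0), q(x) = N(x)/S(x), d(x) = l(x) − l(x+1). The terminal
observed class is closed with q = 1 so that Σd = 1. Person-years use the
midpoint convention L(x) = (l(x)+l(x+1))/2 — deaths are assumed to occur at
mid-interval — which forces e at the last age to 0.5; the choice is the
standard cohort convention and only affects e. The radix scales the S
column for display and nothing else.

## Siler model

Total hazard μ(x) = a₁e^(−b₁x) + a₂ + a₃e^(b₃x) with all five parameters
non-negative; survivorship is the product of the three competing-risk
survivorships (closed form; the b₁ = 0 and b₃ = 0 removable singularities
are handled as constant-hazard limits). The discrete age-at-death pmf is
f(x) = l(x) − l(x+1) with the tail beyond the last class lumped into a
terminal mass, so it sums to one exactly.

**Fitting.** The default objective is the multinomial negative
log-likelihood of the binned age frequencies under f — ages at death are a
census of deaths, and the multinomial respects that. A least-squares fit of
log-hazard to the life-table hazards (`objective="log_hazard_ls"`) is
available as an alternative. Parameters are optimized on the log scale
(positivity for free) by Nelder–Mead from a fixed default start
(a₁=0.1, b₁=0.5, a₂=0.05, a₃=0.01, b₃=0.1) plus 10 seeded jittered
restarts; the best of all restarts is returned with its objective value.
`max_age` defaults to the oldest observed age + 1, opening one empty
terminal class for the tail mass.

**Young-age removal.** Calves are under-represented in strandings
(predation, fast decomposition, low detection). With `rm = k`, the first k
age classes are dropped from the likelihood and the pmf renormalised over
the retained classes; predictions then cover *all* ages from the fitted
curve. On thinned synthetic data this recovers first-year mortality that
the naive fit underestimates by a factor of about two.

## Adapted Heligman–Pollard model

q(x) = A^((x+B)^C) + [I + D·exp(−E·ln²(x/F))] + G·Hˣ/(1+G·Hˣ). The three
terms are the infant decline, the lognormal accident hump (here: bycatch)
whose baseline the ninth parameter I lifts off zero, and the logistic
adult rise. Natural mortality = infant + adult terms; anthropogenic =
hump term. Components are reported unclamped; the total is clamped to
[0, 1]. During fitting, any parameter vector whose total leaves (0, 1)
anywhere on the data's age grid receives −∞ log-likelihood rather than an
exception; direct curve evaluation raises instead (`strict=False` to
clamp).

**Age 0 and the hump.** ln(x/F) is undefined at x = 0, the very age the I
parameter exists for. The hump term is evaluated at the class midpoint 0.5
for age class 0 and at the integer label for every other class, so the
curve is finite at 0 while the hump still peaks exactly at x = F.

**Likelihood.** Binomial deaths-given-at-risk per age class:
Σ_x [M(x)·ln q(x) + (S(x)−M(x))·ln(1−q(x))], with M(x) the deaths and S(x)
the at-risk counts from the observed cohort's cumulative survival, and
binomial coefficients dropped. This is the natural likelihood for a q(x)
curve on life-table data and keeps the Siler and aHP layers on the same
data model.

**Priors.** Independent uniform boxes per parameter. The defaults are wide
(e.g. A ∈ (10⁻⁵, 0.5), F ∈ (0.5, 15), H ∈ (1, 1.5)) and should be narrowed
from biology in real analyses; all bounds are user-configurable. The prior
pool size defaults to 20 000 draws — about two thousand per free dimension
of the nine-parameter box; below that the optimizer starts and mixture
neighbourhoods proved too sparse to tile the posterior ridge reliably.

**Posterior sampling (Bayesian melding with IMIS).**

1. *Prior stage.* Score the uniform pool by log-likelihood; fail if no
   draw is feasible ("priors incompatible with data").
2. *Optimizer stage.* From the n_opt (default 10) highest-likelihood pool
   points, run Nelder–Mead on logit-transformed coordinates inside the
   box (≤ 1000 evaluations per start). Each optimum that beats the prior
   pool's best likelihood becomes a mixture component; the others are
   discarded.
3. *Component scale at a mode.* The inverse of the negative
   finite-difference Hessian of the log posterior, with non-positive
   curvature directions clipped (flat ridges would give unbounded
   variance) and spread capped at the box scale. Because curvature at a
   mode understates the spread of the skewed, banana-shaped marginals this
   model produces (G and H trade off along a curved ridge), the scale is
   then refined by pilot reweighting: draw a pilot cloud from the current
   proposal, weight it by posterior/proposal, and widen the scale by the
   weighted scatter about the mode (×1.2), keeping the curvature scale as
   a floor so degenerate pilot weights cannot collapse it. Three rounds;
   pilot draws are discarded.
4. *Proposal form.* All mixture components are multivariate-t with 5
   degrees of freedom. A Gaussian envelope proved overconfident in the
   tails, biasing importance estimates of skewed marginals by ~25% in a
   grid-verified reduced model; the t keeps the Gaussian core (so
   efficiency survives nine dimensions) with heavy tails.
5. *Incremental stage.* Up to n_imis (default 10) rounds: place a new
   component at the current highest-weight pool point with covariance from
   its B nearest neighbours (Mahalanobis distance under the prior
   covariance; neighbour weights averaged with uniform so zero-weight
   neighbours still contribute spread; ×1.2), sample B = pool/n_opt points
   from it, and recompute all importance weights
   w ∝ prior × likelihood / envelope, where the envelope is the
   draws-proportional mixture of the prior and all components.
6. *Stopping.* After each reweighting, compute the expected unique
   fraction of a K-row resample, Σ_i [1 − (1−w_i)^K]/K; stop when it
   reaches 1 − 1/e ≈ 0.632. The per-round trace is reported either way.
   Ties in "highest-weight point" break by pool index (stable sort), for
   determinism.
7. *Final resample.* n_resample (default 500) rows drawn with replacement
   by weight. The returned object carries the resample, the weighted pool,
   the diagnostic trace and the seed; `posterior_mean()` uses the weighted
   pool (lower Monte-Carlo error than averaging the resample).

All randomness flows from one user seed through named substreams (priors /
clouds / resample and the simulator's natural / bycatch / thinning), so
runs are bit-reproducible and adding a stage never perturbs another's
draws.

**Prediction.** `predict_ahp` returns pointwise quantiles — (1−level)/2,
0.5, 1−(1−level)/2 with level defaulting to 0.90 — of each component
across the resampled rows. `decompose` on a posterior returns pointwise
medians. Parameters can be pinned (`fixed={"D": 0, "I": 0}`) to fit
reduced models; with the hump pinned at zero the aHP reproduces a fitted
Siler curve over the data-supported ages, as it should (the two forms
extrapolate differently once almost nobody remains at risk).

**Calibration.** Against a long-run MCMC on the same posterior, the IMIS
bands match widths within a few percent on typical datasets. Pointwise
frequentist coverage of the 90% bands, averaged over replicate datasets of
3000 strandings from a known aHP truth, is about 0.82–0.85 for IMIS versus
about 0.84–0.87 for exact-posterior MCMC: slightly below nominal for both,
reflecting finite-sample nonlinearity and prior truncation rather than
sampler error, and strongly variable between individual datasets (0.5–1.0)
because misses come in runs of correlated ages.

## Leslie matrices

`build_leslie` uses a post-breeding birth-pulse census: survival
P_i = 1 − q_i on the subdiagonal and fertilities F_i = P_i · s · m_{i+1} on
the top row (s = birth sex ratio, default 0.5; m = calves per female per
year, e.g. a pregnancy rate), with F at the terminal age 0. Only female
offspring are counted — mature males are assumed never limiting. The
fertilities are not graduated across the interval; the simple post-breeding
form is used throughout.

`eigen_analysis` trims trailing post-reproductive classes (which make the
matrix reducible) before the eigendecomposition, then pads back: the
stable age distribution extends by w_{i+1} = P_i·w_i/λ and the trimmed
classes get zero reproductive value. It returns λ (Perron root; an error
is raised if no real non-negative dominant eigenvalue exists),
r = ln λ, the stable age distribution (sum 1), reproductive values
(v₀ = 1), sensitivity s_ij = v_i·w_j/⟨v,w⟩ and elasticity
e_ij = (a_ij/λ)·s_ij (elasticities sum to 1), net production
R₀ = Σ l(x)·F_x, and generation time T = ln R₀ / ln λ with the cohort
formula Σ x·l(x)·F_x / R₀ as the λ = 1 fallback (both are reported).
`project` iterates N_{t+1} = A·N_t for a default horizon of 100 years.

## Synthetic scenarios

A scenario draws natural deaths from a Siler age-at-death pmf by one
multinomial draw, adds bycaught animals with truncated-normal ages rounded
to integer classes (defaults: mean 3 yr, sd 1.5 yr — mode before
maturity), and optionally thins young classes by per-age retention
probabilities. Default sizes are 220 natural + 80 bycaught strandings with
ages to 30 — a realistic multi-decade record for a resident coastal
bottlenose dolphin population — and the default Siler parameters
(a₁=0.25, b₁=0.6, a₂=0.02, a₃=0.004, b₃=0.19) give ~24% first-year
mortality, a ~2%/yr adult background, senescence from the early twenties
and under 0.1% survival to 30. `simulate_from_qx` turns any death
probability schedule (e.g. a known aHP curve) into a generating truth.
Cause labels ride along in the output for diagnostics but are never shown
to the estimators.

What the generator does *not* emulate: drift and detection of carcasses
(spatial stranding probability), age-reading error, temporal trends in
abundance or effort, and any density dependence. Passing recovery tests
therefore shows the estimators work when the stationarity and
representativeness assumptions hold — not that a given real stranding
record satisfies them.

## Experiment sizes

The recovery experiments use 5000 strandings for the Siler fit (error
measured as max relative hazard error over ages 0–25, averaged over 5
replicate datasets), 3000 strandings per replicate for the aHP (hump
location and band coverage averaged over replicates; 10 in the test suite,
20 in the acceptance script), 300 strandings and a 60³-node grid for the
reduced-model quadrature cross-check (log-spaced nodes for G, whose
posterior lives near the lower bound), and 220 + 80 for the example
workflow. These sizes make every Monte-Carlo comparison stable at the
tolerances used while keeping a full run to tens of seconds.

## Known limitations

- Stationary age structure is assumed; growing or shrinking populations
  bias the synthetic cohort.
- Nine parameters on ~30 age classes invite overfitting and ridge-shaped
  posteriors; informative priors are the intended remedy, and uniform
  boxes are the only prior family implemented.
- The binomial likelihood treats age classes as independent given the
  curve; overdispersion (e.g. mass-stranding events) is not modelled.
- No goodness-of-fit testing or model selection is provided.
- Leslie projections use static vital rates — no density dependence,
  environmental stochasticity, or two-sex structure.
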