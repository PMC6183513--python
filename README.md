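# strandmort

Total, natural and anthropogenic (bycatch) mortality-at-age of cetaceans,
estimated from nothing but the ages of stranded animals.

Stranding records are, for most cetacean populations, the only window onto
age-specific mortality: each carcass whose age is read (e.g. from tooth
growth layers) is one observation of an age at death. Assuming a stationary
age structure, the sample of ages at death is a synthetic cohort from which
a life table — survivorship *l(x)*, death probability *q(x)*, life
expectancy *e(x)* — follows directly. `strandmort` provides that life-table
machinery plus three model layers on top of it:

- **Siler competing-risk model** — total mortality as the sum of three
  hazards, μ(x) = a₁e^(−b₁x) + a₂ + a₃e^(b₃x): a declining juvenile risk, a
  constant background risk, and a rising senescent risk. Fitted to the age
  frequencies by maximum (multinomial) likelihood, with an option to drop
  the chronically under-represented calf classes from the likelihood and
  predict them from the fitted curve instead.
- **Adapted Heligman–Pollard (aHP) model** — the death probability

  q(x) = A^((x+B)^C) + [ I + D·exp(−E·ln²(x/F)) ] + G·Hˣ / (1 + G·Hˣ)

  an infant-mortality decline, a lognormal "accident hump" centred at age
  *F* whose baseline is lifted by the ninth parameter *I* (so bycatch of
  age-0 animals is not forced to zero), and a logistic adult rise. The
  natural component is the infant + adult terms; the anthropogenic
  component is the bracketed hump. Fitting is Bayesian melding: uniform
  box priors, a binomial deaths-given-at-risk likelihood, and Incremental
  Mixture Importance Sampling (IMIS) with an optimizer stage, which yields
  a weighted posterior sample and hence 90% credible bands per component.
- **Leslie matrices** — any estimated *q(x)* schedule plus a maternity
  schedule becomes a projection matrix; eigen-analysis gives the annual
  growth rate λ, stable age distribution, reproductive values,
  sensitivities/elasticities, net production R₀ and generation time, so the
  demographic cost of bycatch can be compared against a natural-mortality
  baseline.

A synthetic-data module generates stranding records with known ground truth
(Siler natural deaths + a truncated-normal bycatch pulse + optional
calf-class thinning), so every estimator is testable end to end.

## Worked example

Fit the aHP to 3000 synthetic strandings (2200 natural + 800 bycaught at
mean age 3 yr — the cause labels are hidden from the model):

```python
import numpy as np
import strandmort as sm

spec = sm.ScenarioSpec(n_natural=2200, n_bycatch=800,
                       bycatch_mean_age=3.0, bycatch_sd=1.5, seed=3)
post = sm.fit_ahp(sm.simulate_scenario(spec), seed=3)
print(sm.hump_peak_age(post, np.arange(0, 15.01, 0.25)))
print(sm.predict_ahp(post, np.arange(0, 31, 5)).round(3))
```

This prints a hump peak at age **3.00** (the injected bycatch mean) and the
per-age component medians with 90% bands, e.g. at age 5 a natural median of
0.043 and an anthropogenic median of 0.047 — at the hump's shoulder roughly
half the deaths are bycatch. Feeding the two schedules into Leslie matrices
on a shared maternity schedule (`examples/04_leslie_scenarios.py`) prints

```
natural only      : lambda = 0.9770  (r = -0.0233), R0 = 0.72, T = 14.1 yr
natural + bycatch : lambda = 0.9473  (r = -0.0541), R0 = 0.46, T = 14.3 yr
```

i.e. the population would decline slowly even without bycatch, and bycatch
roughly doubles the annual rate of decline — the quantity a manager needs
to set removal limits.

The `examples/` directory holds one short script per capability (life
table, Siler fit with calf-class removal, aHP decomposition, Leslie
scenarios); each prints what it computes and what the numbers mean. The
same workflow is scriptable from the shell via the `strandmort` CLI
(`simulate`, `lifetable`, `siler`, `hp`, `leslie`, `run`); every output
carries a `.meta.json` sidecar with the seed and parameters that produced
it.

## Documentation

`docs/methods.md` describes the models, the fitting pipeline, every
numerical choice (likelihood form, hump evaluation at age 0, mixture
covariances, stopping rule), what the synthetic generator does and does not
emulate, and known limitations.
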