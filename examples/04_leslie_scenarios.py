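"""Project population consequences of bycatch with Leslie matrices.

Takes the natural and total (natural + bycatch) mortality schedules
estimated in the decomposition example, builds a Leslie matrix for each on
a shared maternity schedule (maturity at 8 yr, one calf per four years,
even birth sex ratio), and compares the eigen-derived demography: annual
growth lambda, net production R0, and generation time.
"""
import numpy as np

import strandmort as sm

spec = sm.ScenarioSpec(n_natural=2200, n_bycatch=800, seed=3)
posterior = sm.fit_ahp(sm.simulate_scenario(spec), seed=3)

ages = np.arange(spec.max_age + 1)
parts = sm.decompose(posterior, ages)
maternity = np.where(ages >= 8, 0.25, 0.0)

for label, q in (("natural only", parts["natural"]),
                 ("natural + bycatch", parts["total"])):
    A = sm.build_leslie(np.clip(q, 0, 1), maternity, sex_ratio=0.5)
    stats = sm.eigen_analysis(A)
    traj = sm.project(A, 1000 * stats.stable_age)  # default 100-yr horizon
    print(f"{label:18s}: lambda = {stats.lambda_:.4f}  (r = {stats.r:+.4f}), "
          f"R0 = {stats.R0:.2f}, T = {stats.generation_time:.1f} yr, "
          f"population after 100 yr: {traj[-1].sum():.0f}")

print("\nlambda < 1 means annual decline; the gap between the two rows is "
      "the demographic cost of bycatch, the basis for setting removal "
      "limits.")
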