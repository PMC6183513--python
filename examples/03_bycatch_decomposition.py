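"""Split total mortality into natural and bycatch components with the aHP.

A synthetic stranding record mixes natural deaths (Siler schedule) with
bycaught animals whose ages centre on 3 yr -- just before maturity, the
classic fishery-interaction signature.  The adapted nine-parameter
Heligman-Pollard model, fitted by Bayesian melding with incremental
mixture importance sampling, recovers the hump location and yields 90%
credible bands for each component, using no cause-of-death information.
"""
import numpy as np

import strandmort as sm

spec = sm.ScenarioSpec(n_natural=2200, n_bycatch=800, bycatch_mean_age=3.0,
                       bycatch_sd=1.5, seed=3)
sample = sm.simulate_scenario(spec)
print(f"fitting {len(sample)} strandings "
      f"({spec.n_bycatch} bycaught, labels hidden from the model)...")

posterior = sm.fit_ahp(sample, seed=3)
print(f"IMIS: {posterior.n_imis_used} incremental rounds, expected unique "
      f"fraction {posterior.unique_fraction:.2f} "
      f"(stops at {sm.IMIS_STOP_FRACTION:.3f})")

peak = sm.hump_peak_age(posterior, np.arange(0, 15.01, 0.25))
print(f"bycatch hump peaks at age {peak:.2f} yr (true mean age 3.0)\n")

ages = np.arange(0, 31, 5)
bands = sm.predict_ahp(posterior, ages)
cols = ["age", "natural_median", "anthropogenic_median", "total_median",
        "total_lower", "total_upper"]
print(bands[cols].round(3).to_string(index=False))
print("\nmedians and 90% bands per age: anthropogenic is the hump "
      "component, natural the infant + senescent terms.")
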