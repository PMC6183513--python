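import numpy as np
import pytest
from hypothesis import settings

import strandmort as sm

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

#: Ground-truth adapted Heligman-Pollard parameters used by the recovery
#: experiments: realistic first-year mortality, a bycatch hump centred at
#: age 3 with a lifted baseline, and a Gompertz-like senescent rise.
AHP_TRUTH = sm.AHPParams(A=0.12, B=0.6, C=1.1, D=0.06, E=1.2, F=3.0,
                         G=0.0008, H=1.26, I=0.015)

SILER_TRUTH = sm.SilerParams(a1=0.3, b1=0.6, a2=0.02, a3=0.005, b3=0.25)


@pytest.fixture(scope="session")
def ahp_truth():
    return AHP_TRUTH


@pytest.fixture(scope="session")
def siler_truth():
    return SILER_TRUTH


@pytest.fixture(scope="session")
def small_sample():
    """A couple of hundred strandings from the default scenario."""
    return sm.simulate_scenario(sm.ScenarioSpec(seed=0))


@pytest.fixture(scope="session")
def siler_sample_5000(siler_truth):
    spec = sm.ScenarioSpec(siler=siler_truth, n_natural=5000, n_bycatch=0,
                           max_age=30, seed=0)
    return sm.simulate_natural(spec)
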