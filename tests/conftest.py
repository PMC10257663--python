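import numpy as np
import pytest

import lctcycle as lc

# Control condition: both phases average 22.3 H (8 G1 subphases at
# 8/22.3 per hour, 20 S-G2 subphases at 20/22.3 per hour; equal rates
# across parts make each phase duration Erlang-distributed).
CONTROL_ALPHA = 8 / 22.3
CONTROL_BETA = 20 / 22.3


@pytest.fixture(scope="session")
def control_rates() -> lc.RateSet:
    return lc.RateSet(alpha=CONTROL_ALPHA, beta=CONTROL_BETA)


@pytest.fixture(scope="session")
def times() -> np.ndarray:
    return lc.default_times()


@pytest.fixture(scope="session")
def g1_blocker(control_rates) -> lc.DrugResponseProfile:
    """Cytostatic G1-targeting drug (lapatinib/palbociclib-like)."""
    return lc.DrugResponseProfile(
        "g1_blocker", control_rates, ec50=50.0, steepness=2.0,
        e_max={"alpha": 0.05})


@pytest.fixture(scope="session")
def s_phase_drug(control_rates) -> lc.DrugResponseProfile:
    """Cytotoxic S-phase drug (gemcitabine-like): slows S-G2, kills there."""
    return lc.DrugResponseProfile(
        "s_drug", control_rates, ec50=10.0, steepness=2.0,
        e_max={"beta": 0.25, "gamma2": 0.04})
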