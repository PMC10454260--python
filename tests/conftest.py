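import numpy as np
import pytest

from cncrasch.model import RSMParams
from cncrasch.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def symmetric_params_8():
    """Eight items centered at zero with symmetric thresholds."""
    d = np.linspace(-1.0, 1.0, 8)
    return RSMParams(deltas=d - d.mean(), taus=np.array([-1.0, 1.0]))


@pytest.fixture(scope="session")
def flat_params_8():
    """Eight identical items, all parameters zero."""
    return RSMParams(deltas=np.zeros(8), taus=np.zeros(2))


@pytest.fixture(scope="session")
def study_cohort():
    """A study-sized synthetic cohort (n=40, 8 items, two timepoints)."""
    return generate_cohort(SimulationConfig(seed=20230611))


@pytest.fixture(scope="session")
def large_cohort():
    """A calibration-sized cohort for recovery experiments."""
    return generate_cohort(SimulationConfig(n_persons=500, seed=7))
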