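import pytest

from htnpathways.cohort import build_cohort
from htnpathways.synthetic import SimulationConfig, simulate


@pytest.fixture(scope="session")
def sim300():
    """A 300-person synthetic bundle with planted exclusions and change events."""
    return simulate(SimulationConfig(n_persons=300, rng_seed=1))


@pytest.fixture(scope="session")
def cohort300(sim300):
    bundle, _ = sim300
    return build_cohort(bundle)
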