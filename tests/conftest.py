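import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from freepol import synthetic_data as synth

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def default_truth() -> synth.SimulationTruth:
    """Study-condition generator truth (logistic OD, 2% noise)."""
    return synth.SimulationTruth(seed=0)


@pytest.fixture
def clean_truth() -> synth.SimulationTruth:
    """Noiseless truth in the pure-exponential regime (identifiability checks)."""
    return synth.noiseless(synth.SimulationTruth(carrying_capacity=np.inf, seed=0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
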