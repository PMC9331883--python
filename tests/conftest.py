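import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dartslip import ProteinRecord, SimulationConfig, make_protein

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def phospho_like_protein() -> ProteinRecord:
    """A seeded 900-residue protein carrying the phosphorylase-style annotations."""
    return make_protein(SimulationConfig(seed=0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
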