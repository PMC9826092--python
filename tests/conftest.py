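import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

from riskdex.grids import GridSpec  # noqa: E402
from riskdex.synthetic_world import WorldConfig, make_world  # noqa: E402


@pytest.fixture(scope="session")
def small_config() -> WorldConfig:
    """Small landscape, every archetype present, fast to model."""
    return WorldConfig(seed=11, n_species=8, extent=(-104.0, -100.0, 18.0, 22.0),
                       resolution=0.05,
                       archetype_mix={"doomed": 0.125, "stable": 0.375,
                                      "shrinking": 0.25, "expanding": 0.25})


@pytest.fixture(scope="session")
def small_world(small_config):
    return make_world(small_config)


@pytest.fixture(scope="session")
def grid() -> GridSpec:
    return GridSpec.from_extent(-104.0, -100.0, 18.0, 22.0, 0.05)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
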