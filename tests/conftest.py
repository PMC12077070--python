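import numpy as np
import pytest

from enercomm.allometry import AllometryConfig, default_community
from enercomm.landscape import SeasonParams, generate_landscape


@pytest.fixture(scope="session")
def community():
    return default_community()


@pytest.fixture(scope="session")
def small_traits(community):
    return community[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_landscape():
    """Small, mostly-habitat world with a flat season (no sinusoid)."""
    return generate_landscape(20, 0.8, "low", seed=7,
                              season=SeasonParams(mean_cap=20.0,
                                                  amplitude_frac=0.0))


@pytest.fixture(scope="session")
def frictionless_config():
    """Allometry with zero travel cost: foraging oracles become closed-form."""
    return AllometryConfig(incremental_coeff=0.0, postural_coeff=0.0)
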