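import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pirnakit.simulate import SimConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale study conditions used by the unit-level recovery tests."""
    return SimConfig(
        seed=7,
        n_target=20,
        n_spermatogenic_nontarget=20,
        n_oogenic=10,
        n_other=60,
        transcript_length=(600, 900),
        n_violating_sites=10,
        library_depth=200_000,
        n_replicates=2,
        n_spots_per_channel=100,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20_26)
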