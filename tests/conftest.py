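import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A small but structured population shared by several test modules."""
    from stayblup.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(n_founders=150, n_generations=4, n_snps=600, n_farms=3, seed=42)
    return cfg, simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
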