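import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from tmesim import (
    SimParams, RecruitParams, generate_training_set, train_surrogate,
)


@pytest.fixture(scope="session")
def surrogate_small():
    """Surrogate trained on a reduced Monte-Carlo set; fast, still accurate."""
    ds = generate_training_set(20_000, rng_seed=0)
    return train_surrogate(ds, rng_seed=0)


@pytest.fixture
def tiny_params():
    """Minimal lattice for fast engine-level tests."""
    return SimParams(
        width=12, height=12, max_days=2.0, tumor_cap=100,
        initial_cancer=4, resident_macrophage_density=0.02,
        recruit=RecruitParams(macrophage_per_day=2.0, r1_per_day=2.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
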