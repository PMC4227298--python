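import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

SEED = 20140703  # fixed master seed for every Monte-Carlo test


@pytest.fixture(scope="session")
def seed() -> int:
    return SEED


@pytest.fixture(scope="session")
def small_pilot_sd(seed):
    """Pooled-SD draws for a 10-per-group pilot, shared across tests."""
    from pilotsize import pooled_sd, simulate_normal_pilot

    reps = simulate_normal_pilot(10, 50_000, seed=seed)
    return np.asarray(pooled_sd(reps.s1_sq, reps.s2_sq))
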