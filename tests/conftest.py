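import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reference_pattern():
    from brushcell.pipeline import reference_burst_pattern

    return reference_burst_pattern()


@pytest.fixture(scope="session")
def continuum_cohort():
    """Small simulated cohort reused across tests (8 trials, fixed seed)."""
    from brushcell.pipeline import simulate_continuum_cohort

    recordings, c_values = simulate_continuum_cohort(
        n_cells=31, n_trials=8, seed=1
    )
    return recordings, c_values
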