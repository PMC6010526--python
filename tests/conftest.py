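import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pepmaps as pm

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scale():
    return pm.load_scale()


@pytest.fixture(scope="session")
def table1():
    return pm.read_activity_table()


@pytest.fixture(scope="session")
def table1_model(table1, scale):
    """Reference-panel PLSR with leave-one-out component selection."""
    return pm.fit_plsr(table1, scale, n_latent="auto")


@pytest.fixture(scope="session")
def design_15():
    return pm.generate_design()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
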