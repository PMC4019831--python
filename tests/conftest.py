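import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rhizotax.io import DEFAULT_ENZYMES

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def enzymes():
    """The default seven-enzyme ARDRA panel, keyed by name."""
    return {e.name: e for e in DEFAULT_ENZYMES}


@pytest.fixture()
def rng():
    return np.random.default_rng(20140408)


def random_distance_matrix(rng, n, scale=1.0):
    a = rng.uniform(0.05, scale, size=(n, n))
    d = (a + a.T) / 2
    np.fill_diagonal(d, 0.0)
    return d
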