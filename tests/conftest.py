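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

from esescan import SyntheticConfig, make_cohort, packaged_fixture_set


@pytest.fixture(scope="session")
def fixture_motifs():
    return packaged_fixture_set()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort shared by read-only tests."""
    cfg = SyntheticConfig(n_genes=40, seed=1234)
    return make_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
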