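import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=20,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Frozen fixture bundle (toy data + oracle fit + scenario + cohort)."""
    from shrinksim.fixtures import make_fixtures

    out = tmp_path_factory.mktemp("fixtures")
    manifest = make_fixtures(seed=0, out=out)
    return out, manifest


@pytest.fixture
def toy_separable_free():
    """Six-point dataset with interleaved outcomes, so the MLE is finite."""
    x = np.array([-2.0, -1.0, 0.0, 0.0, 1.0, 2.0])[:, None]
    y = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
    return x, y
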