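import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from hrfdeconv import DoubleGammaParams, HRStore, double_gamma_hrf  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_hrf():
    """A small 3 s / 10 Hz kernel for store payloads (keeps stores cheap)."""
    return double_gamma_hrf(DoubleGammaParams(duration_s=3.0, sfreq=10.0))


def build_random_store(rng, n_nodes, short_hrf, span=100.0, context=None):
    """Random store with n_nodes in [0, span]^3; returns (store, locations)."""
    store = HRStore()
    locations = rng.uniform(0, span, size=(n_nodes, 3))
    for i, loc in enumerate(locations):
        store.add_estimate(
            hbo=short_hrf,
            location=loc,
            doi="10.0/test",
            channel_id=f"ch{i}",
            context=dict(context or {}),
        )
    return store, locations


@pytest.fixture
def random_store_factory(short_hrf):
    def factory(rng, n_nodes, **kwargs):
        return build_random_store(rng, n_nodes, short_hrf, **kwargs)

    return factory
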