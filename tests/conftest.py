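import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import ichdquant as iq

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_phantom():
    """A small but fully featured phantom VOI with ground truth (shared)."""
    cfg = iq.default_phantom_config(seed=7, shape=(128, 128, 128))
    volume, truth = iq.generate_phantom(cfg)
    return cfg, volume, truth


@pytest.fixture(scope="session")
def small_voi_result(small_phantom):
    _, volume, _ = small_phantom
    return iq.process_voi(volume, voi_id="small", min_voxels=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
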