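import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_session():
    """One 600 s synthetic session shared across read-only tests."""
    from twitchgate.synth import SessionConfig, generate_session

    cfg = SessionConfig(duration_s=600.0, seed=11)
    rec, truth = generate_session(cfg)
    return cfg, rec, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
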