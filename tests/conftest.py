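import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import morphdiverge as md

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def templates():
    return md.make_default_templates()


@pytest.fixture(scope="session")
def study(templates):
    """One synthetic study at the published sample sizes, shared read-only."""
    return md.simulate_study(seed=1)


@pytest.fixture(scope="session")
def superimposed(study):
    return md.gpa(study.landmarks)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
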