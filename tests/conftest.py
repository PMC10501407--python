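import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def table1():
    from glioqsar.datasets import load_table1

    return load_table1()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
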