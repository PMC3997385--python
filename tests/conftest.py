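import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from srnapipe.energy import default_model

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rna(rng, n: int) -> str:
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=n)])
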