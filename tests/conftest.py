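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

from sardmir.catalog import load_catalog  # noqa: E402


@pytest.fixture(scope="session")
def catalog():
    """The packaged 101-record catalog."""
    return load_catalog()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))
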