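import numpy as np
import pytest
from hypothesis import settings

from circsponge.energy import default_table

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
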