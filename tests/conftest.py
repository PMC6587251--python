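import numpy as np
import pytest
from importlib import resources

from dcgr import filter_nonredundant, parse_aaindex1, synthetic_catalog


@pytest.fixture(scope="session")
def fixture_text() -> str:
    return (
        resources.files("dcgr.data")
        .joinpath("synthetic_fixture.aaindex1.txt")
        .read_text()
    )


@pytest.fixture(scope="session")
def raw_catalog(fixture_text):
    return parse_aaindex1(fixture_text)


@pytest.fixture(scope="session")
def catalog(raw_catalog):
    """The shipped fixture catalog after the redundancy filter (5 indices)."""
    return filter_nonredundant(raw_catalog)


@pytest.fixture(scope="session")
def full_catalog():
    """The 158-index synthetic catalog (632 features per sequence)."""
    return synthetic_catalog(158)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_protein(rng, n: int) -> str:
    from dcgr import AMINO_ACIDS

    return "".join(rng.choice(list(AMINO_ACIDS), size=n))
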