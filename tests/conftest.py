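import numpy as np
import pytest

from crossbeta.fixtures import build_ideal_fibril, build_separated_chains
from crossbeta.restraints import short_fibril_protocol
from crossbeta.structures import FibrilSpec


@pytest.fixture(scope="session")
def toy_spec():
    """6-residue x 4-chain parallel fibril, two sheets of two strands."""
    return FibrilSpec("VEALYL", 4, "parallel", [[0, 1], [2, 3]])


@pytest.fixture(scope="session")
def toy_spec_anti():
    return FibrilSpec("VEALYL", 4, "antiparallel", [[0, 1], [2, 3]])


@pytest.fixture(scope="session")
def eight_chain_spec():
    return FibrilSpec("VEALYL", 8, "antiparallel",
                      [[0, 1, 2, 3], [4, 5, 6, 7]])


@pytest.fixture(scope="session")
def toy_fibril(toy_spec):
    return build_ideal_fibril(toy_spec)


@pytest.fixture(scope="session")
def toy_fibril_anti(toy_spec_anti):
    return build_ideal_fibril(toy_spec_anti)


@pytest.fixture(scope="session")
def toy_collection(toy_spec):
    return short_fibril_protocol(toy_spec, "S0")


@pytest.fixture(scope="session")
def toy_start(toy_spec):
    return build_separated_chains(toy_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
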