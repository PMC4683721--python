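import pytest

from lgtnet.examples import (
    cycle_example,
    nonrestricted_example,
    rhodobacter_example,
)


@pytest.fixture(scope="session")
def app_trees():
    """The nine-taxon worked example: (principal, [three secondary trees])."""
    return rhodobacter_example()


@pytest.fixture(scope="session")
def cycle_pair():
    """Six-taxon (T, T1', T2') forcing a directed cycle."""
    return cycle_example()


@pytest.fixture(scope="session")
def nonrestricted_pair():
    """Six-taxon (T, T1') failing the cluster condition at (a)."""
    return nonrestricted_example()


def f(*labels):
    return frozenset(str(x) for x in labels)
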