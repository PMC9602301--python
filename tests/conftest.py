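import pytest

from worldviews import (
    build_simple_model,
    build_two_theme_model,
    enumerate_organizations,
    parse_network,
)

WORKED_EXAMPLE = """\
# two-reaction worked example
r1: 0 -> s1 ; k=1
r2: s1 + s2 -> 2 s2 ; k=1
"""


@pytest.fixture(scope="session")
def worked_net():
    """The two-species production/autocatalysis example network."""
    return parse_network(WORKED_EXAMPLE)


@pytest.fixture(scope="session")
def simple_net():
    """The 5-species single-theme worldview model (S, U, D, s, p)."""
    return build_simple_model()


@pytest.fixture(scope="session")
def simple_lattice(simple_net):
    return enumerate_organizations(simple_net)


@pytest.fixture(scope="session")
def two_theme_net():
    """The 40-species two-theme model (validated separately in its own tests)."""
    return build_two_theme_model()
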