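import numpy as np
import pytest

from cssmkit import fixtures, make_kitchen_domain
from cssmkit.domain import reachable_states


@pytest.fixture(scope="session")
def tiny_domain():
    return make_kitchen_domain("tiny")


@pytest.fixture(scope="session")
def tiny_graph(tiny_domain):
    return reachable_states(tiny_domain, cap=1000)


@pytest.fixture(scope="session")
def small_domain():
    return make_kitchen_domain("small")


@pytest.fixture(scope="session")
def small_graph(small_domain):
    return reachable_states(small_domain, cap=200_000)


@pytest.fixture(scope="session")
def tiny_bank(tiny_domain):
    return fixtures.default_duration_bank(tiny_domain)
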