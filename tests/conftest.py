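from __future__ import annotations

import pytest
from hypothesis import settings

from pgentropy import fixtures

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def c4():
    return fixtures.named("C4").graph


@pytest.fixture(scope="session")
def k4():
    return fixtures.named("K4").graph


@pytest.fixture(scope="session")
def p4():
    return fixtures.named("P4").graph


@pytest.fixture(scope="session")
def s4():
    return fixtures.named("S4").graph


@pytest.fixture(scope="session")
def graph_x():
    return fixtures.named("X").graph


@pytest.fixture(scope="session")
def graph_y():
    return fixtures.named("Y").graph


@pytest.fixture(scope="session")
def all_named():
    return {name: fixtures.named(name).graph for name in fixtures.fixture_names()}
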