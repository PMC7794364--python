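import pytest

import gbmflux as g

from helpers import quiet_contextualize


@pytest.fixture(scope="session")
def scenario():
    """Deterministic default paired cell-line scenario."""
    return g.make_paired_scenario()


@pytest.fixture(scope="session")
def ctx_pair(scenario):
    """Contextualized models for both cell lines (built once)."""
    result_a = quiet_contextualize(scenario.template, scenario.spec_a,
                                   scenario.precursors)
    result_b = quiet_contextualize(scenario.template, scenario.spec_b,
                                   scenario.precursors)
    return result_a, result_b


@pytest.fixture(scope="session")
def ctx_fvas(ctx_pair):
    """Whole-polytope (gamma=0) FVA of both contextualized models."""
    result_a, result_b = ctx_pair
    config = g.FVAConfig(gamma=0.0)
    return g.fva(result_a.model, config), g.fva(result_b.model, config)


@pytest.fixture
def chain():
    return g.make_toy_network("chain")


@pytest.fixture
def branch():
    return g.make_toy_network("branch")


@pytest.fixture
def simplex():
    return g.make_toy_network("simplex")


@pytest.fixture
def cycle():
    return g.make_toy_network("cycle")
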