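import pytest

import fibrosex as fx
from fibrosex.synthetic_data import mini_fibroblast, mini_output_categories


@pytest.fixture(scope="session")
def mini():
    return mini_fibroblast()


@pytest.fixture(scope="session")
def mini_male(mini):
    return fx.apply_condition(mini, fx.make_condition("male"))


@pytest.fixture(scope="session")
def mini_female(mini):
    return fx.apply_condition(mini, fx.make_condition("female_pre"))


@pytest.fixture(scope="session")
def mini_categories():
    return mini_output_categories()


@pytest.fixture()
def two_node_cascade():
    """source -> up -> down, unit weights, default Hill parameters."""
    return fx.NetworkModel(
        species=[fx.SpeciesSpec(id="up"), fx.SpeciesSpec(id="down")],
        reactions=[
            fx.ReactionSpec(rule="=> up", w=0.0),
            fx.ReactionSpec(rule="up => down"),
        ],
    )
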