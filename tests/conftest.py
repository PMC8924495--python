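import numpy as np
import pytest

from relcat.relnet import RelationType, RelationalNetwork, Stimulus
from relcat.scenarios import SNAKE_WOODS_CONTEXT, build_fixture


@pytest.fixture
def snake_woods():
    return build_fixture("snake-woods-negative-self")


@pytest.fixture
def snake_woods_positive():
    return build_fixture("snake-woods-positive-self")


@pytest.fixture
def full_context():
    return SNAKE_WOODS_CONTEXT


@pytest.fixture
def three_snake_net():
    """The minimal three-stimulus comparison chain (5-, 3-, 2-stripe)."""
    net = RelationalNetwork()
    for sid in ["snake5", "snake3", "snake2"]:
        net.add_stimulus(Stimulus(sid))
    net.relate("snake5", RelationType.COMPARISON_MORE, "snake3", 1.0, {"dangerous"})
    net.relate("snake3", RelationType.COMPARISON_MORE, "snake2", 1.0, {"dangerous"})
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
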