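import numpy as np
import pytest

from foragesim import Agent, Landscape, SimulationConfig
from foragesim.fixtures import make_depletion_state, make_duel_state, make_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    config, _ = make_fixture("tiny", seed=7)
    return config


@pytest.fixture
def duel():
    """(config, state) with two equal-RHP agents on one energized patch."""
    return make_duel_state(seed=11)


@pytest.fixture
def depletion():
    """(config, state) with one agent on one 30-energy patch."""
    return make_depletion_state(seed=11)


@pytest.fixture
def flat_landscape():
    """9x9 world, every patch a resource patch of quality 100, extraction 6."""
    land = Landscape(9)
    for px in range(9):
        for py in range(9):
            land.set_patch(px, py, quality=100.0, extraction_rate=6.0)
    return land.finalize()


def reduced_config(**overrides) -> SimulationConfig:
    """General-scenario midpoints on a desk-scale world: 101-patch side with
    abundance scaled by the area ratio (preserving energy and agent
    density), 1,500 ticks."""
    from foragesim import general_config

    cfg = general_config(**overrides)
    ratio = (101 / cfg.side) ** 2
    return cfg.replace(side=101, abundance=cfg.abundance * ratio,
                       run_ticks=1500)


def place(agent: Agent, x: float, y: float) -> Agent:
    agent.xcor, agent.ycor = x, y
    return agent
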