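"""Miniature worlds for tests and demonstrations.

Four named fixtures: ``tiny`` (a 21-patch world with four agents, a full
but fast tick loop), ``duel`` (two agents on a single energized patch, for
the fight pathway), ``depletion`` (one agent on one patch with a short
regrowth interval, for the deplete/regrow cycle), and ``clumptest`` (a
zero-variance landscape whose clump allocation is exactly predictable).
Fixture configurations deliberately sit outside the calibrated slider
ranges; they are built directly, bypassing range validation.
"""

from __future__ import annotations

import numpy as np

from .agents import Agent
from .config import SimulationConfig
from .landscape import Landscape
from .scheduler import SimulationState

FIXTURES = ("tiny", "duel", "depletion", "clumptest")


def make_fixture(name: str, seed: int = 0
                 ) -> tuple[SimulationConfig, Landscape | None]:
    """(config, optional hand-built landscape) for a named fixture.  A None
    landscape means the standard clump generator builds it from the
    config."""
    if name == "tiny":
        return SimulationConfig(
            tgt_neighbor=1, tgt_distance=5.0, abundance=2_000.0,
            energy_per_capita=500.0, clump_size=5, qual_mean=50, qual_sd=5,
            regrowth_rate=0.75, patch_regrowth_interval=50,
            extraction_rate_mean=6.0, extraction_rate_sd=1.0,
            movement_noise=20.0, max_move=5.0,
            resource_detection_radius=10.0,
            other_primate_detection_radius=10.0,
            side=21, run_ticks=200, seed=seed), None
    if name == "duel":
        config = SimulationConfig(
            tgt_neighbor=0, tgt_distance=5.0, abundance=1_000.0,
            energy_per_capita=500.0, clump_size=1, qual_mean=500, qual_sd=1,
            regrowth_rate=1.0, patch_regrowth_interval=1_000,
            extraction_rate_mean=5.0, extraction_rate_sd=0.0,
            movement_noise=20.0, max_move=3.0,
            resource_detection_radius=5.0,
            other_primate_detection_radius=5.0,
            side=7, run_ticks=100, seed=seed)
        land = Landscape(config.side)
        land.set_patch(3, 3, quality=500.0, extraction_rate=5.0)
        return config, land.finalize()
    if name == "depletion":
        config = SimulationConfig(
            tgt_neighbor=0, tgt_distance=5.0, abundance=30.0,
            energy_per_capita=30.0, clump_size=1, qual_mean=30, qual_sd=1,
            regrowth_rate=1.0, patch_regrowth_interval=50,
            extraction_rate_mean=6.0, extraction_rate_sd=0.0,
            movement_noise=20.0, max_move=3.0,
            resource_detection_radius=5.0,
            other_primate_detection_radius=5.0,
            side=7, run_ticks=200, seed=seed)
        land = Landscape(config.side)
        land.set_patch(3, 3, quality=30.0, extraction_rate=6.0)
        return config, land.finalize()
    if name == "clumptest":
        return SimulationConfig(
            tgt_neighbor=0, tgt_distance=5.0, abundance=500.0,
            energy_per_capita=100.0, clump_size=5, qual_mean=100, qual_sd=0,
            regrowth_rate=0.75, patch_regrowth_interval=100,
            extraction_rate_mean=6.0, extraction_rate_sd=0.0,
            movement_noise=20.0, max_move=5.0,
            resource_detection_radius=10.0,
            other_primate_detection_radius=10.0,
            side=21, run_ticks=100, seed=seed), None
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")


def make_duel_state(seed: int = 0, rhp_a: int = 5, rhp_b: int = 5
                    ) -> tuple[SimulationConfig, SimulationState]:
    """Ready-to-tick state with two agents standing on the duel patch."""
    config, land = make_fixture("duel", seed)
    agents = [Agent(0, 3.5, 3.5, 0.0, rhp_a), Agent(1, 3.5, 3.5, 180.0, rhp_b)]
    state = SimulationState(0, land, agents, np.random.default_rng(seed))
    return config, state


def make_depletion_state(seed: int = 0
                         ) -> tuple[SimulationConfig, SimulationState]:
    """Ready-to-tick state with one agent on the single depletion patch."""
    config, land = make_fixture("depletion", seed)
    agents = [Agent(0, 3.5, 3.5, 0.0, 4)]
    state = SimulationState(0, land, agents, np.random.default_rng(seed))
    return config, state
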