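"""The per-tick event loop and full-run orchestration.

Each tick (about 30 minutes of daylight) the agents act once each, in a
freshly shuffled random order.  An agent on an energized patch may try to
evict a co-occupant and then eats; an agent on an empty patch senses and
moves.  After all agents have acted, every agent's xp relaxes toward its
fight-outcome average, and — on ticks that are multiples of the regrowth
interval — the whole landscape regrows at once.  A single global random
stream drives every stochastic step, so a fixed seed reproduces a run
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from . import behavior
from .agents import Agent, init_population
from .landscape import Landscape, generate_landscape, regrow

if TYPE_CHECKING:  # pragma: no cover
    from .config import SimulationConfig
    from .metrics import MetricsSummary


@dataclass
class FightRecord:
    tick: int
    attacker_id: int
    defender_id: int
    attacker_rhp: int
    defender_rhp: int
    B: float
    C: float
    p_attack: float
    attacked: bool
    winner_id: int  # -1 when no attack happened


@dataclass
class SimulationState:
    """Mutable world state threaded through the tick loop."""

    tick: int
    landscape: Landscape
    agents: list[Agent]
    rng: np.random.Generator
    xs: np.ndarray = field(default=None)  # type: ignore[assignment]
    ys: np.ndarray = field(default=None)  # type: ignore[assignment]
    occupancy: dict[int, list[int]] = field(default_factory=dict)
    fight_log: list[FightRecord] = field(default_factory=list)
    log_fights: bool = False
    #: optional per-agent time series: (tick, id, x, y, action, gain,
    #: stored_energy, xp) rows, recorded when log_trace is set
    trace: list[tuple] = field(default_factory=list)
    log_trace: bool = False

    def __post_init__(self) -> None:
        if self.xs is None:
            self.xs = np.array([a.xcor for a in self.agents])
            self.ys = np.array([a.ycor for a in self.agents])
        if not self.occupancy:
            side = self.landscape.side
            for i, a in enumerate(self.agents):
                self.occupancy.setdefault(a.patch_index(side), []).append(i)

    def _relocate(self, i: int, old_pidx: int) -> None:
        """Update the position arrays and occupancy map after agent i moved."""
        a = self.agents[i]
        self.xs[i] = a.xcor
        self.ys[i] = a.ycor
        new_pidx = a.patch_index(self.landscape.side)
        if new_pidx != old_pidx:
            self.occupancy[old_pidx].remove(i)
            self.occupancy.setdefault(new_pidx, []).append(i)


def tick(state: SimulationState, config: "SimulationConfig") -> SimulationState:
    """Advance the world by one time step."""
    land = state.landscape
    agents = state.agents
    rng = state.rng
    side = land.side
    penergy = land.penergy
    t = state.tick

    order = rng.permutation(len(agents))
    for i in order:
        a = agents[i]
        if a.evicted_tick == t:
            if state.log_trace:
                state.trace.append((t, a.id, a.xcor, a.ycor, "evicted",
                                    0.0, a.stored_energy, a.xp))
            continue  # chased out earlier this tick: turn forfeited
        pidx = a.patch_index(side)
        if penergy[pidx] > 0:
            occ = state.occupancy.get(pidx, ())
            evicted_self = False
            if len(occ) > 1:
                co = [agents[j] for j in occ if j != i]
                decision = behavior.decide_to_fight(a, co, land, rng)
                if decision is not None and decision.attack:
                    winner, loser = behavior.resolve_fight(a, decision.defender)
                    behavior.update_xp_after_fight(winner, True)
                    behavior.update_xp_after_fight(loser, False)
                    behavior.flee(loser, land, rng, pidx)
                    loser.evicted_tick = t
                    state._relocate(loser.id, pidx)
                    evicted_self = loser is a
                if state.log_fights and decision is not None:
                    asmt = decision.assessment
                    state.fight_log.append(FightRecord(
                        t, a.id, decision.defender.id, a.rhp,
                        decision.defender.rhp, asmt.B, asmt.C, asmt.p_attack,
                        decision.attack,
                        -1 if not decision.attack
                        else behavior.resolve_fight(a, decision.defender)[0].id,
                    ))
            if not evicted_self:
                gain = behavior.eat(a, land, t)
                if state.log_trace:
                    state.trace.append((t, a.id, a.xcor, a.ycor, "eat",
                                        gain, a.stored_energy, a.xp))
            elif state.log_trace:
                state.trace.append((t, a.id, a.xcor, a.ycor, "evicted",
                                    0.0, a.stored_energy, a.xp))
        else:
            behavior._move(a, land, state.xs, state.ys, i, config, rng)
            state._relocate(i, pidx)
            if state.log_trace:
                state.trace.append((t, a.id, a.xcor, a.ycor, "move",
                                    0.0, a.stored_energy, a.xp))

    for a in agents:
        behavior.decay_xp(a)

    regrow(land, config.regrowth_rate, t + 1, config.patch_regrowth_interval)
    state.tick = t + 1
    return state


def init_state(config: "SimulationConfig",
               rng: np.random.Generator | None = None,
               landscape: Landscape | None = None,
               agents: list[Agent] | None = None,
               log_fights: bool = False,
               log_trace: bool = False) -> SimulationState:
    """Build the initial world: landscape, then population, from one seeded
    stream.  A hand-built landscape or agent list (fixtures) may be
    supplied."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if landscape is None:
        landscape = generate_landscape(config, rng)
    if agents is None:
        agents = init_population(config, landscape, rng)
    return SimulationState(0, landscape, agents, rng, log_fights=log_fights,
                           log_trace=log_trace)


def run_simulation(config: "SimulationConfig",
                   landscape: Landscape | None = None,
                   agents: list[Agent] | None = None,
                   log_fights: bool = False,
                   log_trace: bool = False,
                   ) -> tuple["MetricsSummary", SimulationState]:
    """Run a full simulation and summarize it.

    Identical config + seed gives bit-identical output.  Returns the
    metrics summary and the final state (which carries the event logs).
    """
    from .metrics import summarize

    state = init_state(config, landscape=landscape, agents=agents,
                       log_fights=log_fights, log_trace=log_trace)
    for _ in range(config.run_ticks):
        tick(state, config)
    return summarize(state.agents, config), state
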