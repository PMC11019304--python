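"""Agent state, population setup, and sensing.

Agents are identical primate-like foragers except for a fixed competitive
strength (resource holding potential, RHP, an integer 1-8 drawn uniformly at
setup).  Each agent carries a learned self-estimate of fighting ability
(``xp`` in [0, 1], starting at 0.5) plus a memory of its last five fight
outcomes, continuous torus coordinates, a heading in degrees clockwise from
north, and bookkeeping counters for the output metrics (distance traveled,
ticks spent eating vs. moving, per-tick energy intake).

Sensing is radius-limited: agents see energized resource patches within the
resource-detection radius and conspecifics within the other-primate
detection radius (capped at the target-neighbors count when that is >= 1).
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .config import ConfigurationError
from .landscape import Landscape, Patch

if TYPE_CHECKING:  # pragma: no cover
    from .config import SimulationConfig

XP_START = 0.5
STORED_ENERGY_START = 30.0
RHP_MIN, RHP_MAX = 1, 8
N_SPAWN_PATCHES = 5
FIGHT_MEMORY = 5  # running-average window of fight outcomes


class Agent:
    """One forager.  Mutable; mutated in place by the behavior submodels."""

    __slots__ = (
        "id", "xcor", "ycor", "heading", "stored_energy", "rhp", "xp",
        "fight_history", "patch_picked", "distance_traveled",
        "ticks_eating", "ticks_moving", "intake_ticks", "intake_gains",
        "evicted_tick",
    )

    def __init__(self, id: int, xcor: float, ycor: float, heading: float,
                 rhp: int):
        self.id = id
        self.xcor = xcor
        self.ycor = ycor
        self.heading = heading % 360.0
        self.stored_energy = STORED_ENERGY_START
        self.rhp = rhp
        self.xp = XP_START
        self.fight_history: list[int] = []  # last 5 outcomes, win=1 loss=0
        self.patch_picked: int | None = None  # flat patch index of goal
        self.distance_traveled = 0.0
        self.ticks_eating = 0
        self.ticks_moving = 0
        self.intake_ticks: list[int] = []
        self.intake_gains: list[float] = []
        self.evicted_tick = -1  # tick on which this agent was last evicted

    @property
    def pos(self) -> tuple[float, float]:
        return (self.xcor, self.ycor)

    def total_intake(self) -> float:
        return float(sum(self.intake_gains))

    def intake_log(self) -> list[tuple[int, float]]:
        """Per-tick energy gains as (tick, gain) pairs."""
        return list(zip(self.intake_ticks, self.intake_gains))

    def patch_index(self, side: int) -> int:
        """Flat index of the patch containing the agent."""
        return (int(self.ycor) % side) * side + (int(self.xcor) % side)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Agent(id={self.id}, x={self.xcor:.2f}, y={self.ycor:.2f}, "
                f"rhp={self.rhp}, xp={self.xp:.3f})")


def population_size(abundance: float, energy_per_capita: float) -> int:
    """Number of agents: floor(abundance / energy-per-capita)."""
    if abundance <= 0 or energy_per_capita <= 0:
        raise ConfigurationError("abundance and energy_per_capita must be > 0")
    n = int(abundance // energy_per_capita)
    if n < 1:
        raise ConfigurationError(
            f"abundance {abundance} / energy_per_capita {energy_per_capita} "
            "yields an empty population"
        )
    return n


def init_population(config: "SimulationConfig", landscape: Landscape,
                    rng: np.random.Generator) -> list[Agent]:
    """Create the population on five randomly chosen resource spawn patches.

    Each agent starts at the center of one of five spawn patches (chosen
    uniformly without replacement from all resource patches), with a uniform
    random heading and a uniform random RHP in {1..8}.
    """
    if landscape.res_idx.size < N_SPAWN_PATCHES:
        raise ConfigurationError(
            f"need at least {N_SPAWN_PATCHES} resource patches to spawn on, "
            f"got {landscape.res_idx.size}"
        )
    n = population_size(config.abundance, config.energy_per_capita)
    spawn = rng.choice(landscape.res_idx, size=N_SPAWN_PATCHES, replace=False)
    rhps = rng.integers(RHP_MIN, RHP_MAX + 1, size=n)
    headings = rng.uniform(0.0, 360.0, size=n)
    assign = rng.integers(0, N_SPAWN_PATCHES, size=n)
    side = landscape.side
    agents = []
    for i in range(n):
        py, px = divmod(int(spawn[assign[i]]), side)
        agents.append(Agent(i, px + 0.5, py + 0.5, float(headings[i]),
                            int(rhps[i])))
    return agents


# ---------------------------------------------------------------------------
# sensing


def visible_resource_indices(x: float, y: float, landscape: Landscape,
                             radius: float) -> np.ndarray:
    """Flat indices of energized resource patches whose centers lie within
    torus distance ``radius`` of (x, y).  Fast path used by the behavior
    module."""
    side = landscape.side
    dx = np.abs(landscape.res_x - x)
    np.minimum(dx, side - dx, out=dx)
    near = dx <= radius  # cheap box prefilter before the hypot
    if not near.any():
        return landscape.res_idx[:0]
    dx = dx[near]
    dy = np.abs(landscape.res_y[near] - y)
    np.minimum(dy, side - dy, out=dy)
    idx = landscape.res_idx[near]
    mask = (dx * dx + dy * dy <= radius * radius) & (landscape.penergy[idx] > 0)
    return idx[mask]


def find_visible_resources(agent: Agent, landscape: Landscape,
                           radius: float) -> list[Patch]:
    """All patches with energy whose center is within ``radius`` of the
    agent (torus distance)."""
    idx = visible_resource_indices(agent.xcor, agent.ycor, landscape, radius)
    return [landscape.patch(i) for i in idx]


def others_within(agent: Agent, others: Sequence[Agent], radius: float,
                  side: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions kept as (dist, order)) -- returns the indices into
    ``others`` within the closed ball of ``radius``, and their distances."""
    if not others:
        return np.empty(0, dtype=np.intp), np.empty(0)
    xs = np.fromiter((o.xcor for o in others), float, count=len(others))
    ys = np.fromiter((o.ycor for o in others), float, count=len(others))
    dx = np.abs(xs - agent.xcor)
    dy = np.abs(ys - agent.ycor)
    np.minimum(dx, side - dx, out=dx)
    np.minimum(dy, side - dy, out=dy)
    d = np.hypot(dx, dy)
    keep = np.flatnonzero(d <= radius)
    return keep, d[keep]


def find_nearest_primates(agent: Agent, others: Sequence[Agent],
                          radius: float, tgt_neighbor: int,
                          side: int | None = None) -> list[Agent]:
    """Conspecifics within ``radius``, nearest first (distance ties broken
    by ascending agent id), truncated to ``tgt_neighbor`` entries when that
    is >= 1.  ``tgt_neighbor = 0`` returns the full sorted set (used for
    travel headings)."""
    if side is None:
        raise TypeError("side (grid dimension) is required")
    keep, d = others_within(agent, others, radius, side)
    if keep.size == 0:
        return []
    ids = np.fromiter((others[i].id for i in keep), int, count=keep.size)
    order = np.lexsort((ids, d))
    if tgt_neighbor >= 1:
        order = order[:tgt_neighbor]
    return [others[i] for i in keep[order]]


def gregariousness_satisfied(agent: Agent, others: Iterable[Agent],
                             tgt_neighbor: int, tgt_distance: float,
                             side: int | None = None) -> bool:
    """True iff the agent has at least ``tgt_neighbor`` conspecifics within
    the closed ball of ``tgt_distance`` (always true for tgt_neighbor=0)."""
    if tgt_neighbor <= 0:
        return True
    if side is None:
        raise TypeError("side (grid dimension) is required")
    keep, _ = others_within(agent, list(others), tgt_distance, side)
    return keep.size >= tgt_neighbor


def heading_to(from_x: float, from_y: float, to_x: float, to_y: float,
               side: int) -> float:
    """Heading in degrees clockwise from north along the shortest torus
    displacement from one point to another."""
    dx = _wrap_delta(to_x - from_x, side)
    dy = _wrap_delta(to_y - from_y, side)
    return math.degrees(math.atan2(dx, dy)) % 360.0


def _wrap_delta(d: float, side: int) -> float:
    """Signed minimal displacement along one torus axis."""
    half = side / 2.0
    if d > half:
        d -= side
    elif d < -half:
        d += side
    return d
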