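"""Per-tick agent decision logic.

Two adaptive behaviors drive the model.  On an energized patch an agent may
try to evict one co-occupant: it weighs the benefit of one fewer competitor
(the extra share of the patch's energy, relative to the mean energy of the
eight neighboring patches) against a cost estimated from the xp asymmetry
with a randomly chosen opponent,

    B = clamp((penergy_c/(count-1) - penergy_c/count) / mean(penergy_a), 0, 1)
    C = (xp_opp - xp_self + 1) / 2
    P(attack) = B / (B + C)

and attacks with probability P.  The fight winner is simply the agent with
the higher RHP (the aggressor loses ties); the loser flees to a random
neighboring patch and forfeits its turn.  Both combatants shift their xp by
0.01 (win up, loss down, bounded to [0.02 - 0.01, 0.98 + 0.01] by the
update guards), and every tick xp relaxes by a small step toward the
running average of the last five outcomes.

Off an empty patch the agent moves, dispatching among four submodels:
wander (correlated random walk), travel (toward sensed conspecifics when
none of either resource is visible), forage (toward the best visible
patch when the gregariousness rules are satisfied), and cohere (toward
sensed conspecifics beyond the comfort-zone radius when they are not).
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING, NamedTuple, Sequence

import numpy as np

from .agents import Agent, heading_to, visible_resource_indices
from .landscape import Landscape, torus_distance

if TYPE_CHECKING:  # pragma: no cover
    from .config import SimulationConfig

XP_STEP = 0.01          # per-fight xp increment/decrement
XP_HIGH_GUARD = 0.98    # no increment when xp already above this
XP_LOW_GUARD = 0.02     # no decrement when xp already below this
XP_DECAY = 0.001        # per-tick relaxation toward the fight-outcome average


class FightAssessment(NamedTuple):
    """Benefit/cost bookkeeping for one potential fight."""

    penergy_c: float
    count: int
    mean_penergy_a: float
    B: float
    xp_self: float
    xp_opp: float
    C: float
    p_attack: float


class FightDecision(NamedTuple):
    """Outcome of one decide-to-fight evaluation (attack may be False)."""

    attacker: Agent
    defender: Agent
    assessment: FightAssessment
    attack: bool


# ---------------------------------------------------------------------------
# fight closed forms


def compute_benefits(penergy_c: float, count: int, mean_penergy_a: float) -> float:
    """Benefit of evicting one co-occupant: the gain in expected share of
    the contested patch, relative to mean neighboring-patch energy, clamped
    to [0, 1].  All local energy concentrated in the contested patch
    (mean_penergy_a = 0) is the maximal-benefit case, B = 1."""
    if count < 2:
        raise ValueError(f"count={count}: benefits need an opponent (count >= 2)")
    if mean_penergy_a <= 0:
        return 1.0
    raw = (penergy_c / (count - 1) - penergy_c / count) / mean_penergy_a
    return min(1.0, max(0.0, raw))


def compute_costs(xp_self: float, xp_opp: float) -> float:
    """Cost estimate from the xp asymmetry: (xp_opp - xp_self + 1)/2,
    0.5 for evenly matched opponents."""
    return (xp_opp - xp_self + 1.0) / 2.0


def attack_probability(B: float, C: float) -> float:
    """P(attack) = B/(B+C); 0 when there is no benefit."""
    if B <= 0.0:
        return 0.0
    return B / (B + C)


def assess_fight(penergy_c: float, count: int, mean_penergy_a: float,
                 xp_self: float, xp_opp: float) -> FightAssessment:
    B = compute_benefits(penergy_c, count, mean_penergy_a)
    C = compute_costs(xp_self, xp_opp)
    return FightAssessment(penergy_c, count, mean_penergy_a, B,
                           xp_self, xp_opp, C, attack_probability(B, C))


def decide_to_fight(agent: Agent, co_occupants: Sequence[Agent],
                    landscape: Landscape,
                    rng: np.random.Generator) -> FightDecision | None:
    """Pick one co-occupant uniformly at random, assess benefits and costs,
    and decide stochastically whether to attack.  Returns None when the
    agent is alone on its patch; otherwise a :class:`FightDecision` whose
    ``attack`` flag says whether a fight actually breaks out."""
    if not co_occupants:
        return None
    opp = co_occupants[int(rng.integers(len(co_occupants)))]
    pidx = agent.patch_index(landscape.side)
    nbr = landscape.neighbor_indices()[pidx]
    assessment = assess_fight(
        float(landscape.penergy[pidx]),
        len(co_occupants) + 1,
        float(landscape.penergy[nbr].mean()),
        agent.xp,
        opp.xp,
    )
    attack = rng.random() < assessment.p_attack
    return FightDecision(agent, opp, assessment, attack)


def resolve_fight(attacker: Agent, defender: Agent) -> tuple[Agent, Agent]:
    """(winner, loser): the higher RHP wins; the aggressor loses ties."""
    if attacker.rhp > defender.rhp:
        return attacker, defender
    return defender, attacker


def flee(loser: Agent, landscape: Landscape, rng: np.random.Generator,
         contested_idx: int | None = None) -> Agent:
    """Move the loser to a uniformly random Moore neighbor of the contested
    patch (its own patch by default).  Counts as a moving tick."""
    if contested_idx is None:
        contested_idx = loser.patch_index(landscape.side)
    dest = int(landscape.neighbor_indices()[contested_idx][int(rng.integers(8))])
    py, px = divmod(dest, landscape.side)
    new_x, new_y = px + 0.5, py + 0.5
    loser.distance_traveled += torus_distance(
        (loser.xcor, loser.ycor), (new_x, new_y), landscape.side)
    loser.xcor, loser.ycor = new_x, new_y
    loser.ticks_moving += 1
    return loser


def update_xp_after_fight(agent: Agent, won: bool) -> Agent:
    """Shift xp by 0.01 toward the outcome (guarded near the bounds) and
    append the outcome to the five-deep fight memory."""
    if won:
        if agent.xp <= XP_HIGH_GUARD:
            agent.xp += XP_STEP
        agent.fight_history.append(1)
    else:
        if agent.xp >= XP_LOW_GUARD:
            agent.xp -= XP_STEP
        agent.fight_history.append(0)
    if len(agent.fight_history) > 5:
        del agent.fight_history[0]
    return agent


def decay_xp(agent: Agent, delta: float = XP_DECAY) -> Agent:
    """Relax xp by at most ``delta`` toward the running average of the
    last five fight outcomes (0.5 before any fight), without overshoot."""
    h = agent.fight_history
    target = (sum(h) / len(h)) if h else 0.5
    if agent.xp > target:
        agent.xp = max(target, agent.xp - delta)
    elif agent.xp < target:
        agent.xp = min(target, agent.xp + delta)
    return agent


# ---------------------------------------------------------------------------
# eating


def eat(agent: Agent, landscape: Landscape, tick: int = 0) -> float:
    """Consume min(extraction_rate, penergy) from the agent's patch.
    Returns the energy gained.  Counts as an eating tick."""
    pidx = agent.patch_index(landscape.side)
    gain = min(float(landscape.extraction[pidx]),
               float(landscape.penergy[pidx]))
    landscape.penergy[pidx] -= gain
    agent.stored_energy += gain
    agent.intake_ticks.append(tick)
    agent.intake_gains.append(gain)
    agent.ticks_eating += 1
    return gain


# ---------------------------------------------------------------------------
# movement


def _mean_heading_toward(agent: Agent, xs: np.ndarray, ys: np.ndarray,
                         side: int) -> float:
    """Heading toward the wrapped centroid of a set of positions: average
    the minimal-wrap displacement vectors and take the angle."""
    dx = xs - agent.xcor
    dy = ys - agent.ycor
    half = side / 2.0
    dx = np.where(dx > half, dx - side, np.where(dx < -half, dx + side, dx))
    dy = np.where(dy > half, dy - side, np.where(dy < -half, dy + side, dy))
    return math.degrees(math.atan2(float(dx.mean()), float(dy.mean()))) % 360.0


def _pick_forage_patch(agent: Agent, landscape: Landscape,
                       vis_res: np.ndarray) -> int:
    """Keep the current goal patch if still visible; otherwise the visible
    patch with maximum energy (ties: nearest, then smallest row-major
    index).  Returns the goal's flat index."""
    if agent.patch_picked is not None:
        j = int(np.searchsorted(vis_res, agent.patch_picked))
        if j < vis_res.size and vis_res[j] == agent.patch_picked:
            return agent.patch_picked
    pe = landscape.penergy[vis_res]
    cand = vis_res[pe == pe.max()]
    if cand.size > 1:
        ys, xs = np.divmod(cand, landscape.side)
        d = torus_distance((xs + 0.5, ys + 0.5), (agent.xcor, agent.ycor),
                           landscape.side)
        cand = cand[d == d.min()]  # remaining ties: row-major (min index)
    goal = int(cand.min()) if cand.size > 1 else int(cand[0])
    agent.patch_picked = goal
    return goal


def _conspecific_distances(agent: Agent, xs: np.ndarray, ys: np.ndarray,
                           self_i: int | None, side: int) -> np.ndarray:
    dx = np.abs(xs - agent.xcor)
    dy = np.abs(ys - agent.ycor)
    np.minimum(dx, side - dx, out=dx)
    np.minimum(dy, side - dy, out=dy)
    d = np.hypot(dx, dy)
    if self_i is not None:
        d[self_i] = np.inf
    return d


def _move(agent: Agent, landscape: Landscape, xs: np.ndarray, ys: np.ndarray,
          self_i: int | None, config: "SimulationConfig",
          rng: np.random.Generator) -> Agent:
    """Heading choice and step for one agent on a depleted patch.  ``xs``,
    ``ys`` are current positions of the whole population (``self_i`` the
    agent's own slot, excluded from sensing)."""
    side = landscape.side
    tgt_n = config.tgt_neighbor
    vis_res = visible_resource_indices(agent.xcor, agent.ycor, landscape,
                                       config.resource_detection_radius)
    d = _conspecific_distances(agent, xs, ys, self_i, side)

    goal: int | None = None
    if vis_res.size == 0:
        visible = np.flatnonzero(d <= config.other_primate_detection_radius)
        if visible.size == 0 or tgt_n == 0:
            # wander: correlated random walk
            noise = rng.uniform(0.0, config.movement_noise) - config.movement_noise / 2.0
            agent.heading = (agent.heading + noise) % 360.0
        else:
            # travel: toward the sensed (nearest, capped) conspecifics
            sensed = visible[np.argsort(d[visible], kind="stable")][:tgt_n]
            agent.heading = _mean_heading_toward(agent, xs[sensed], ys[sensed], side)
            noise = rng.uniform(0.0, config.movement_noise) - config.movement_noise / 2.0
            agent.heading = (agent.heading + noise) % 360.0
    else:
        satisfied = tgt_n == 0 or int((d <= config.tgt_distance).sum()) >= tgt_n
        if not satisfied:
            visible = np.flatnonzero(d <= config.other_primate_detection_radius)
            sensed = visible[np.argsort(d[visible], kind="stable")][:tgt_n]
            beyond = sensed[d[sensed] > config.tgt_distance]
            if beyond.size:
                # cohere: toward the sensed agents outside the comfort zone
                agent.heading = _mean_heading_toward(
                    agent, xs[beyond], ys[beyond], side)
            else:
                satisfied = True  # revert to foraging for this tick
        if satisfied:
            goal = _pick_forage_patch(agent, landscape, vis_res)
            gy, gx = divmod(goal, side)
            agent.heading = heading_to(agent.xcor, agent.ycor,
                                       gx + 0.5, gy + 0.5, side)

    # take the step
    step = config.max_move
    if goal is not None:
        gy, gx = divmod(goal, side)
        dist = torus_distance((agent.xcor, agent.ycor), (gx + 0.5, gy + 0.5),
                              side)
        if dist <= step:
            step = dist
            agent.xcor, agent.ycor = gx + 0.5, gy + 0.5
            agent.patch_picked = None
        else:
            rad = math.radians(agent.heading)
            agent.xcor = (agent.xcor + step * math.sin(rad)) % side
            agent.ycor = (agent.ycor + step * math.cos(rad)) % side
    else:
        rad = math.radians(agent.heading)
        agent.xcor = (agent.xcor + step * math.sin(rad)) % side
        agent.ycor = (agent.ycor + step * math.cos(rad)) % side
    agent.distance_traveled += step
    agent.ticks_moving += 1
    return agent


def choose_heading_and_move(agent: Agent, landscape: Landscape,
                            others: Sequence[Agent],
                            config: "SimulationConfig",
                            rng: np.random.Generator) -> Agent:
    """Public single-agent movement entry point: dispatches among wander /
    travel / forage / cohere and advances up to ``max_move`` patch-lengths
    (truncated at the goal patch center when foraging)."""
    n = len(others)
    xs = np.fromiter((o.xcor for o in others), float, count=n)
    ys = np.fromiter((o.ycor for o in others), float, count=n)
    return _move(agent, landscape, xs, ys, None, config, rng)


__all__ = [
    "FightAssessment", "FightDecision", "compute_benefits", "compute_costs",
    "attack_probability", "assess_fight", "decide_to_fight", "resolve_fight",
    "flee", "update_xp_after_fight", "decay_xp", "eat",
    "choose_heading_and_move", "XP_STEP", "XP_DECAY",
]
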