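"""Fight decisions, xp bookkeeping, eating, and movement dispatch."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from foragesim import (
    Agent,
    Landscape,
    attack_probability,
    choose_heading_and_move,
    compute_benefits,
    compute_costs,
    decay_xp,
    decide_to_fight,
    eat,
    flee,
    resolve_fight,
    update_xp_after_fight,
)
from foragesim.landscape import torus_distance

from conftest import place

unit = st.floats(0.0, 1.0)


class TestBenefits:
    @pytest.mark.parametrize("penergy_c,count,mean_a,expected", [
        (100.0, 2, 50.0, 1.0),
        (60.0, 3, 30.0, 1 / 3),
        (10.0, 2, 1000.0, 0.005),
    ])
    def test_closed_form(self, penergy_c, count, mean_a, expected):
        assert compute_benefits(penergy_c, count, mean_a) == pytest.approx(expected)

    def test_clamped_to_unit_interval(self):
        assert compute_benefits(1000.0, 2, 1.0) == 1.0

    def test_empty_neighborhood_is_maximal_benefit(self):
        assert compute_benefits(50.0, 3, 0.0) == 1.0

    def test_requires_an_opponent(self):
        with pytest.raises(ValueError):
            compute_benefits(100.0, 1, 50.0)


class TestCosts:
    @pytest.mark.parametrize("xp_self,xp_opp,expected", [
        (0.3, 0.3, 0.5),
        (0.0, 1.0, 1.0),
        (1.0, 0.0, 0.0),
    ])
    def test_closed_form(self, xp_self, xp_opp, expected):
        assert compute_costs(xp_self, xp_opp) == expected

    @settings(max_examples=200, derandomize=True)
    @given(unit, unit)
    def test_antisymmetry_sums_to_one(self, a, b):
        assert compute_costs(a, b) + compute_costs(b, a) == pytest.approx(1.0)


class TestAttackProbability:
    @pytest.mark.parametrize("B,C,expected", [
        (0.2, 0.2, 0.5),
        (0.9, 0.9, 0.5),
        (0.0, 0.5, 0.0),
        (1.0, 1 / 3, 0.75),
    ])
    def test_closed_form(self, B, C, expected):
        assert attack_probability(B, C) == pytest.approx(expected)

    def test_zero_benefit_zero_cost(self):
        assert attack_probability(0.0, 0.0) == 0.0

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(0.01, 1.0), st.floats(0.01, 0.99), unit)
    def test_monotone_in_benefit_and_cost(self, B, C, eps):
        assert attack_probability(B + eps * (1 - B) + 1e-6, C) > attack_probability(B, C) - 1e-12
        assert attack_probability(B, C + eps * (1 - C) + 1e-6) < attack_probability(B, C) + 1e-12


def _arena(penergy_c=100.0, neighbor_energy=0.0):
    """5x5 world: center patch energized, its 8 neighbors at a set level."""
    land = Landscape(5)
    land.set_patch(2, 2, quality=max(penergy_c, 1.0), extraction_rate=5.0,
                   penergy=penergy_c)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if dx or dy:
                land.set_patch(2 + dx, 2 + dy, quality=100.0,
                               extraction_rate=5.0, penergy=neighbor_energy)
    return land.finalize()


class TestDecideToFight:
    def test_alone_no_event(self, rng):
        a = place(Agent(0, 0, 0, 0, 4), 2.5, 2.5)
        assert decide_to_fight(a, [], _arena(), rng) is None

    def test_certain_attack_when_costless_and_beneficial(self, rng):
        # B = 1 (all energy in the contested patch), C = 0 (opponent weak)
        land = _arena(neighbor_energy=0.0)
        a = place(Agent(0, 0, 0, 0, 4), 2.5, 2.5)
        b = place(Agent(1, 0, 0, 0, 4), 2.5, 2.5)
        a.xp, b.xp = 1.0, 0.0
        for _ in range(50):
            decision = decide_to_fight(a, [b], land, rng)
            assert decision.attack
            assert decision.assessment.B == 1.0
            assert decision.assessment.C == 0.0

    def test_attack_frequency_half_when_benefit_equals_cost(self, rng):
        # penergy_c=100, count=2, neighbors at 100 -> B = 0.5; equal xp -> C = 0.5
        land = _arena(penergy_c=100.0, neighbor_energy=100.0)
        a = place(Agent(0, 0, 0, 0, 4), 2.5, 2.5)
        b = place(Agent(1, 0, 0, 0, 4), 2.5, 2.5)
        n = 10_000
        attacks = sum(decide_to_fight(a, [b], land, rng).attack
                      for _ in range(n))
        assert abs(attacks / n - 0.5) < 0.015  # binomial 3 sigma


class TestResolveFight:
    def test_higher_rhp_wins(self):
        a, b = Agent(0, 0, 0, 0, 7), Agent(1, 0, 0, 0, 3)
        assert resolve_fight(a, b) == (a, b)

    def test_aggressor_loses_ties(self):
        a, b = Agent(0, 0, 0, 0, 5), Agent(1, 0, 0, 0, 5)
        assert resolve_fight(a, b) == (b, a)

    def test_weak_attacker_loses(self):
        a, b = Agent(0, 0, 0, 0, 3), Agent(1, 0, 0, 0, 8)
        assert resolve_fight(a, b) == (b, a)


class TestFlee:
    def test_flees_to_a_moore_neighbor(self, rng):
        land = _arena()
        loser = place(Agent(0, 0, 0, 0, 4), 2.5, 2.5)
        flee(loser, land, rng)
        assert (int(loser.xcor), int(loser.ycor)) in {
            (2 + dx, 2 + dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
            if dx or dy}

    def test_displacement_bounded(self, rng):
        land = _arena()
        for _ in range(20):
            loser = place(Agent(0, 0, 0, 0, 4), 2.5, 2.5)
            before = (loser.xcor, loser.ycor)
            flee(loser, land, rng)
            moved = torus_distance(before, (loser.xcor, loser.ycor), land.side)
            assert moved <= math.sqrt(2) + 1e-12
            assert loser.distance_traveled == pytest.approx(moved)
            assert loser.ticks_moving == 1


class TestXp:
    @pytest.mark.parametrize("xp,won,expected", [
        (0.5, True, 0.51),
        (0.5, False, 0.49),
        (0.985, True, 0.985),   # guard above 0.98
        (0.98, True, 0.99),
        (0.015, False, 0.015),  # guard below 0.02
        (0.02, False, 0.01),
    ])
    def test_fight_update(self, xp, won, expected):
        a = Agent(0, 0, 0, 0, 4)
        a.xp = xp
        update_xp_after_fight(a, won)
        assert a.xp == pytest.approx(expected)

    def test_history_keeps_last_five(self):
        a = Agent(0, 0, 0, 0, 4)
        for outcome in (True, True, False, True, False, False, True):
            update_xp_after_fight(a, outcome)
        assert a.fight_history == [0, 1, 0, 0, 1]

    def test_decay_no_fights_stays_at_half(self):
        a = Agent(0, 0, 0, 0, 4)
        decay_xp(a)
        assert a.xp == 0.5

    def test_decay_steps_toward_outcome_average(self):
        a = Agent(0, 0, 0, 0, 4)
        a.xp, a.fight_history = 0.60, [1, 1, 1, 1, 1]
        decay_xp(a)
        assert a.xp == pytest.approx(0.601)

    def test_decay_does_not_overshoot(self):
        a = Agent(0, 0, 0, 0, 4)
        a.xp, a.fight_history = 0.2004, [0, 0, 0, 0, 1]
        decay_xp(a)
        assert a.xp == pytest.approx(0.2)

    def test_xp_bounded_over_random_fight_sequences(self, rng):
        a = Agent(0, 0, 0, 0, 4)
        for _ in range(100_000):
            u = rng.random()
            if u < 0.45:
                update_xp_after_fight(a, True)
            elif u < 0.9:
                update_xp_after_fight(a, False)
            else:
                decay_xp(a)
            assert 0.0 <= a.xp <= 1.0


class TestEat:
    def test_consumes_extraction_rate(self):
        land = _arena(penergy_c=100.0)
        a = place(Agent(0, 0, 0, 0, 4), 2.5, 2.5)
        gain = eat(a, land, tick=3)
        assert gain == 5.0
        assert land.penergy[land.index(2, 2)] == 95.0
        assert a.stored_energy == 35.0
        assert a.intake_log() == [(3, 5.0)]
        assert a.ticks_eating == 1

    def test_cannot_overdraw_the_patch(self):
        land = _arena(penergy_c=4.0)
        a = place(Agent(0, 0, 0, 0, 4), 2.5, 2.5)
        assert eat(a, land) == 4.0
        assert land.penergy[land.index(2, 2)] == 0.0

    def test_sequential_co_occupants_split_the_remainder(self):
        land = _arena(penergy_c=8.0)
        a = place(Agent(0, 0, 0, 0, 4), 2.5, 2.5)
        b = place(Agent(1, 0, 0, 0, 4), 2.5, 2.5)
        assert eat(a, land) == 5.0
        assert eat(b, land) == 3.0
        assert land.penergy[land.index(2, 2)] == 0.0


class TestMovement:
    def _world(self, side=51):
        land = Landscape(side)
        land.set_patch(30, 25, quality=100.0, extraction_rate=5.0)
        return land.finalize()

    def _config(self, **overrides):
        from foragesim.fixtures import make_fixture

        config, _ = make_fixture("tiny", 0)
        overrides = {"max_move": 37.5, **overrides}
        return config.replace(side=51, resource_detection_radius=20.0,
                              other_primate_detection_radius=20.0,
                              **overrides)

    def test_solitary_forages_despite_conspecifics(self, rng):
        config = self._config(tgt_neighbor=0)
        land = self._world()
        a = place(Agent(0, 0, 0, 90.0, 4), 25.5, 25.5)
        others = [place(Agent(1, 0, 0, 0, 4), 20.5, 25.5)]
        choose_heading_and_move(a, land, others, config, rng)
        assert (int(a.xcor), int(a.ycor)) == (30, 25)  # on the picked patch

    def test_step_truncates_at_goal_center(self, rng):
        config = self._config(tgt_neighbor=0)
        land = self._world()
        a = place(Agent(0, 0, 0, 0.0, 4), 27.5, 25.5)  # 3 patches away
        choose_heading_and_move(a, land, [], config, rng)
        assert (a.xcor, a.ycor) == (30.5, 25.5)
        assert a.distance_traveled == pytest.approx(3.0)
        assert a.patch_picked is None  # cleared on arrival
        assert a.ticks_moving == 1

    def test_unsatisfied_agent_coheres_toward_far_conspecifics(self, rng):
        # target neighbors 4 with only 2 in the comfort zone: head toward
        # the sensed agents beyond the target distance
        config = self._config(tgt_neighbor=4, tgt_distance=6.0, max_move=5.0)
        land = self._world()
        a = place(Agent(0, 0, 0, 0.0, 4), 25.5, 25.5)
        others = [place(Agent(1, 0, 0, 0, 4), 27.5, 25.5),
                  place(Agent(2, 0, 0, 0, 4), 25.5, 27.5),
                  place(Agent(3, 0, 0, 0, 4), 25.5, 40.5),
                  place(Agent(4, 0, 0, 0, 4), 25.5, 40.5)]
        choose_heading_and_move(a, land, others, config, rng)
        # far agents sit due "north" (+y): heading 0, so x unchanged
        assert a.heading == pytest.approx(0.0)
        assert a.xcor == pytest.approx(25.5)
        assert a.ycor > 25.5

    def test_wander_applies_bounded_noise(self, rng):
        config = self._config(tgt_neighbor=0, movement_noise=20.0)
        land = Landscape(51).finalize()  # no resources anywhere
        for _ in range(50):
            a = place(Agent(0, 0, 0, 90.0, 4), 25.5, 25.5)
            choose_heading_and_move(a, land, [], config, rng)
            assert 80.0 <= a.heading <= 100.0
            assert a.distance_traveled == pytest.approx(config.max_move)

    def test_goal_patch_kept_while_visible(self, rng):
        config = self._config(tgt_neighbor=0, max_move=2.0)
        land = self._world()
        land.set_patch(14, 25, quality=50.0, extraction_rate=5.0)
        land.finalize()
        a = place(Agent(0, 0, 0, 0.0, 4), 25.5, 25.5)
        choose_heading_and_move(a, land, [], config, rng)
        first_goal = a.patch_picked
        assert first_goal == land.index(30, 25)  # highest energy wins
        choose_heading_and_move(a, land, [], config, rng)
        assert a.patch_picked == first_goal
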