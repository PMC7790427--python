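import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tmesim.agents import (
    ACTIVE, EXHAUSTED, M0, M1, M2, RECRUITED,
    ActivationParams, CancerCell, Macrophage, TCell,
    activation_probability, cancer_step, macrophage_step, resolve_engagement,
    tcell_step,
)
from tmesim.engine import SimParams, SimState
from tmesim.recruitment import RecruitParams

QUIET = SimParams(
    width=9, height=9, initial_cancer=0, resident_macrophage_density=0.0,
    recruit=RecruitParams(macrophage_per_day=0.0, r1_per_day=0.0),
)


def bare_state(params=QUIET, seed=0):
    return SimState(params, seed=seed)


class TestActivationProbability:
    def test_no_antigen_gates_to_zero(self):
        p = ActivationParams()
        assert activation_probability(0, 0, 5, p) == 0.0
        assert activation_probability(0, 3, 0, p) == 0.0

    def test_no_macrophage_closed_form(self):
        p = ActivationParams(k=6.0, s=0.6)
        expected = 1.0 / (1.0 + math.exp(-6.0 * (1.0 - 0.6)))
        assert activation_probability(1, 0, 0, p) == pytest.approx(expected)
        assert expected == pytest.approx(0.9168, abs=1e-4)

    def test_strong_m2_context_suppresses(self):
        p = ActivationParams()
        assert activation_probability(1, 0, 3, p) < 0.1

    @given(m2=st.integers(0, 8), m1=st.integers(0, 8))
    def test_bounded_probability(self, m1, m2):
        val = activation_probability(1, m1, m2, ActivationParams())
        assert 0.0 <= val <= 1.0

    @given(m1=st.integers(0, 8), m2=st.integers(0, 7))
    def test_monotone_nonincreasing_in_m2(self, m1, m2):
        p = ActivationParams()
        assert (activation_probability(1, m1, m2 + 1, p)
                <= activation_probability(1, m1, m2, p))

    @given(m1=st.integers(0, 7), m2=st.integers(0, 8))
    def test_m1_buffers_m2_suppression(self, m1, m2):
        p = ActivationParams()
        assert (activation_probability(1, m1 + 1, m2, p)
                >= activation_probability(1, m1, m2, p))


class TestMacrophage:
    def test_below_threshold_stays_m0(self):
        env = bare_state()
        m = Macrophage(id=env.next_id(), position=(4, 4))
        env.add_agent(m)
        macrophage_step(m, env)
        assert m.phenotype == M0

    def test_licensed_high_ifng_becomes_m1(self):
        env = bare_state()
        env.fields["activation"][:, :] = 5.0
        env.fields["ifng"][:, :] = 80.0
        m = Macrophage(id=env.next_id(), position=(4, 4))
        env.add_agent(m)
        macrophage_step(m, env)
        assert m.phenotype == M1

    def test_licensed_high_il4_becomes_m2(self):
        env = bare_state()
        env.fields["activation"][:, :] = 5.0
        env.fields["il4"][:, :] = 80.0
        m = Macrophage(id=env.next_id(), position=(4, 4))
        env.add_agent(m)
        macrophage_step(m, env)
        assert m.phenotype == M2

    def test_redifferentiation_waits_for_clock(self):
        env = bare_state()
        env.fields["activation"][:, :] = 5.0
        env.fields["il4"][:, :] = 80.0
        m = Macrophage(id=env.next_id(), position=(4, 4))
        env.add_agent(m)
        macrophage_step(m, env)
        assert m.phenotype == M2
        # environment flips; next hour is too soon to re-evaluate
        env.fields["il4"][:, :] = 0.0
        env.fields["ifng"][:, :] = 80.0
        macrophage_step(m, env)
        assert m.phenotype == M2
        for _ in range(24):
            macrophage_step(m, env)
        assert m.phenotype == M1

    def test_dies_at_lifespan(self):
        env = bare_state()
        m = Macrophage(id=env.next_id(), position=(4, 4), lifespan_h=1.0)
        env.add_agent(m)
        macrophage_step(m, env)
        assert not m.alive

    def test_climbs_activation_gradient(self):
        env = bare_state(QUIET.replace(chemotaxis_bias=1.0))
        grad = np.tile(np.arange(9, dtype=float), (9, 1))
        env.fields.grids["activation"] = grad
        m = Macrophage(id=env.next_id(), position=(4, 4))
        env.add_agent(m)
        macrophage_step(m, env)
        assert m.position[1] == 5  # moved one column up-gradient


class TestTCellAndEngagement:
    def _engaged_pair(self, env):
        t = TCell(id=env.next_id(), position=(4, 4), state=ACTIVE,
                  kills_remaining=1)
        c = CancerCell(id=env.next_id(), position=(4, 5))
        env.add_agent(t)
        env.add_agent(c)
        tcell_step(t, env)
        return t, c

    def test_active_tcell_engages_adjacent_cancer(self):
        env = bare_state()
        t, c = self._engaged_pair(env)
        assert t.engaged_with == c.id and c.engaged_by == t.id
        assert t.engagement_timer_h == env.params.engagement_duration_h

    def test_engaged_pair_frozen_until_expiry(self):
        env = bare_state()
        t, c = self._engaged_pair(env)
        pos_t, pos_c = t.position, c.position
        age_c = c.age_h
        cancer_step(c, env)       # engaged cancer does nothing
        assert c.age_h == age_c and c.prolif_clock_h == 0.0
        tcell_step(t, env)        # only the timer advances
        assert t.position == pos_t and c.position == pos_c
        assert t.engagement_timer_h == env.params.engagement_duration_h - 1.0

    def test_kill_at_expiry_exhausts_budget(self):
        env = bare_state()
        t, c = self._engaged_pair(env)
        for _ in range(int(env.params.engagement_duration_h)):
            tcell_step(t, env)
        assert not c.alive
        assert t.kills_remaining == 0 and t.state == EXHAUSTED
        assert env.death_log.total() == 1

    def test_exhausted_tcell_does_not_engage(self):
        env = bare_state()
        t = TCell(id=env.next_id(), position=(4, 4), state=EXHAUSTED,
                  kills_remaining=0)
        c = CancerCell(id=env.next_id(), position=(4, 5))
        env.add_agent(t)
        env.add_agent(c)
        tcell_step(t, env)
        assert t.engaged_with is None and c.engaged_by is None

    def test_dangling_engagement_is_integrity_error(self):
        env = bare_state()
        t = TCell(id=env.next_id(), position=(4, 4), state=ACTIVE,
                  engaged_with=999)
        env.add_agent(t)
        with pytest.raises(RuntimeError):
            resolve_engagement(t, env)

    def test_unactivated_cell_with_suppressive_ring_stays_recruited(self):
        env = bare_state(seed=3)
        t = TCell(id=env.next_id(), position=(4, 4))
        env.add_agent(t)
        env.add_agent(CancerCell(id=env.next_id(), position=(3, 4)))
        for site in [(3, 3), (4, 3), (5, 3), (5, 4), (5, 5), (4, 5), (3, 5)]:
            env.add_agent(Macrophage(id=env.next_id(), position=site, phenotype=M2))
        for _ in range(20):
            tcell_step(t, env)
        assert t.state == RECRUITED


class TestCancer:
    def test_division_period_from_rate(self):
        assert QUIET.division_period_h == pytest.approx(30.0)
        assert QUIET.replace(proliferation_rate_per_day=1.2).division_period_h == 20.0

    def test_surrounded_cell_goes_quiescent_then_resumes(self):
        env = bare_state()
        c = CancerCell(id=env.next_id(), position=(4, 4),
                       prolif_clock_h=QUIET.division_period_h)
        env.add_agent(c)
        ring = [Macrophage(id=env.next_id(), position=s)
                for s in env.lattice.neighbor_sites((4, 4))]
        for m in ring:
            env.add_agent(m)
        assert cancer_step(c, env) is None
        assert c.quiescent
        # free one neighbor: the cell divides on a later step
        blocker = ring[0]
        env.lattice.remove(blocker.position)
        del env.agents[blocker.id]
        daughter = cancer_step(c, env)
        assert daughter is not None and not c.quiescent
        assert daughter.position == blocker.position

    def test_lifespan_death_logged(self):
        env = bare_state()
        c = CancerCell(id=env.next_id(), position=(4, 4),
                       age_h=QUIET.cancer_lifespan_h)
        env.add_agent(c)
        cancer_step(c, env)
        assert not c.alive
        assert env.death_log.total() == 1


def test_kill_budget_conserved_over_run():
    # no T cell ever kills more than its budget, exactly
    from tmesim.engine import desk_params

    params = desk_params(max_days=16.0, kill_budget=2)
    state = SimState(params, seed=5)
    kills = {}
    for _ in range(int(16 * 24)):
        state.step()
        for a in state.agents.values():
            if isinstance(a, TCell):
                used = params.kill_budget - a.kills_remaining
                kills[a.id] = max(kills.get(a.id, 0), used)
                assert 0 <= a.kills_remaining <= params.kill_budget
                assert (a.state == EXHAUSTED) == (a.kills_remaining == 0)
    assert kills and max(kills.values()) <= params.kill_budget


def test_engagement_links_form_perfect_matching():
    from tmesim.engine import desk_params

    state = SimState(desk_params(), seed=7)
    for _ in range(360):
        state.step()
        tcells = {a.id: a for a in state.agents.values() if isinstance(a, TCell)}
        cancers = {a.id: a for a in state.agents.values() if isinstance(a, CancerCell)}
        engaged_c = [c for c in cancers.values() if c.engaged_by is not None]
        engaged_t = [t for t in tcells.values() if t.engaged_with is not None]
        assert len(engaged_c) == len(engaged_t)
        for t in engaged_t:
            assert cancers[t.engaged_with].engaged_by == t.id
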