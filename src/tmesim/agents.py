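"""Behavior rules for macrophages, T cells, and cancer cells.

Each agent occupies one lattice site and acts once per engine step, in a
random order drawn fresh each step.  The functions here mutate the agent
and its environment (lattice occupancy, death log, birth list); secretion
into the cytokine fields is collected by the engine at the start of each
step from the current agent states.

Chemotaxis is a biased random walk on the tumor-secreted activation
factor field: with the configured bias probability an agent steps to the
empty neighbor with the highest concentration (when the signal there is
detectable), otherwise to a uniformly random empty neighbor.  See
:func:`chemotaxis_move`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .grid import Lattice

M0, M1, M2 = "M0", "M1", "M2"
RECRUITED, ACTIVE, EXHAUSTED = "recruited", "active", "exhausted"


@dataclass
class Macrophage:
    id: int
    position: tuple[int, int]
    phenotype: str = M0
    age_h: float = 0.0
    lifespan_h: float = 240.0
    # starts elapsed so a macrophage evaluates as soon as it is licensed
    rediff_clock_h: float = float("inf")
    alive: bool = True


@dataclass
class TCell:
    id: int
    position: tuple[int, int]
    state: str = RECRUITED
    kills_remaining: int = 5
    engaged_with: Optional[int] = None
    engagement_timer_h: float = 0.0
    prolif_clock_h: float = 0.0
    age_h: float = 0.0
    lifespan_h: float = 120.0
    alive: bool = True


@dataclass
class CancerCell:
    id: int
    position: tuple[int, int]
    prolif_clock_h: float = 0.0
    divisions: int = 0
    quiescent: bool = False
    engaged_by: Optional[int] = None
    age_h: float = 0.0
    alive: bool = True


@dataclass(frozen=True)
class ActivationParams:
    """Sigmoid constants of the T-cell activation probability."""

    k: float = 6.0
    s: float = 0.6

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")


def activation_probability(
    antigen_present: int, num_m1: int, num_m2: int, params: ActivationParams
) -> float:
    """Probability that a T cell in contact with antigen becomes fully active.

        P_act = antigenPresence * sigmoid(k * ((antigenPresence - numM2/(numM1+1)) - s))

    M1 neighbors buffer the suppressive effect of M2 neighbors; with no
    antigen the probability is zero regardless of macrophage context.
    """
    if num_m1 < 0 or num_m2 < 0:
        raise ValueError("macrophage counts must be non-negative")
    if antigen_present not in (0, 1):
        raise ValueError("antigen_present must be 0 or 1")
    if antigen_present == 0:
        return 0.0
    x = (antigen_present - num_m2 / (num_m1 + 1)) - params.s
    return 1.0 / (1.0 + math.exp(-params.k * x))


def chemotaxis_move(agent, env) -> None:
    """Biased random-walk step toward the activation-factor gradient.

    With probability ``chemotaxis_bias`` the agent takes a gradient step:
    it moves to the empty neighbor with the highest activation-factor
    concentration (ties broken uniformly; it stays put on a strict local
    maximum).  Otherwise it steps to a uniformly random empty neighbor.
    Bias 1 recovers deterministic steepest ascent; bias 0 is an unbiased
    random walk.

    Gradient steps additionally require a detectable signal: if the best
    candidate concentration is below ``chemotaxis_sensing_threshold`` the
    cell cannot read the (numerically tiny) far-field gradient and random
    walks instead.  Together the two rules keep peritumoral immune cells a
    loose, fluctuating cloud instead of a packed shell, which a
    single-occupancy lattice would otherwise turn into an artificial
    physical cage around the tumor.
    """
    lattice: Lattice = env.lattice
    candidates = lattice.empty_neighbors(agent.position, env.movement_neighborhood)
    if not candidates:
        return
    dst = None
    if env.rng.random() < env.params.chemotaxis_bias:
        grid = env.fields["activation"]
        values = np.array([grid[s] for s in candidates])
        best = values.max()
        if best >= env.params.chemotaxis_sensing_threshold:
            if best < grid[agent.position]:
                return
            choices = [s for s, v in zip(candidates, values) if v == best]
            dst = choices[env.rng.integers(len(choices))] if len(choices) > 1 else choices[0]
    if dst is None:
        dst = candidates[env.rng.integers(len(candidates))]
    if lattice.move_agent(agent.id, agent.position, dst, env.movement_neighborhood):
        agent.position = dst


# ---------------------------------------------------------------------------
# macrophages

def macrophage_step(m: Macrophage, env) -> None:
    """Age, possibly (re)differentiate, then chemotax toward the tumor.

    Differentiation is licensed by the local activation-factor level
    crossing ``env.params.activation_threshold`` and is re-evaluated at
    most once per ``rediff_period_h`` (macrophage plasticity): the decision
    reads local IL-4 / IFN-g plus the current effective PI3K activity and
    commits to the phenotype the differentiation model returns.
    """
    if not m.alive:
        return
    p = env.params
    m.age_h += p.dt_h
    if m.age_h >= m.lifespan_h:
        env.mark_dead(m)
        return
    if math.isfinite(m.rediff_clock_h):
        m.rediff_clock_h += p.dt_h
    licensed = env.fields.local(m.position, "activation", p.readout_mode) >= p.activation_threshold
    if licensed and (not math.isfinite(m.rediff_clock_h) or m.rediff_clock_h >= p.rediff_period_h):
        il4 = env.fields.local(m.position, "il4", p.readout_mode)
        ifng = env.fields.local(m.position, "ifng", p.readout_mode)
        m.phenotype = env.decide_phenotype(il4, ifng, env.pi3k)
        m.rediff_clock_h = 0.0
    chemotaxis_move(m, env)


# ---------------------------------------------------------------------------
# T cells

def _neighbor_context(t: TCell, env):
    """Antigen presence, M1/M2 neighbor counts, and adjacent free cancer cells."""
    num_m1 = num_m2 = 0
    free_cancer: list[CancerCell] = []
    antigen = 0
    for _site, aid in env.lattice.occupied_neighbors(t.position, env.contact_neighborhood):
        a = env.agents.get(aid)
        if a is None or not a.alive:
            continue
        if isinstance(a, Macrophage):
            if a.phenotype == M1:
                num_m1 += 1
                antigen = 1
            elif a.phenotype == M2:
                num_m2 += 1
        elif isinstance(a, CancerCell):
            antigen = 1
            if a.engaged_by is None:
                free_cancer.append(a)
    return antigen, num_m1, num_m2, free_cancer


def tcell_step(t: TCell, env) -> None:
    """One step of T-cell behavior.

    An engaged T cell only advances its kill timer.  Otherwise the cell
    ages; an unactivated cell in contact with antigen (a cancer cell or an
    M1 macrophage) draws full activation against the macrophage-dependent
    probability; an active cell may proliferate into an empty neighbor site
    on its clock and then engages an adjacent free cancer cell if any.
    Cells that did not engage migrate up the activation-factor gradient.
    """
    if not t.alive:
        return
    if t.engaged_with is not None:
        resolve_engagement(t, env)
        return
    p = env.params
    t.age_h += p.dt_h
    if t.age_h >= t.lifespan_h:
        env.mark_dead(t)
        return

    antigen, num_m1, num_m2, free_cancer = _neighbor_context(t, env)

    if t.state == RECRUITED and p.immune_functional:
        prob = activation_probability(antigen, num_m1, num_m2, p.activation)
        if prob > 0 and env.rng.random() < prob:
            t.state = ACTIVE

    engaged = False
    if t.state == ACTIVE:
        t.prolif_clock_h += p.dt_h
        if t.prolif_clock_h >= p.tcell_prolif_period_h:
            empties = env.lattice.empty_neighbors(t.position, env.movement_neighborhood)
            if empties:
                site = empties[env.rng.integers(len(empties))]
                # daughters enter unactivated: expansion adds T-cell mass but
                # effector function still has to pass the activation gate
                daughter = TCell(
                    id=env.next_id(), position=site, state=RECRUITED,
                    kills_remaining=p.kill_budget, lifespan_h=p.tcell_lifespan_h,
                )
                env.add_agent(daughter)
                t.prolif_clock_h = 0.0
        if free_cancer and t.kills_remaining > 0:
            target = free_cancer[env.rng.integers(len(free_cancer))] \
                if len(free_cancer) > 1 else free_cancer[0]
            t.engaged_with = target.id
            target.engaged_by = t.id
            t.engagement_timer_h = p.engagement_duration_h
            engaged = True

    if not engaged:
        chemotaxis_move(t, env)


def resolve_engagement(t: TCell, env) -> None:
    """Advance a mutual kill engagement; on expiry the cancer cell dies.

    The kill is appended to the death log (feeding T-cell recruitment), the
    T cell's kill budget decrements, and the T cell is freed — or becomes
    exhausted when the budget reaches zero.  A one-sided link is an
    integrity error.
    """
    c = env.agents.get(t.engaged_with)
    if c is None or not isinstance(c, CancerCell) or c.engaged_by != t.id:
        raise RuntimeError(f"dangling engagement: T{t.id} -> {t.engaged_with}")
    t.engagement_timer_h -= env.params.dt_h
    if t.engagement_timer_h > 0:
        return
    c.engaged_by = None
    env.mark_dead(c, log_death=True)
    t.engaged_with = None
    t.kills_remaining -= 1
    if t.kills_remaining <= 0:
        t.state = EXHAUSTED


# ---------------------------------------------------------------------------
# cancer cells

def cancer_step(c: CancerCell, env) -> Optional[CancerCell]:
    """Proliferation with contact inhibition and a replicative limit.

    The internal clock advances while the cell is not quiescent; at the
    division period the cell divides into a uniformly random empty neighbor
    site, or becomes quiescent if fully surrounded.  Quiescent cells
    re-check for space every step and resume dividing once a site opens.
    A cell that has spent its division budget (or its lifetime, in hours
    mode) dies and its antigen is logged like any other cancer death.
    Engaged cells do nothing.
    """
    if not c.alive or c.engaged_by is not None:
        return None
    p = env.params
    c.age_h += p.dt_h
    if p.cancer_lifespan_mode == "hours" and c.age_h >= p.cancer_lifespan_h:
        env.mark_dead(c, log_death=True)
        return None
    if p.cancer_lifespan_mode == "divisions" and c.divisions >= p.cancer_max_divisions:
        env.mark_dead(c, log_death=True)
        return None

    if not c.quiescent:
        c.prolif_clock_h += p.dt_h
    if c.prolif_clock_h >= p.division_period_h:
        empties = env.lattice.empty_neighbors(c.position, env.movement_neighborhood)
        if not empties:
            c.quiescent = True
            return None
        c.quiescent = False
        site = empties[env.rng.integers(len(empties))]
        daughter = CancerCell(id=env.next_id(), position=site)
        env.add_agent(daughter)
        c.divisions += 1
        c.prolif_clock_h = 0.0
        return daughter
    return None
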