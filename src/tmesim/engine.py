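"""Simulation loop: initialization, step ordering, stopping rules, recording.

A run starts from a compact micrometastasis (25 cancer cells in the lattice
center) surrounded by randomly scattered tissue-resident M0 macrophages,
and advances in fixed steps (default 1 h).  Each step executes, in order:

1. secretion by the current secreting cells, then diffusion/decay of the
   three factors over the step;
2. macrophage recruitment (reduced by recruitment-inhibition therapy);
3. macrophages act in a freshly drawn random order;
4. T-cell recruitment from the windowed death log, then T cells act in
   random order;
5. cancer cells act in random order;
6. dead agents are removed from the lattice;
7. treatment events (continuous depletion draws, cycle-start bulk removal);
8. recording.

The run stops when the tumor is eliminated, when the tumor cell count
reaches a cap (space for immune recruits is mostly gone by then), or at the
maximum simulated time.  A single PCG64 stream seeded from the run config
drives every random choice, so (seed, params, treatment) fully determine
every output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .agents import (
    ACTIVE, M2, ActivationParams, CancerCell, Macrophage, TCell,
    cancer_step, macrophage_step, tcell_step,
)
from .diffusion import CytokineFields, FieldParams
from .grid import Lattice, Neighborhood
from .intracellular import (
    DEFAULT_RANGES, StandInConstants, SurrogateModel, mechanistic_label,
)
from .recruitment import (
    DeathLog, RecruitParams, RecruitmentStream, place_recruits,
    tcell_recruitment_rate,
)
from .treatment import TreatmentSpec, depletion_survivors, effective_pi3k, recruitment_inhibition

ELIMINATED, PERSISTED, CAPPED = "eliminated", "persisted", "capped"


@dataclass(frozen=True)
class SimParams:
    """Every rate and constant of the simulator, with shipped defaults.

    Rates are expressed per hour or per day as suffixed; concentrations are
    per-site molecule counts.  Defaults were calibrated so that, without
    treatment, the tumor escapes early immune clearance and settles into an
    immune-controlled equilibrium in the large majority of runs.
    """

    # lattice / time
    width: int = 100
    height: int = 100
    site_length_um: float = 15.0
    dt_h: float = 1.0
    max_days: float = 200.0
    tumor_cap: int = 5000
    initial_cancer: int = 25
    resident_macrophage_density: float = 2e-3
    rng_seed: int = 0

    # topology / movement
    neighborhood: Neighborhood = Neighborhood.MOORE_8
    readout_mode: str = "site"
    chemotaxis_bias: float = 0.5   # 0 = random walk, 1 = steepest ascent
    chemotaxis_sensing_threshold: float = 0.5  # molecules/site to read a gradient

    # diffusible factors
    diffusivity_um2_s: float = 2.0
    decay_per_h: float = 1.0
    sec_activation_tumor_per_h: float = 30.0
    sec_il4_tumor_per_h: float = 30.0
    sec_il4_m2_per_h: float = 15.0
    sec_ifng_tcell_per_h: float = 30.0

    # macrophages
    activation_threshold: float = 1.0
    macrophage_lifespan_h: float = 240.0
    rediff_period_h: float = 24.0
    pi3k_baseline: float = 1.0
    standin: StandInConstants = StandInConstants()
    cytokine_ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    decider: str = "mechanistic"          # or "surrogate"

    # T cells
    tcell_lifespan_h: float = 120.0
    kill_budget: int = 5
    engagement_duration_h: float = 6.0
    tcell_prolif_period_h: float = 24.0
    activation: ActivationParams = ActivationParams()
    immune_functional: bool = True

    # recruitment
    recruit: RecruitParams = RecruitParams()
    recruit_mode: str = "carry"           # or "poisson"

    # cancer cells
    proliferation_rate_per_day: float = 0.8
    cancer_lifespan_mode: str = "hours"       # or "divisions"
    cancer_max_divisions: int = 10
    cancer_lifespan_h: float = 240.0

    record_every_h: float = 1.0

    def __post_init__(self) -> None:
        if self.dt_h <= 0:
            raise ValueError("dt_h must be positive")
        if not 0.0 <= self.resident_macrophage_density <= 1.0:
            raise ValueError("resident_macrophage_density must be in [0, 1]")

    @property
    def division_period_h(self) -> float:
        """Cancer division period: 24 h / proliferation rate per day."""
        return 24.0 / self.proliferation_rate_per_day

    def replace(self, **changes) -> "SimParams":
        return dataclasses.replace(self, **changes)


def desk_params(**overrides) -> SimParams:
    """Scaled-down study conditions for desk-sized experiments.

    A 50 x 50 lattice (quarter area) with recruitment rates scaled by the
    same factor, a 60-day horizon, and a tumor cap matched to the smaller
    lattice.  Treatment studies on this scale start therapy at day 20,
    after the scaled system has settled (see the companion docs).
    """
    base = dict(
        width=50, height=50, max_days=60.0, tumor_cap=1500,
        recruit=RecruitParams(macrophage_per_day=15.0, r1_per_day=15.0),
    )
    base.update(overrides)
    return SimParams(**base)


DESK_TREATMENT_START_DAY = 20.0


@dataclass
class RunSummary:
    outcome: str
    elimination_day: Optional[float]
    max_m1: int
    max_total_t: int
    max_active_t: int
    final_tumor: int


class SimState:
    """Mutable simulation state; the ``env`` seen by the agent rules."""

    def __init__(
        self,
        params: SimParams,
        treatment: Optional[TreatmentSpec] = None,
        surrogate: Optional[SurrogateModel] = None,
        seed: Optional[int] = None,
    ):
        self.params = params
        self.treatment = treatment
        self.rng = np.random.default_rng(params.rng_seed if seed is None else seed)
        self.lattice = Lattice(params.width, params.height, params.site_length_um)
        fp = FieldParams(params.diffusivity_um2_s, params.decay_per_h)
        self.fields = CytokineFields(
            self.lattice.shape, params.site_length_um,
            params={k: fp for k in ("activation", "il4", "ifng")},
        )
        self.agents: dict[int, Union[Macrophage, TCell, CancerCell]] = {}
        self._next_id = 0
        self.t_h = 0.0
        self.death_log = DeathLog()
        self.mac_stream = RecruitmentStream(params.recruit_mode)
        self.tcell_stream = RecruitmentStream(params.recruit_mode)
        self.records: list[dict] = []
        self.contact_neighborhood = params.neighborhood
        self.movement_neighborhood = params.neighborhood
        self._dead: list[int] = []
        if params.decider == "surrogate":
            if surrogate is None:
                raise ValueError("decider='surrogate' requires a trained SurrogateModel")
            self._decide = surrogate.predict
        else:
            consts = params.standin
            self._decide = lambda il4, ifng, pi3k: mechanistic_label(il4, ifng, pi3k, consts)
        self._initialize()

    # -- env interface used by the agent rules --------------------------

    @property
    def t_days(self) -> float:
        return self.t_h / 24.0

    @property
    def pi3k(self) -> float:
        return effective_pi3k(self.treatment, self.t_days, self.params.pi3k_baseline)

    def decide_phenotype(self, il4: float, ifng: float, pi3k: float) -> str:
        return self._decide(il4, ifng, pi3k)

    def next_id(self) -> int:
        self._next_id += 1
        return self._next_id

    def add_agent(self, agent) -> None:
        self.lattice.place(agent.id, agent.position)
        self.agents[agent.id] = agent

    def mark_dead(self, agent, log_death: bool = False) -> None:
        if not agent.alive:
            return
        agent.alive = False
        self._dead.append(agent.id)
        if log_death and isinstance(agent, CancerCell):
            self.death_log.record(self.t_days)

    # -- initialization --------------------------------------------------

    def _initialize(self) -> None:
        p = self.params
        side = int(np.ceil(np.sqrt(p.initial_cancer)))
        if side > min(p.width, p.height):
            raise ValueError("initial cancer block exceeds lattice")
        r0 = (p.height - side) // 2
        c0 = (p.width - side) // 2
        placed = 0
        for r in range(r0, r0 + side):
            for c in range(c0, c0 + side):
                if placed >= p.initial_cancer:
                    break
                self.add_agent(CancerCell(id=self.next_id(), position=(r, c)))
                placed += 1
        # resident macrophages on the remaining sites, independent Bernoulli
        mask = self.rng.random(self.lattice.shape) < p.resident_macrophage_density
        for (r, c) in zip(*np.nonzero(mask)):
            site = (int(r), int(c))
            if self.lattice.is_empty(site):
                self.add_agent(Macrophage(
                    id=self.next_id(), position=site,
                    lifespan_h=p.macrophage_lifespan_h,
                ))

    # -- census helpers ---------------------------------------------------

    def census(self) -> dict[str, int]:
        n = {"cancer": 0, "m0": 0, "m1": 0, "m2": 0, "t_total": 0, "t_active": 0}
        for a in self.agents.values():
            if not a.alive:
                continue
            if isinstance(a, CancerCell):
                n["cancer"] += 1
            elif isinstance(a, Macrophage):
                n[a.phenotype.lower()] += 1
            else:
                n["t_total"] += 1
                if a.state == ACTIVE:
                    n["t_active"] += 1
        return n

    def n_cancer(self) -> int:
        return sum(1 for a in self.agents.values()
                   if a.alive and isinstance(a, CancerCell))

    # -- phases -----------------------------------------------------------

    def _collect_sources(self) -> list[tuple[tuple[int, int], str, float]]:
        p = self.params
        sources = []
        for a in self.agents.values():
            if not a.alive:
                continue
            if isinstance(a, CancerCell):
                if a.engaged_by is None:
                    sources.append((a.position, "activation", p.sec_activation_tumor_per_h))
                    sources.append((a.position, "il4", p.sec_il4_tumor_per_h))
            elif isinstance(a, Macrophage):
                if a.phenotype == M2:
                    sources.append((a.position, "il4", p.sec_il4_m2_per_h))
            elif isinstance(a, TCell):
                if a.state == ACTIVE and a.engaged_with is None:
                    sources.append((a.position, "ifng", p.sec_ifng_tcell_per_h))
        return sources

    def _recruit_macrophages(self) -> None:
        p = self.params
        inh = recruitment_inhibition(self.treatment, self.t_days)
        expected = p.recruit.macrophage_per_day * (1.0 - inh) * p.dt_h / 24.0
        n = self.mac_stream.arrivals(expected, self.rng)
        for site in place_recruits(n, self.lattice, self.rng, self.mac_stream):
            self.add_agent(Macrophage(
                id=self.next_id(), position=site, lifespan_h=p.macrophage_lifespan_h,
            ))

    def _recruit_tcells(self) -> None:
        p = self.params
        n_death = self.death_log.windowed_deaths(self.t_days, p.recruit)
        rate = tcell_recruitment_rate(n_death, p.recruit)
        n = self.tcell_stream.arrivals(rate * p.dt_h / 24.0, self.rng)
        for site in place_recruits(n, self.lattice, self.rng, self.tcell_stream):
            self.add_agent(TCell(
                id=self.next_id(), position=site,
                kills_remaining=p.kill_budget, lifespan_h=p.tcell_lifespan_h,
            ))

    def _iter_random(self, cls) -> list:
        ids = [aid for aid, a in self.agents.items() if isinstance(a, cls) and a.alive]
        if len(ids) > 1:
            order = self.rng.permutation(len(ids))
            ids = [ids[i] for i in order]
        return [self.agents[i] for i in ids]

    def _remove_dead(self) -> None:
        for aid in self._dead:
            a = self.agents.pop(aid, None)
            if a is not None:
                self.lattice.remove(a.position)
        self._dead.clear()

    def _apply_treatment(self) -> None:
        spec = self.treatment
        if spec is None or spec.strategy != "depletion":
            return
        p = self.params
        if spec.schedule == "continuous":
            if not spec.active(self.t_days):
                return
            cycle_start = False
        else:
            cycle_start = spec.cycle_starts_at(self.t_days - p.dt_h / 24.0, p.dt_h / 24.0)
            if not cycle_start:
                return
        macs = [a for a in self.agents.values() if isinstance(a, Macrophage) and a.alive]
        keep = depletion_survivors(len(macs), spec, self.rng, cycle_start)
        for m, k in zip(macs, keep):
            if not k:
                self.mark_dead(m)
        self._remove_dead()

    def _record(self) -> None:
        c = self.census()
        il4 = self.fields["il4"]
        ifng = self.fields["ifng"]
        self.records.append({
            "time_days": self.t_days,
            "cancer": c["cancer"], "m0": c["m0"], "m1": c["m1"], "m2": c["m2"],
            "t_total": c["t_total"], "t_active": c["t_active"],
            "il4_mean": float(il4.mean()), "il4_max": float(il4.max()),
            "ifng_mean": float(ifng.mean()), "ifng_max": float(ifng.max()),
            "treatment_on": int(self.treatment.active(self.t_days))
            if self.treatment else 0,
        })

    # -- the step ---------------------------------------------------------

    def step(self) -> None:
        p = self.params
        # 1. secretion then diffusion/decay over the step
        self.fields.secrete(self._collect_sources(), p.dt_h)
        self.fields.diffuse(p.dt_h)
        # 2. macrophage recruitment (treatment-adjusted)
        self._recruit_macrophages()
        # 3. macrophages in random order
        for m in self._iter_random(Macrophage):
            macrophage_step(m, self)
        # 4. T-cell recruitment, then T cells in random order
        self._recruit_tcells()
        for t in self._iter_random(TCell):
            tcell_step(t, self)
        # 5. cancer cells in random order
        for c in self._iter_random(CancerCell):
            cancer_step(c, self)
        # 6. remove dead agents
        self._remove_dead()
        # 7. treatment events (time advances first so schedules see the
        #    step's end time, matching the recorded treatment state)
        self.t_h += p.dt_h
        self._apply_treatment()

    def timecourse(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def run(
    params: SimParams,
    treatment: Optional[TreatmentSpec] = None,
    surrogate: Optional[SurrogateModel] = None,
    seed: Optional[int] = None,
    audit: bool = False,
) -> tuple[pd.DataFrame, RunSummary]:
    """Simulate one tumor from seeding to elimination, cap, or max time.

    Returns the per-hour time course and a summary whose maxima are taken
    over the records at or after treatment start (the whole run when no
    treatment is given).  ``audit=True`` verifies the occupancy bijection
    after every step (slow; used in tests).
    """
    state = SimState(params, treatment, surrogate, seed)
    state._record()
    max_steps = int(round(params.max_days * 24.0 / params.dt_h))
    record_stride = max(1, int(round(params.record_every_h / params.dt_h)))
    outcome = PERSISTED
    elimination_day = None
    for istep in range(max_steps):
        state.step()
        if audit:
            state.lattice.audit({aid: a.position for aid, a in state.agents.items()})
        n = state.n_cancer()
        done = n == 0 or n >= params.tumor_cap
        if (istep + 1) % record_stride == 0 or done:
            state._record()
        if n == 0:
            outcome = ELIMINATED
            elimination_day = state.t_days
            break
        if n >= params.tumor_cap:
            outcome = CAPPED
            break
    tc = state.timecourse()
    window_start = treatment.start_day if treatment is not None else 0.0
    w = tc[tc["time_days"] >= window_start]
    if w.empty:
        w = tc
    summary = RunSummary(
        outcome=outcome,
        elimination_day=elimination_day,
        max_m1=int(w["m1"].max()),
        max_total_t=int(w["t_total"].max()),
        max_active_t=int(w["t_active"].max()),
        final_tumor=int(tc["cancer"].iloc[-1]),
    )
    return tc, summary
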