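"""Macrophage-targeted immunotherapies and their schedules.

Three strategies, each parameterized by a strength in [0, 1]:

* ``depletion`` — macrophages of every phenotype are killed: continuously
  (per-step apoptosis probability = strength) or, when cycled, by removing
  a fixed fraction = strength of all macrophages at the start of each cycle.
* ``recruitment_inhibition`` — the macrophage recruitment rate is scaled by
  (1 - strength) while treatment is on.
* ``pi3k_inhibition`` (re-education) — the PI3K-activity input of the
  differentiation decision becomes (1 - strength) while treatment is on,
  biasing macrophages toward the M1 phenotype.  It touches nothing else.

Schedules are pure functions of time: ``continuous`` is on from
``start_day`` forever; ``cycled`` is on for the first ``days_on`` of every
``cycle_duration`` window after ``start_day``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEPLETION = "depletion"
RECRUITMENT_INHIBITION = "recruitment_inhibition"
PI3K_INHIBITION = "pi3k_inhibition"
STRATEGIES = (DEPLETION, RECRUITMENT_INHIBITION, PI3K_INHIBITION)


@dataclass(frozen=True)
class TreatmentSpec:
    """One intervention arm: strategy, strength, and schedule."""

    strategy: str
    strength: float
    schedule: str = "continuous"          # or "cycled"
    start_day: float = 100.0
    cycle_duration_days: float | None = None
    days_on: float | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")
        if self.schedule not in ("continuous", "cycled"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.schedule == "cycled":
            if self.cycle_duration_days is None or self.days_on is None:
                raise ValueError("cycled schedule needs cycle_duration_days and days_on")
            if self.cycle_duration_days <= 0:
                raise ValueError("cycle_duration_days must be positive")
            if not 0 < self.days_on < self.cycle_duration_days:
                # on-time >= cycle length is just continuous treatment; such
                # combinations are rejected rather than silently collapsed.
                raise ValueError("cycled schedule requires 0 < days_on < cycle_duration")

    def active(self, t_days: float) -> bool:
        """Whether treatment is being given at simulation time ``t_days``."""
        if t_days < self.start_day:
            return False
        if self.schedule == "continuous":
            return True
        return (t_days - self.start_day) % self.cycle_duration_days < self.days_on

    def cycle_starts_at(self, t_days: float, dt_days: float) -> bool:
        """True when step [t, t+dt) contains a cycle start (incl. start_day)."""
        if self.schedule != "cycled":
            return False
        if t_days + dt_days <= self.start_day:
            return False
        # index of cycle containing the end of this step vs the previous step
        prev = np.floor((t_days - self.start_day) / self.cycle_duration_days)
        cur = np.floor((t_days + dt_days - self.start_day) / self.cycle_duration_days)
        return bool(cur > prev) or (t_days <= self.start_day < t_days + dt_days)


def depletion_survivors(
    n_macrophages: int, spec: TreatmentSpec, rng: np.random.Generator,
    cycle_start: bool,
) -> np.ndarray:
    """Boolean mask over macrophage slots: True = survives this step.

    Continuous mode thins each macrophage independently with probability
    = strength per step, phenotype-blind.  Cycled mode removes an exact
    fraction (round-half-up) of the population, sampled without
    replacement, only on the step that opens a cycle.
    """
    keep = np.ones(n_macrophages, dtype=bool)
    # strength 0 must not consume RNG draws: a zero-strength arm replays
    # the untreated trajectory bit-exactly under the same seed
    if spec.strategy != DEPLETION or n_macrophages == 0 or spec.strength == 0.0:
        return keep
    if spec.schedule == "continuous":
        keep = rng.random(n_macrophages) >= spec.strength
    elif cycle_start:
        n_remove = int(np.floor(spec.strength * n_macrophages + 0.5))
        if n_remove > 0:
            idx = rng.choice(n_macrophages, size=min(n_remove, n_macrophages),
                             replace=False)
            keep[idx] = False
    return keep


def recruitment_inhibition(spec: TreatmentSpec | None, t_days: float) -> float:
    """Fraction by which macrophage recruitment is reduced at time t."""
    if spec is None or spec.strategy != RECRUITMENT_INHIBITION or not spec.active(t_days):
        return 0.0
    return spec.strength


def effective_pi3k(spec: TreatmentSpec | None, t_days: float, baseline: float = 1.0) -> float:
    """PI3K activity fed to the differentiation decision at time t."""
    if spec is None or spec.strategy != PI3K_INHIBITION or not spec.active(t_days):
        return baseline
    return baseline * (1.0 - spec.strength)
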