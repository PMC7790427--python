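"""Immune-cell influx into the tumor microenvironment.

T-cell recruitment is driven by logged cancer-cell deaths: dying tumor
cells release antigen that primes T cells in the lymph node, and the
recruitment rate saturates in the number of recent deaths,

    r(t) = ka * N_death * r1 / (ki + N_death),

where ``ka`` is the tumor mutational burden, ``r1`` the basal recruitment
rate, ``ki`` the neoantigen strength (half-saturation in deaths), and
``N_death`` counts deaths inside a window of width ``t_window`` centered at
``t - t_delay`` (the delay covers priming and trafficking).  Macrophages
are recruited at a constant rate, reducible by recruitment-inhibition
therapy.  Both kinds of recruits land on uniformly random empty sites.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .grid import Lattice


@dataclass(frozen=True)
class RecruitParams:
    """Constants of the recruitment laws (rates per day)."""

    ka: float = 1.0                      # mutational burden (dimensionless)
    r1_per_day: float = 60.0             # basal T-cell recruitment rate
    ki: float = 10.0                     # neoantigen strength (deaths, half-sat)
    t_delay_days: float = 3.0
    t_window_days: float = 2.0
    macrophage_per_day: float = 60.0

    def __post_init__(self) -> None:
        for name in ("ka", "r1_per_day", "ki", "t_delay_days", "t_window_days",
                     "macrophage_per_day"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ki <= 0:
            raise ValueError("ki must be positive")


@dataclass
class DeathLog:
    """Time-ordered record of cancer-cell deaths feeding T-cell recruitment."""

    times: list[float] = field(default_factory=list)   # days, non-decreasing
    counts: list[int] = field(default_factory=list)

    def record(self, t_days: float, count: int = 1) -> None:
        if count < 1:
            raise ValueError("count must be >= 1")
        if self.times and t_days < self.times[-1]:
            raise ValueError("death times must be non-decreasing")
        self.times.append(t_days)
        self.counts.append(count)

    def total(self) -> int:
        return sum(self.counts)

    def windowed_deaths(self, t_days: float, params: RecruitParams) -> int:
        """Deaths inside the closed window centered at ``t - t_delay``."""
        center = t_days - params.t_delay_days
        lo = center - 0.5 * params.t_window_days
        hi = center + 0.5 * params.t_window_days
        i = bisect.bisect_left(self.times, lo)
        j = bisect.bisect_right(self.times, hi)
        return sum(self.counts[i:j])


def tcell_recruitment_rate(n_death: int, params: RecruitParams) -> float:
    """Saturating recruitment law; cells per day, bounded by ka * r1."""
    if n_death < 0:
        raise ValueError("n_death must be non-negative")
    return params.ka * n_death * params.r1_per_day / (params.ki + n_death)


@dataclass
class RecruitmentStream:
    """Converts a continuous arrival rate into integer per-step arrivals.

    Default mode is a deterministic carry accumulator: each step contributes
    ``rate * dt`` to a fractional balance and the integer part arrives, so
    long-run arrivals per unit time equal the rate exactly and runs are
    reproducible.  ``mode='poisson'`` draws Poisson counts instead.
    """

    mode: str = "carry"
    carry: float = 0.0
    shortfall: int = 0

    def arrivals(self, expected: float, rng: np.random.Generator) -> int:
        if expected < 0:
            raise ValueError("expected arrivals must be non-negative")
        if self.mode == "poisson":
            return int(rng.poisson(expected))
        self.carry += expected
        n = int(self.carry)
        self.carry -= n
        return n


def place_recruits(
    n: int, lattice: Lattice, rng: np.random.Generator,
    stream: RecruitmentStream | None = None,
) -> list[tuple[int, int]]:
    """Pick uniformly random empty sites for ``n`` recruits.

    If fewer empty sites exist than arrivals, places as many as fit and
    records the shortfall on the stream (recruitment declines inherently as
    the lattice fills).
    """
    if n <= 0:
        return []
    empties = lattice.empty_sites()
    if len(empties) < n:
        if stream is not None:
            stream.shortfall += n - len(empties)
        n = len(empties)
    if n == 0:
        return []
    idx = rng.choice(len(empties), size=n, replace=False)
    return [empties[i] for i in np.atleast_1d(idx)]
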