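"""Reaction-diffusion layer for the three diffusible factors.

Each factor i obeys

    dC_i/dt = D_i * laplacian(C_i) - lambda_i * C_i + k_sec,i * [secreting cells]

on the same grid as the cell lattice.  Concentrations are per-site molecule
counts.  The solver is an explicit 5-point finite-difference scheme with
zero-flux (reflecting) boundaries, which conserves total mass exactly when
decay and secretion are zero.  A macro time step is split into the smallest
number of sub-steps satisfying the stability bound D*dt/h^2 <= 1/4, so the
scheme also preserves non-negativity.

First-order decay is an extension: without it per-site molecule counts grow
without bound under continuous secretion.  Setting ``decay_per_h`` to zero
recovers the pure diffusion-plus-secretion dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

FACTORS = ("activation", "il4", "ifng")

STABILITY_LIMIT = 0.25  # max D*dt/h^2 per explicit sub-step


@njit(cache=True)
def _diffuse_kernel(c: np.ndarray, r: float, decay_factor: float, n_sub: int) -> None:
    """In-place explicit diffusion with reflecting boundaries.

    ``r = D * dt_sub / h^2``; each sub-step applies the 5-point Laplacian
    then multiplies by ``decay_factor = exp(-lambda * dt_sub)``.  Missing
    neighbors at the boundary are replaced by the center value (no flux).
    """
    ny, nx = c.shape
    src = c
    buf = np.empty_like(c)
    for _ in range(n_sub):
        for i in range(ny):
            for j in range(nx):
                center = src[i, j]
                up = src[i - 1, j] if i > 0 else center
                down = src[i + 1, j] if i < ny - 1 else center
                left = src[i, j - 1] if j > 0 else center
                right = src[i, j + 1] if j < nx - 1 else center
                buf[i, j] = (center + r * (up + down + left + right - 4.0 * center)) * decay_factor
        src, buf = buf, src
    if src is not c:
        c[:, :] = src


@dataclass
class FieldParams:
    """Transport constants for one diffusible factor."""

    diffusivity_um2_s: float = 2.0
    decay_per_h: float = 1.0


@dataclass
class CytokineFields:
    """The three scalar concentration grids co-registered with the lattice.

    Factors: ``activation`` (tumor-secreted macrophage activation factor,
    chiefly HMG-B1), ``il4`` (tumor- and M2-secreted, M2-polarizing) and
    ``ifng`` (active-T-cell-secreted, M1-polarizing).
    """

    shape: tuple[int, int]
    site_length_um: float = 15.0
    params: dict[str, FieldParams] = field(default_factory=dict)
    grids: dict[str, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        for f in FACTORS:
            self.params.setdefault(f, FieldParams())
        self.grids = {f: np.zeros(self.shape, dtype=np.float64) for f in FACTORS}

    def __getitem__(self, factor: str) -> np.ndarray:
        if factor not in self.grids:
            raise KeyError(f"unknown factor {factor!r}; have {sorted(self.grids)}")
        return self.grids[factor]

    def total_mass(self, factor: str) -> float:
        return float(self[factor].sum())

    # -- source term --------------------------------------------------------

    def secrete(self, sources: list[tuple[tuple[int, int], str, float]], dt_h: float) -> None:
        """Forward-Euler source term: each (site, factor, rate) adds rate*dt.

        Rates are molecules per hour per secreting cell; multiple sources on
        one site are additive.
        """
        if dt_h <= 0:
            raise ValueError("dt must be positive")
        ny, nx = self.shape
        for (r, c), factor, rate in sources:
            if rate < 0:
                raise ValueError("secretion rate must be non-negative")
            if not (0 <= r < ny and 0 <= c < nx):
                raise IndexError(f"source site {(r, c)} out of bounds")
            self[factor][r, c] += rate * dt_h

    # -- transport ----------------------------------------------------------

    def n_substeps(self, factor: str, dt_h: float) -> int:
        """Sub-steps needed so each satisfies the explicit stability bound."""
        p = self.params[factor]
        d_sites_h = p.diffusivity_um2_s * 3600.0 / self.site_length_um**2
        if not math.isfinite(d_sites_h) or d_sites_h < 0:
            raise ValueError(f"non-finite diffusivity for {factor}")
        return max(1, math.ceil(d_sites_h * dt_h / STABILITY_LIMIT))

    def diffuse(self, dt_h: float, substeps: int | None = None) -> None:
        """Advance all factors by ``dt_h`` hours of diffusion + decay."""
        if dt_h <= 0:
            raise ValueError("dt must be positive")
        for factor in FACTORS:
            p = self.params[factor]
            n_sub = substeps if substeps is not None else self.n_substeps(factor, dt_h)
            dt_sub = dt_h / n_sub
            d_sites_h = p.diffusivity_um2_s * 3600.0 / self.site_length_um**2
            r = d_sites_h * dt_sub
            decay_factor = math.exp(-p.decay_per_h * dt_sub)
            _diffuse_kernel(self.grids[factor], r, decay_factor, n_sub)

    # -- readout ------------------------------------------------------------

    def local(self, site: tuple[int, int], factor: str, mode: str = "site") -> float:
        """Concentration an agent senses at ``site``.

        ``mode='site'`` reads the agent's own site (default); ``'mean3x3'``
        averages the in-bounds 3x3 patch around it.
        """
        grid = self[factor]
        ny, nx = self.shape
        r, c = site
        if not (0 <= r < ny and 0 <= c < nx):
            raise IndexError(f"site {site} out of bounds")
        if mode == "site":
            return float(grid[r, c])
        if mode == "mean3x3":
            patch = grid[max(0, r - 1): r + 2, max(0, c - 1): c + 2]
            return float(patch.mean())
        raise ValueError(f"unknown readout mode {mode!r}")

    def to_frame(self):
        """Long-format DataFrame (factor, row, col, concentration) for CSV export."""
        import pandas as pd

        rows = []
        for f in FACTORS:
            g = self.grids[f]
            r_idx, c_idx = np.indices(g.shape)
            rows.append(pd.DataFrame({
                "factor": f,
                "row": r_idx.ravel(),
                "col": c_idx.ravel(),
                "concentration": g.ravel(),
            }))
        return pd.concat(rows, ignore_index=True)
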