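"""Spatial snapshots: agent-type grids as CSV codes or PNG rasters."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .agents import ACTIVE, CancerCell, Macrophage, TCell

#: integer codes written to CSV snapshots
CODES = {
    "empty": 0, "cancer": 1, "tcell": 2, "tcell_active": 3,
    "m0": 4, "m1": 5, "m2": 6,
}

#: display colors: tumor black, T cell yellow, active T cell red,
#: M0 blue, M1 green, M2 purple
COLORS = {
    0: (1.0, 1.0, 1.0), 1: (0.0, 0.0, 0.0), 2: (1.0, 0.9, 0.1),
    3: (0.9, 0.1, 0.1), 4: (0.2, 0.4, 0.9), 5: (0.1, 0.7, 0.2),
    6: (0.6, 0.2, 0.7),
}


def type_grid(state) -> np.ndarray:
    """Agent-type code per site for the current simulation state."""
    grid = np.zeros(state.lattice.shape, dtype=np.int8)
    for a in state.agents.values():
        if not a.alive:
            continue
        if isinstance(a, CancerCell):
            code = CODES["cancer"]
        elif isinstance(a, Macrophage):
            code = CODES[a.phenotype.lower()]
        elif isinstance(a, TCell):
            code = CODES["tcell_active"] if a.state == ACTIVE else CODES["tcell"]
        else:
            continue
        grid[a.position] = code
    return grid


def write_csv(state, path: str | Path) -> None:
    np.savetxt(path, type_grid(state), fmt="%d", delimiter=",")


def write_png(state, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    grid = type_grid(state)
    cmap = ListedColormap([COLORS[i] for i in range(len(COLORS))])
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(grid, cmap=cmap, vmin=0, vmax=len(COLORS) - 1, interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
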