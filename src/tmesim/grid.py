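"""Lattice geometry and occupancy bookkeeping.

The tissue slice is a regular 2-D lattice in which every site holds at most
one cell.  With the default 100 x 100 grid and a 15 micrometer site length
(one cell diameter) the domain represents a 1.5 x 1.5 mm slice.  All agents
and the cytokine fields share this geometry.  Coordinates are 0-based
``(row, col)`` pairs and every deterministic iteration is row-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

import numpy as np

EMPTY = -1


class Neighborhood(str, Enum):
    """Lattice adjacency used for contact interactions and movement."""

    VON_NEUMANN_4 = "von_neumann_4"
    MOORE_8 = "moore_8"

    @property
    def offsets(self) -> tuple[tuple[int, int], ...]:
        if self is Neighborhood.VON_NEUMANN_4:
            return ((-1, 0), (0, -1), (0, 1), (1, 0))
        return (
            (-1, -1), (-1, 0), (-1, 1),
            (0, -1), (0, 1),
            (1, -1), (1, 0), (1, 1),
        )


@dataclass
class Lattice:
    """Single-occupancy grid mapping sites to agent identifiers.

    ``occupancy[r, c]`` is an agent id or :data:`EMPTY`.  Boundaries are hard
    walls: sites outside the grid do not exist and agents cannot wrap around.
    """

    width: int = 100
    height: int = 100
    site_length_um: float = 15.0
    occupancy: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("lattice dimensions must be positive")
        self.occupancy = np.full((self.height, self.width), EMPTY, dtype=np.int64)

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def n_sites(self) -> int:
        return self.height * self.width

    @property
    def extent_um(self) -> tuple[float, float]:
        """Physical size (height, width) of the slice in micrometers."""
        return (self.height * self.site_length_um, self.width * self.site_length_um)

    def in_bounds(self, site: tuple[int, int]) -> bool:
        r, c = site
        return 0 <= r < self.height and 0 <= c < self.width

    def center(self) -> tuple[int, int]:
        return (self.height // 2, self.width // 2)

    # -- occupancy --------------------------------------------------------

    def is_empty(self, site: tuple[int, int]) -> bool:
        return self.occupancy[site] == EMPTY

    def agent_at(self, site: tuple[int, int]) -> int | None:
        aid = self.occupancy[site]
        return None if aid == EMPTY else int(aid)

    def place(self, agent_id: int, site: tuple[int, int]) -> None:
        if not self.in_bounds(site):
            raise IndexError(f"site {site} out of bounds")
        if self.occupancy[site] != EMPTY:
            raise ValueError(f"site {site} already occupied")
        self.occupancy[site] = agent_id

    def remove(self, site: tuple[int, int]) -> int:
        aid = self.occupancy[site]
        if aid == EMPTY:
            raise ValueError(f"site {site} is empty")
        self.occupancy[site] = EMPTY
        return int(aid)

    def empty_sites(self) -> list[tuple[int, int]]:
        """All unoccupied sites in row-major order."""
        rows, cols = np.nonzero(self.occupancy == EMPTY)
        return list(zip(rows.tolist(), cols.tolist()))

    def n_empty(self) -> int:
        return int(np.count_nonzero(self.occupancy == EMPTY))

    def neighbor_sites(
        self, site: tuple[int, int], kind: Neighborhood = Neighborhood.MOORE_8
    ) -> list[tuple[int, int]]:
        """In-bounds neighbor sites; boundary sites get truncated lists."""
        if not self.in_bounds(site):
            raise IndexError(f"site {site} out of bounds")
        r, c = site
        out = []
        for dr, dc in kind.offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < self.height and 0 <= cc < self.width:
                out.append((rr, cc))
        return out

    def occupied_neighbors(
        self, site: tuple[int, int], kind: Neighborhood = Neighborhood.MOORE_8
    ) -> list[tuple[tuple[int, int], int]]:
        """(site, agent_id) pairs for occupied in-bounds neighbors."""
        out = []
        for s in self.neighbor_sites(site, kind):
            aid = self.occupancy[s]
            if aid != EMPTY:
                out.append((s, int(aid)))
        return out

    def empty_neighbors(
        self, site: tuple[int, int], kind: Neighborhood = Neighborhood.MOORE_8
    ) -> list[tuple[int, int]]:
        return [s for s in self.neighbor_sites(site, kind) if self.occupancy[s] == EMPTY]

    def move_agent(
        self,
        agent_id: int,
        src: tuple[int, int],
        dst: tuple[int, int],
        kind: Neighborhood = Neighborhood.MOORE_8,
    ) -> bool:
        """Move ``agent_id`` from ``src`` to an adjacent empty ``dst``.

        Returns True on success.  An occupied destination refuses the move
        and leaves the lattice unchanged (contention, not failure).  A stale
        ``src`` or a non-adjacent ``dst`` signals a caller bug.
        """
        if self.occupancy[src] != agent_id:
            raise ValueError(f"agent {agent_id} does not occupy {src}")
        if dst not in self.neighbor_sites(src, kind):
            raise ValueError(f"{dst} is not adjacent to {src}")
        if self.occupancy[dst] != EMPTY:
            return False
        self.occupancy[src] = EMPTY
        self.occupancy[dst] = agent_id
        return True

    def iter_occupied(self) -> Iterator[tuple[tuple[int, int], int]]:
        rows, cols = np.nonzero(self.occupancy != EMPTY)
        for r, c in zip(rows.tolist(), cols.tolist()):
            yield (r, c), int(self.occupancy[r, c])

    def audit(self, agent_positions: dict[int, tuple[int, int]]) -> None:
        """Assert the occupancy <-> agent-position bijection.

        ``agent_positions`` maps live agent ids to their stored positions.
        Raises AssertionError on any mismatch; used as an integrity check
        after every engine step in tests.
        """
        occupied = {site: aid for site, aid in self.iter_occupied()}
        assert len(occupied) == len(agent_positions), (
            f"{len(occupied)} occupied sites vs {len(agent_positions)} live agents"
        )
        for aid, pos in agent_positions.items():
            got = occupied.get(tuple(pos))
            assert got == aid, f"agent {aid} at {pos} but lattice holds {got}"
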