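"""Map geometry for Kohonen self-organizing maps.

A map is a K-row by J-column lattice of nodes. Nodes carry a linear index
``n = k * J + j`` with ``k`` counted from the *bottom* row, so the map is read
left to right and bottom to top: linear index 0 (node 1 in one-based reports)
is the bottom-left node and index K*J - 1 the top-right one. All neighbourhood
arithmetic is Euclidean on node coordinates; the hexagonal topology offsets
odd rows by half a column width and compresses row spacing by sqrt(3)/2 so
that each interior node has six unit-distance neighbours.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidConfigError

_TOPOLOGIES = ("rectangular", "hexagonal")

# adjacency = unit grid distance; the slack only absorbs float rounding
_ADJACENCY_TOL = 1e-9


class SOMGrid:
    """Geometry of a K x J self-organizing map.

    Parameters
    ----------
    n_rows, n_cols : int
        Lattice dimensions (K rows, J columns), both >= 1.
    topology : {"rectangular", "hexagonal"}
        Node layout. "linear" maps are not supported; use a 1 x J rectangle.
    """

    def __init__(self, n_rows: int, n_cols: int, topology: str = "rectangular"):
        if n_rows < 1 or n_cols < 1:
            raise InvalidConfigError(
                f"grid dimensions must be >= 1, got {n_rows} x {n_cols}"
            )
        if topology == "linear":
            raise InvalidConfigError(
                "linear topology is recognised but not implemented; "
                "use a 1-row rectangular grid instead"
            )
        if topology not in _TOPOLOGIES:
            raise InvalidConfigError(f"unknown topology {topology!r}")
        self.n_rows = int(n_rows)
        self.n_cols = int(n_cols)
        self.topology = topology
        self.coords = self._node_coordinates()
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        self._sq_distances = np.einsum("ijk,ijk->ij", diff, diff)

    @property
    def n_nodes(self) -> int:
        return self.n_rows * self.n_cols

    def _node_coordinates(self) -> np.ndarray:
        k, j = np.divmod(np.arange(self.n_nodes), self.n_cols)
        x = j.astype(float)
        y = k.astype(float)
        if self.topology == "hexagonal":
            x = x + 0.5 * (k % 2)
            y = y * (np.sqrt(3.0) / 2.0)
        return np.column_stack([x, y])

    def linear_index(self, row: int, col: int) -> int:
        """Linear index of node (row, col); row 0 is the bottom row."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"node ({row}, {col}) outside {self.n_rows} x {self.n_cols} grid")
        return row * self.n_cols + col

    def node_position(self, index: int) -> tuple[int, int]:
        """(row, col) of a linear index, row 0 = bottom."""
        if not 0 <= index < self.n_nodes:
            raise IndexError(f"linear index {index} outside map of {self.n_nodes} nodes")
        return divmod(index, self.n_cols)

    def grid_distance(self, a: int, b: int) -> float:
        """Euclidean distance between two nodes in grid units."""
        return float(np.sqrt(self._sq_distances[a, b]))

    def squared_distances_from(self, index: int) -> np.ndarray:
        """Squared grid distances from one node to every node (read-only view)."""
        return self._sq_distances[index]

    def are_adjacent(self, a: int, b: int) -> bool:
        """Direct lattice neighbours: unit grid distance (4-neighbourhood on a
        rectangle, 6-neighbourhood on a hexagonal layout)."""
        return a != b and self._sq_distances[a, b] <= 1.0 + _ADJACENCY_TOL

    def neighbours(self, index: int) -> np.ndarray:
        """Linear indices of the direct lattice neighbours of a node."""
        d2 = self._sq_distances[index]
        mask = (d2 <= 1.0 + _ADJACENCY_TOL) & (np.arange(self.n_nodes) != index)
        return np.flatnonzero(mask)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SOMGrid({self.n_rows} x {self.n_cols}, {self.topology})"
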