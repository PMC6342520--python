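"""Bounded hexagonal lattice for multicellular signalling models.

Cells sit on a hexagonal grid truncated to a disc (all cells within a given
hex distance of the centre).  The lattice has *fixed*, non-periodic
boundaries: cells on the rim simply have fewer than six neighbours, mirroring
the physical edge of a micropatterned cell island.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["HexLattice", "build_disc_hex_lattice", "neighbor_mean"]

logger = logging.getLogger(__name__)

# Axial-coordinate displacements of the six hex neighbours.
_HEX_DIRECTIONS = ((1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1))


@dataclass
class HexLattice:
    """A disc-shaped patch of hexagonally packed cells.

    Attributes
    ----------
    positions
        ``(n_cells, 2)`` Cartesian coordinates at unit spacing.
    adjacency
        Per-cell tuple of neighbour indices (symmetric; interior cells have
        six, rim cells fewer).
    is_boundary
        True for cells with fewer than six neighbours.
    radius_norm
        Dimensionless radial coordinate in ``[0, 1]``: Euclidean distance to
        the lattice centroid divided by the largest such distance.
    """

    positions: np.ndarray
    adjacency: tuple[tuple[int, ...], ...]
    is_boundary: np.ndarray = field(init=False)
    radius_norm: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        n = self.positions.shape[0]
        if len(self.adjacency) != n:
            raise ValueError("adjacency length must match number of cells")
        for i, nbrs in enumerate(self.adjacency):
            for j in nbrs:
                if i not in self.adjacency[j]:
                    raise ValueError(f"adjacency not symmetric at pair ({i}, {j})")
        self.is_boundary = np.array([len(a) < 6 for a in self.adjacency])
        centroid = self.positions.mean(axis=0)
        dist = np.linalg.norm(self.positions - centroid, axis=1)
        dmax = dist.max()
        self.radius_norm = dist / dmax if dmax > 0 else np.zeros(n)

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(a) for a in self.adjacency])


def build_disc_hex_lattice(n_rings: int) -> HexLattice:
    """Build the disc of hexagonal-grid cells within ``n_rings`` of the centre.

    ``n_rings = 0`` gives a single cell; ``n_rings = k`` gives ``1 + 3k(k+1)``
    cells.  Adjacency is built at unit spacing with fixed (truncated)
    boundaries.
    """
    n_rings = int(n_rings)
    if n_rings < 0:
        raise ValueError(f"n_rings must be non-negative, got {n_rings}")

    # Enumerate axial coordinates (q, r) with hex distance <= n_rings.
    coords: list[tuple[int, int]] = []
    for q in range(-n_rings, n_rings + 1):
        for r in range(max(-n_rings, -q - n_rings), min(n_rings, -q + n_rings) + 1):
            coords.append((q, r))
    index = {c: i for i, c in enumerate(coords)}

    positions = np.array(
        [(q + 0.5 * r, (np.sqrt(3) / 2.0) * r) for q, r in coords], dtype=float
    )
    adjacency = tuple(
        tuple(index[(q + dq, r + dr)] for dq, dr in _HEX_DIRECTIONS if (q + dq, r + dr) in index)
        for q, r in coords
    )
    return HexLattice(positions=positions, adjacency=adjacency)


def neighbor_mean(values: np.ndarray, lattice: HexLattice, divisor: str = "realized") -> np.ndarray:
    """Mean of ``values`` over each cell's actual neighbours, ⟨X⟩_i.

    Parameters
    ----------
    values
        Per-cell vector, length ``lattice.n_cells``.
    divisor
        ``"realized"`` divides by the realised neighbour count (rim cells
        average over their existing <6 neighbours); ``"fixed6"`` always
        divides by six, equivalent to padding the rim with phantom neighbours
        carrying zero ligand.

    An isolated cell (no neighbours) gets ⟨X⟩ = 0 by convention.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (lattice.n_cells,):
        raise ValueError(
            f"values has length {values.size}, lattice has {lattice.n_cells} cells"
        )
    if divisor not in ("realized", "fixed6"):
        raise ValueError("divisor must be 'realized' or 'fixed6'")
    out = np.zeros(lattice.n_cells)
    for i, nbrs in enumerate(lattice.adjacency):
        if not nbrs:
            logger.warning("cell %d has no neighbours; neighbor mean set to 0", i)
            continue
        total = values[list(nbrs)].sum()
        out[i] = total / (6.0 if divisor == "fixed6" else len(nbrs))
    return out
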