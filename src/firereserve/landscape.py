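"""Lattice landscapes: square focal grids with buffer rings and hexagonal lattices.

Two concrete landscape types are provided:

* :class:`GridLandscape` — a ``rows x cols`` focal grid surrounded by an
  optional buffer ring.  Fires spread by first-order queen contiguity;
  only focal parcels may be selected for a reserve, but fires may ignite
  anywhere in the represented lattice (focal plus buffer).
* :class:`HexLandscape` — a rhombus of axial hexagon cells (or an explicit
  adjacency list for real tessellations).  Every parcel is focal and an
  eligible ignition point; fires spread to the (up to) six edge neighbours.

Parcel identifiers are 1-based.  Focal parcels of a grid are numbered
row-major (left to right, top to bottom) ``1..J``; buffer parcels receive
identifiers ``J+1..`` in row-major order over the full lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Set, Tuple

__all__ = [
    "GridLandscape",
    "HexLandscape",
    "build_square_landscape",
    "build_hex_landscape",
    "queen_neighbors",
    "shared_borders",
]

# Axial hex directions: six edge neighbours of cell (q, r).
_HEX_DIRECTIONS: Tuple[Tuple[int, int], ...] = (
    (1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1),
)


class LandscapeError(ValueError):
    """Invalid landscape construction or parcel lookup."""


@dataclass(frozen=True)
class GridLandscape:
    """Square focal grid with a buffer ring, queen-contiguity fire spread.

    Attributes
    ----------
    rows, cols : int
        Dimensions of the focal grid; ``J = rows * cols``.
    buffer_width : int
        Number of buffer rings around the focal grid.  Buffer parcels can
        ignite and carry fire into the focal grid but cannot be reserved.
    """

    rows: int
    cols: int
    buffer_width: int
    # internal: parcel id -> (row, col) over the full lattice, 0-based
    _coords: Mapping[int, Tuple[int, int]] = field(repr=False)
    _ids: Mapping[Tuple[int, int], int] = field(repr=False)

    @property
    def n_focal(self) -> int:
        return self.rows * self.cols

    @property
    def focal_ids(self) -> range:
        """Focal parcel identifiers ``1..J`` (row-major)."""
        return range(1, self.n_focal + 1)

    @property
    def ignition_ids(self) -> range:
        """All parcels (focal plus buffer) from which a fire may ignite."""
        return range(1, len(self._coords) + 1)

    def is_focal(self, parcel: int) -> bool:
        return 1 <= parcel <= self.n_focal

    def coord(self, parcel: int) -> Tuple[int, int]:
        try:
            return self._coords[parcel]
        except KeyError:
            raise LandscapeError(f"unknown parcel id {parcel}") from None

    def spread_neighbors(self, parcel: int) -> FrozenSet[int]:
        """Queen (Chebyshev distance 1) neighbours within the lattice."""
        r, c = self.coord(parcel)
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nb = self._ids.get((r + dr, c + dc))
                if nb is not None:
                    out.append(nb)
        return frozenset(out)

    def border_neighbors(self, parcel: int) -> FrozenSet[int]:
        """Rook (edge-sharing) neighbours — used for shared-border counts."""
        r, c = self.coord(parcel)
        out = []
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = self._ids.get((r + dr, c + dc))
            if nb is not None:
                out.append(nb)
        return frozenset(out)

    def chebyshev_distance(self, a: int, b: int) -> int:
        (ra, ca), (rb, cb) = self.coord(a), self.coord(b)
        return max(abs(ra - rb), abs(ca - cb))


@dataclass(frozen=True)
class HexLandscape:
    """Hexagonal lattice; every parcel is focal and an ignition candidate."""

    n_parcels: int
    _adjacency: Mapping[int, FrozenSet[int]] = field(repr=False)
    _coords: Mapping[int, Tuple[int, int]] | None = field(default=None, repr=False)

    @property
    def n_focal(self) -> int:
        return self.n_parcels

    @property
    def focal_ids(self) -> range:
        return range(1, self.n_parcels + 1)

    @property
    def ignition_ids(self) -> range:
        return self.focal_ids

    def is_focal(self, parcel: int) -> bool:
        return 1 <= parcel <= self.n_parcels

    def spread_neighbors(self, parcel: int) -> FrozenSet[int]:
        try:
            return self._adjacency[parcel]
        except KeyError:
            raise LandscapeError(f"unknown parcel id {parcel}") from None

    # On hex lattices border adjacency and spread adjacency coincide.
    border_neighbors = spread_neighbors


def build_square_landscape(rows: int, cols: int, buffer_width: int = 1) -> GridLandscape:
    """Build a focal ``rows x cols`` grid wrapped in ``buffer_width`` buffer rings.

    Focal parcels are numbered ``1..rows*cols`` row-major over the focal
    region; buffer parcels continue the numbering row-major over the full
    lattice.  The default 5x5 grid with a one-parcel buffer has 25 focal
    parcels and 49 ignition parcels.
    """
    if rows < 1 or cols < 1:
        raise LandscapeError(f"grid dimensions must be positive, got {rows}x{cols}")
    if buffer_width < 0:
        raise LandscapeError(f"buffer_width must be >= 0, got {buffer_width}")

    full_rows = rows + 2 * buffer_width
    full_cols = cols + 2 * buffer_width
    coords: Dict[int, Tuple[int, int]] = {}
    ids: Dict[Tuple[int, int], int] = {}

    def in_focal(r: int, c: int) -> bool:
        return (buffer_width <= r < buffer_width + rows
                and buffer_width <= c < buffer_width + cols)

    next_id = 1
    for r in range(full_rows):  # focal first: ids 1..J row-major
        for c in range(full_cols):
            if in_focal(r, c):
                coords[next_id] = (r, c)
                ids[(r, c)] = next_id
                next_id += 1
    for r in range(full_rows):
        for c in range(full_cols):
            if not in_focal(r, c):
                coords[next_id] = (r, c)
                ids[(r, c)] = next_id
                next_id += 1

    return GridLandscape(rows=rows, cols=cols, buffer_width=buffer_width,
                         _coords=coords, _ids=ids)


def build_hex_landscape(n_rows: int, n_cols: int) -> HexLandscape:
    """Build a rhombus of axial hex cells, numbered row-major ``1..n_rows*n_cols``.

    A 17x17 rhombus gives the default 289-parcel landscape.  Interior
    parcels have six neighbours; boundary parcels have between two and
    five.
    """
    if n_rows < 1 or n_cols < 1:
        raise LandscapeError(f"hex dimensions must be positive, got {n_rows}x{n_cols}")
    coords: Dict[int, Tuple[int, int]] = {}
    ids: Dict[Tuple[int, int], int] = {}
    next_id = 1
    for r in range(n_rows):
        for q in range(n_cols):
            coords[next_id] = (q, r)
            ids[(q, r)] = next_id
            next_id += 1
    adjacency: Dict[int, FrozenSet[int]] = {}
    for pid, (q, r) in coords.items():
        nbs = [ids[(q + dq, r + dr)]
               for dq, dr in _HEX_DIRECTIONS if (q + dq, r + dr) in ids]
        adjacency[pid] = frozenset(nbs)
    return HexLandscape(n_parcels=n_rows * n_cols, _adjacency=adjacency, _coords=coords)


def hex_landscape_from_adjacency(n_parcels: int,
                                 edges: Iterable[Tuple[int, int]]) -> HexLandscape:
    """Build a hex-style landscape from an explicit edge list (real tessellations).

    Edges are unordered pairs of 1-based parcel ids; the relation is
    symmetrised.  Parcels may have at most six neighbours.
    """
    if n_parcels < 1:
        raise LandscapeError("n_parcels must be positive")
    adj: Dict[int, Set[int]] = {p: set() for p in range(1, n_parcels + 1)}
    for a, b in edges:
        if a == b:
            raise LandscapeError(f"self-adjacency on parcel {a}")
        if not (1 <= a <= n_parcels and 1 <= b <= n_parcels):
            raise LandscapeError(f"edge ({a},{b}) references an unknown parcel")
        adj[a].add(b)
        adj[b].add(a)
    for p, nbs in adj.items():
        if len(nbs) > 6:
            raise LandscapeError(f"parcel {p} has {len(nbs)} neighbours (max 6)")
    return HexLandscape(n_parcels=n_parcels,
                        _adjacency={p: frozenset(nbs) for p, nbs in adj.items()})


def queen_neighbors(landscape: GridLandscape, parcel: int) -> FrozenSet[int]:
    """All parcels at Chebyshev distance 1 of ``parcel`` within the lattice."""
    return landscape.spread_neighbors(parcel)


def shared_borders(landscape, reserve: Iterable[int]) -> int:
    """Number of unordered edge-adjacent parcel pairs within a reserve.

    Edge adjacency is rook adjacency on square grids and the six-neighbour
    relation on hex lattices; it measures reserve agglomeration, distinct
    from the queen contiguity used for fire spread.
    """
    parcels = sorted(set(reserve))
    for p in parcels:
        if not landscape.is_focal(p):
            raise LandscapeError(f"parcel {p} is not a focal parcel")
    count = 0
    pset = set(parcels)
    for p in parcels:
        count += sum(1 for nb in landscape.border_neighbors(p) if nb in pset and nb > p)
    return count
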