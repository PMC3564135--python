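"""Area adjacency lattices for conditional-autoregressive spatial models.

An :class:`AreaLattice` records, for each of ``n_areas`` small areas, the
indices of its contiguity neighbours.  It is the structure underpinning the
intrinsic CAR (ICAR) prior, in which the spatial effect of an area is
normally distributed around the mean of its neighbours' effects.  Lattices
can be built synthetically on a regular grid, or read from the plain-text
adjacency-list format used throughout applied disease mapping.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "AreaLattice",
    "LatticeError",
    "GraphParseError",
    "make_grid_lattice",
    "read_graph",
    "write_graph",
]


class LatticeError(ValueError):
    """Raised when an adjacency structure violates a lattice invariant."""


class GraphParseError(ValueError):
    """Raised when a graph file is malformed; names the offending line."""


@dataclass(frozen=True)
class AreaLattice:
    """Symmetric, loop-free adjacency over ``n_areas`` small areas.

    Parameters
    ----------
    n_areas
        Number of areas (> 0).
    neighbors
        Per-area tuples of 0-based neighbour indices.
    area_ids
        Per-area string labels; defaults to ``area_0001`` style ids.
    """

    n_areas: int
    neighbors: tuple[tuple[int, ...], ...]
    area_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_areas <= 0:
            raise LatticeError("n_areas must be positive")
        if len(self.neighbors) != self.n_areas:
            raise LatticeError(
                f"{len(self.neighbors)} neighbor lists for {self.n_areas} areas"
            )
        if not self.area_ids:
            width = len(str(self.n_areas))
            object.__setattr__(
                self,
                "area_ids",
                tuple(f"area_{i + 1:0{width}d}" for i in range(self.n_areas)),
            )
        elif len(self.area_ids) != self.n_areas:
            raise LatticeError("area_ids length must equal n_areas")
        self._validate()

    def _validate(self) -> None:
        seen = [set(nb) for nb in self.neighbors]
        for i, nb in enumerate(self.neighbors):
            if len(nb) == 0:
                raise LatticeError(
                    f"area {i} has no neighbours; islands are not supported "
                    "by the ICAR prior (link or remove them explicitly)"
                )
            if len(seen[i]) != len(nb):
                raise LatticeError(f"area {i} has duplicate neighbour entries")
            if i in seen[i]:
                raise LatticeError(f"area {i} lists itself as a neighbour")
            for j in nb:
                if not 0 <= j < self.n_areas:
                    raise LatticeError(f"area {i} lists out-of-range neighbour {j}")
                if i not in seen[j]:
                    raise LatticeError(
                        f"asymmetric adjacency: {i} lists {j} but {j} omits {i}"
                    )

    # -- derived structure -------------------------------------------------

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self.neighbors) // 2

    def degrees(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=np.int64)

    def adjacency_matrix(self) -> sp.csr_matrix:
        """Sparse 0/1 adjacency matrix (symmetric, zero diagonal)."""
        indptr = np.zeros(self.n_areas + 1, dtype=np.int64)
        indices = []
        for i, nb in enumerate(self.neighbors):
            indptr[i + 1] = indptr[i] + len(nb)
            indices.extend(sorted(nb))
        data = np.ones(len(indices), dtype=np.float64)
        return sp.csr_matrix(
            (data, np.array(indices, dtype=np.int64), indptr),
            shape=(self.n_areas, self.n_areas),
        )

    def is_connected(self) -> bool:
        """Breadth-first reachability of every area from area 0."""
        seen = np.zeros(self.n_areas, dtype=bool)
        queue: deque[int] = deque([0])
        seen[0] = True
        while queue:
            i = queue.popleft()
            for j in self.neighbors[i]:
                if not seen[j]:
                    seen[j] = True
                    queue.append(j)
        return bool(seen.all())

    def coloring(self) -> np.ndarray:
        """Greedy proper vertex colouring.

        Areas sharing a colour are mutually non-adjacent, so their ICAR
        full conditionals are independent given the rest of the field —
        the basis for blocked single-site MCMC updates.
        """
        colors = np.full(self.n_areas, -1, dtype=np.int64)
        for i in range(self.n_areas):
            used = {colors[j] for j in self.neighbors[i] if colors[j] >= 0}
            c = 0
            while c in used:
                c += 1
            colors[i] = c
        return colors

    def subset(self, keep: Sequence[int] | np.ndarray) -> "AreaLattice":
        """Induced sub-lattice on ``keep`` (0-based original indices).

        Raises :class:`LatticeError` if the subset creates an island.
        """
        keep_idx = np.asarray(keep, dtype=np.int64)
        remap = {int(old): new for new, old in enumerate(keep_idx)}
        nbs = tuple(
            tuple(sorted(remap[j] for j in self.neighbors[int(old)] if int(j) in remap))
            for old in keep_idx
        )
        ids = tuple(self.area_ids[int(old)] for old in keep_idx)
        return AreaLattice(len(keep_idx), nbs, ids)


def make_grid_lattice(
    n_rows: int, n_cols: int, contiguity: str = "rook"
) -> AreaLattice:
    """Regular-grid lattice as a synthetic stand-in for areal contiguity.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; ``n_rows * n_cols >= 2``.
    contiguity
        ``"rook"`` (edge-sharing, 4 interior neighbours) or ``"queen"``
        (edge- or corner-sharing, 8 interior neighbours).
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("grid dimensions must be positive")
    if n_rows * n_cols < 2:
        raise ValueError("lattice needs at least 2 areas")
    if contiguity not in ("rook", "queen"):
        raise ValueError(f"contiguity must be 'rook' or 'queen', got {contiguity!r}")
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if contiguity == "queen":
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    nbs = []
    for r in range(n_rows):
        for c in range(n_cols):
            cell = []
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    cell.append(rr * n_cols + cc)
            nbs.append(tuple(sorted(cell)))
    return AreaLattice(n_rows * n_cols, tuple(nbs))


def write_graph(lattice: AreaLattice, path: str | Path) -> None:
    """Write the plain-text adjacency file (1-based indices).

    Line 1 holds ``n_areas``; each following line is
    ``<area> <n_neighbours> <neighbour_1> ... <neighbour_k>``.
    """
    lines = [str(lattice.n_areas)]
    for i, nb in enumerate(lattice.neighbors):
        parts = [str(i + 1), str(len(nb))] + [str(j + 1) for j in sorted(nb)]
        lines.append(" ".join(parts))
    Path(path).write_text("\n".join(lines) + "\n")


def read_graph(path: str | Path) -> AreaLattice:
    """Read an adjacency file written by :func:`write_graph`."""
    raw = Path(path).read_text().splitlines()
    lines = [(no, ln) for no, ln in enumerate(raw, start=1) if ln.strip()]
    if not lines:
        raise GraphParseError(f"{path}: empty graph file")
    try:
        n_areas = int(lines[0][1].split()[0])
    except ValueError as exc:
        raise GraphParseError(f"{path}:1: cannot parse area count") from exc
    if n_areas <= 0:
        raise GraphParseError(f"{path}:1: non-positive area count {n_areas}")
    if len(lines) - 1 != n_areas:
        raise GraphParseError(
            f"{path}: expected {n_areas} adjacency lines, found {len(lines) - 1}"
        )
    nbs: list[tuple[int, ...]] = [()] * n_areas
    seen = np.zeros(n_areas, dtype=bool)
    for no, ln in lines[1:]:
        try:
            fields = [int(tok) for tok in ln.split()]
        except ValueError as exc:
            raise GraphParseError(f"{path}:{no}: non-integer token") from exc
        if len(fields) < 2:
            raise GraphParseError(f"{path}:{no}: too few fields")
        area, k, rest = fields[0], fields[1], fields[2:]
        if not 1 <= area <= n_areas:
            raise GraphParseError(f"{path}:{no}: area index {area} out of range")
        if seen[area - 1]:
            raise GraphParseError(f"{path}:{no}: duplicate line for area {area}")
        if len(rest) != k:
            raise GraphParseError(
                f"{path}:{no}: declared {k} neighbours, listed {len(rest)}"
            )
        for j in rest:
            if not 1 <= j <= n_areas:
                raise GraphParseError(
                    f"{path}:{no}: neighbour index {j} out of range for "
                    f"{n_areas} areas"
                )
        seen[area - 1] = True
        nbs[area - 1] = tuple(sorted(j - 1 for j in rest))
    try:
        return AreaLattice(n_areas, tuple(nbs))
    except LatticeError as exc:
        raise GraphParseError(f"{path}: {exc}") from exc
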