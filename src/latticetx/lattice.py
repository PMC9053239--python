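"""The occupancy lattice and its seeding routines.

Cells live on an ``l x l`` grid with single occupancy and no-flux boundaries
(edge sites simply have fewer von Neumann neighbours).  Three initial
configurations are supported: uniform random seeding, rectangular resistant
nests with sensitive cells scattered around them, and a densely packed central
disk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .params import ParameterError, SimParams

EMPTY = 0
SENSITIVE = 1
RESISTANT = 2


class GeometryError(ValueError):
    """Raised when requested nests do not fit or overlap."""


class Lattice:
    """An ``l x l`` occupancy grid over {empty, sensitive, resistant}.

    Counts ``S``, ``R`` and ``N = S + R`` are cached and kept in sync by the
    stepping code; :meth:`recount` re-derives them from the grid.
    """

    __slots__ = ("grid", "S", "R")

    def __init__(self, grid: np.ndarray):
        grid = np.ascontiguousarray(grid, dtype=np.int8)
        if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
            raise ValueError("grid must be a square 2-D array")
        self.grid = grid
        self.recount()

    @property
    def l(self) -> int:
        return self.grid.shape[0]

    @property
    def N(self) -> int:
        return self.S + self.R

    def recount(self) -> None:
        self.S = int(np.count_nonzero(self.grid == SENSITIVE))
        self.R = int(np.count_nonzero(self.grid == RESISTANT))

    def copy(self) -> "Lattice":
        return Lattice(self.grid.copy())

    def __eq__(self, other) -> bool:
        return isinstance(other, Lattice) and np.array_equal(self.grid, other.grid)


@dataclass(frozen=True)
class Nest:
    """A rectangular resistant nest: ``height x width`` sites, anchored by the
    offset of its top-left corner from the domain centre ``((l-1)/2, (l-1)/2)``.
    Offsets are in lattice sites and may be fractional halves on even grids."""

    height: int
    width: int
    row_offset: float = 0.0
    col_offset: float = 0.0


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def seed_random(params: SimParams, rng) -> Lattice:
    """Spread ``N0`` cells uniformly at random, ``R0`` of them resistant."""
    rng = _as_rng(rng)
    n_sites = params.l * params.l
    n0, r0 = params.N0, params.R0
    if n0 > n_sites:
        raise ParameterError("initial density exceeds the lattice size")
    flat = rng.choice(n_sites, size=n0, replace=False)
    grid = np.zeros(n_sites, dtype=np.int8)
    grid[flat] = SENSITIVE
    if r0 > 0:
        grid[rng.choice(flat, size=r0, replace=False)] = RESISTANT
    return Lattice(grid.reshape(params.l, params.l))


def _nest_slices(nest: Nest, l: int) -> tuple[slice, slice]:
    centre = (l - 1) / 2.0
    r0 = int(round(centre - nest.height / 2.0 + 0.5 + nest.row_offset))
    c0 = int(round(centre - nest.width / 2.0 + 0.5 + nest.col_offset))
    if r0 < 0 or c0 < 0 or r0 + nest.height > l or c0 + nest.width > l:
        raise GeometryError(f"nest {nest} does not fit in an {l}x{l} domain")
    return slice(r0, r0 + nest.height), slice(c0, c0 + nest.width)


def seed_nests(params: SimParams, nests: Sequence[Nest], rng) -> Lattice:
    """Place resistant cells as the given rectangles; scatter sensitive cells
    uniformly over the remaining sites so the total density is ``n0``."""
    rng = _as_rng(rng)
    l = params.l
    grid = np.zeros((l, l), dtype=np.int8)
    n_resistant = 0
    for nest in nests:
        rows, cols = _nest_slices(nest, l)
        if np.any(grid[rows, cols] != EMPTY):
            raise GeometryError(f"nest {nest} overlaps a previously placed nest")
        grid[rows, cols] = RESISTANT
        n_resistant += nest.height * nest.width
    n_sensitive = params.N0 - n_resistant
    if n_sensitive < 0:
        raise GeometryError("nests hold more cells than the requested density")
    empty_flat = np.flatnonzero(grid == EMPTY)
    chosen = rng.choice(empty_flat, size=n_sensitive, replace=False)
    grid.flat[chosen] = SENSITIVE
    return Lattice(grid)


def two_nests(separation: int, height: int = 2, width: int = 2) -> list[Nest]:
    """Two equal nests placed symmetrically about the centre with the given
    edge-to-edge gap (in sites) along the horizontal axis.  ``separation=0``
    reproduces the single ``height x (2*width)`` block."""
    if separation < 0:
        raise GeometryError("separation must be >= 0")
    total = 2 * width + separation
    # left nest's left edge sits total/2 columns left of centre
    left = Nest(height, width, 0.0, -total / 2.0 + width / 2.0)
    right = Nest(height, width, 0.0, total / 2.0 - width / 2.0)
    return [left, right]


def seed_disk(params: SimParams, rng) -> Lattice:
    """Occupy the ``N0`` sites closest to the domain centre (Euclidean
    distance, ties broken lexicographically); ``R0`` of them resistant,
    assigned uniformly at random within the disk."""
    rng = _as_rng(rng)
    l = params.l
    n0, r0 = params.N0, params.R0
    centre = (l - 1) / 2.0
    rr, cc = np.mgrid[0:l, 0:l]
    d2 = (rr - centre) ** 2 + (cc - centre) ** 2
    order = np.lexsort((cc.ravel(), rr.ravel(), d2.ravel()))
    chosen = order[:n0]
    grid = np.zeros(l * l, dtype=np.int8)
    grid[chosen] = SENSITIVE
    if r0 > 0:
        grid[rng.choice(chosen, size=r0, replace=False)] = RESISTANT
    return Lattice(grid.reshape(l, l))
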