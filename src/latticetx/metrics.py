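"""Competition instruments for the lattice model.

These quantify how crowding suppresses growth: the fraction of division
attempts blocked for want of space, the composition of resistant cells'
von Neumann neighbourhoods, per-capita net growth rates, and the geometry
(count, size, convexity) of 4-connected resistant nests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint
from skimage.measure import label

from .lattice import RESISTANT, SENSITIVE, Lattice
from .simulate import TimeSeries


@dataclass(frozen=True)
class NeighbourhoodComposition:
    """Mean fractions of sensitive / resistant / empty sites in resistant
    cells' von Neumann neighbourhoods (boundary-truncated neighbourhoods are
    normalised by their actual size, so the three fractions sum to 1)."""

    mean_frac_S: float
    mean_frac_R: float
    mean_frac_empty: float


@dataclass(frozen=True)
class NestSummary:
    """4-connected resistant components: count, areas, and per-component
    convexity = component area / convex-hull area of its unit-square union."""

    n_nests: int
    sizes: np.ndarray
    convexities: np.ndarray


def blocked_fraction(series: TimeSeries, population: str = "R", window: int = 1) -> np.ndarray:
    """Trailing-window fraction of blocked division attempts.

    Element ``k`` is ``sum(blocked) / sum(attempts)`` over the ``window``
    most recent steps ending at record ``k``; NaN where no attempts occurred
    (and for the initial record, which has no step behind it).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if population not in ("S", "R"):
        raise ValueError("population must be 'S' or 'R'")
    attempts = np.asarray(series[f"attempts_{population}"], dtype=float)
    blocked = np.asarray(series[f"blocked_{population}"], dtype=float)
    ca = np.concatenate(([0.0], np.cumsum(attempts)))
    cb = np.concatenate(([0.0], np.cumsum(blocked)))
    n = attempts.size
    out = np.full(n, np.nan)
    for k in range(1, n):
        j = max(0, k - window)
        denom = ca[k + 1] - ca[j + 1]
        if denom > 0:
            out[k] = (cb[k + 1] - cb[j + 1]) / denom
    return out


def neighbourhood_composition(lattice: Lattice) -> NeighbourhoodComposition:
    """Average a resistant cell's neighbourhood composition over all
    resistant cells; NaN fractions when there are none."""
    grid = lattice.grid
    rows, cols = np.nonzero(grid == RESISTANT)
    if rows.size == 0:
        return NeighbourhoodComposition(np.nan, np.nan, np.nan)
    l = lattice.l
    frac_s = np.zeros(rows.size)
    frac_r = np.zeros(rows.size)
    frac_e = np.zeros(rows.size)
    for i, (r, c) in enumerate(zip(rows, cols)):
        ns = nr = ne = 0
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < l and 0 <= cc < l:
                v = grid[rr, cc]
                if v == SENSITIVE:
                    ns += 1
                elif v == RESISTANT:
                    nr += 1
                else:
                    ne += 1
        total = ns + nr + ne
        frac_s[i] = ns / total
        frac_r[i] = nr / total
        frac_e[i] = ne / total
    return NeighbourhoodComposition(
        float(frac_s.mean()), float(frac_r.mean()), float(frac_e.mean())
    )


def per_capita_growth(series: TimeSeries, population: str = "R", window: float = 10.0) -> np.ndarray:
    """Centred finite difference of log counts:
    ``(ln X(t + w/2) - ln X(t - w/2)) / w`` per day; NaN where either count is
    zero or the window leaves the series."""
    t = np.asarray(series["t"], dtype=float)
    x = np.asarray(series[population], dtype=float)
    if t.size < 2:
        return np.full(t.size, np.nan)
    dt = t[1] - t[0]
    half = int(round(window / 2.0 / dt))
    if half < 1:
        raise ValueError("window must span at least one step on each side")
    out = np.full(t.size, np.nan)
    for k in range(half, t.size - half):
        a, b = x[k - half], x[k + half]
        if a > 0 and b > 0:
            out[k] = (np.log(b) - np.log(a)) / (t[k + half] - t[k - half])
    return out


def nest_summary(lattice: Lattice) -> NestSummary:
    """Identify 4-connected resistant nests and score their convexity.

    Convexity of a component is its area (unit cells) divided by the area of
    the convex hull of the union of its unit squares, so rectangles score
    exactly 1 and ragged, branched nests score lower.
    """
    mask = lattice.grid == RESISTANT
    labels, n = label(mask, connectivity=1, return_num=True)
    sizes = np.zeros(n, dtype=int)
    convexities = np.zeros(n)
    for comp in range(1, n + 1):
        rows, cols = np.nonzero(labels == comp)
        sizes[comp - 1] = rows.size
        corners = np.empty((rows.size * 4, 2))
        for sign_r, sign_c, off in ((-0.5, -0.5, 0), (-0.5, 0.5, 1), (0.5, -0.5, 2), (0.5, 0.5, 3)):
            corners[off::4, 0] = rows + sign_r
            corners[off::4, 1] = cols + sign_c
        hull = MultiPoint(corners).convex_hull
        convexities[comp - 1] = rows.size / hull.area
    return NestSummary(n_nests=n, sizes=sizes, convexities=convexities)


def composition_series(series: TimeSeries):
    """Neighbourhood composition at every stored snapshot of a run, as a
    tidy table (t, mean_frac_S, mean_frac_R, mean_frac_empty)."""
    import pandas as pd

    rows = []
    for t, lat in series.snapshots:
        c = neighbourhood_composition(lat)
        rows.append({"t": t, "mean_frac_S": c.mean_frac_S,
                     "mean_frac_R": c.mean_frac_R, "mean_frac_empty": c.mean_frac_empty})
    return pd.DataFrame(rows)


def nest_summary_frame(lattice: Lattice):
    """Nest summary as a tidy table (component id, size, convexity)."""
    import pandas as pd

    s = nest_summary(lattice)
    return pd.DataFrame(
        {"component": np.arange(1, s.n_nests + 1), "size": s.sizes, "convexity": s.convexities}
    )
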