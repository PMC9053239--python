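"""Independent oracles for the stochastic update rule.

`enumerate_step` walks every processing order and event outcome of a single
lattice step on a tiny grid, returning the exact successor-state distribution
and the expected event tallies.  It is a direct transcription of the update
rule's probability tree, independent of the simulation kernel.
"""

from __future__ import annotations

from itertools import permutations
from math import factorial

import numpy as np

EMPTY, SENSITIVE, RESISTANT = 0, 1, 2

STAT_NAMES = (
    "attempts_S", "attempts_R", "blocked_S", "blocked_R",
    "drug_kills", "deaths_S", "deaths_R", "births_S", "births_R",
)


def _empty_neighbours(grid, r, c):
    l = grid.shape[0]
    out = []
    for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
        if 0 <= rr < l and 0 <= cc < l and grid[rr, cc] == EMPTY:
            out.append((rr, cc))
    return out


def enumerate_step(grid, p_death, p_div_s, p_div_r, p_kill):
    """Exact one-step successor distribution and expected tallies.

    Returns ``(dist, expected)`` where ``dist`` maps successor grid bytes to
    probability and ``expected`` maps tally names to expected values.
    """
    grid = np.asarray(grid, dtype=np.int8)
    cells = [tuple(x) for x in np.argwhere(grid != EMPTY)]
    dist: dict[bytes, float] = {}
    expected = {k: 0.0 for k in STAT_NAMES}
    n = len(cells)
    if n == 0:
        return {grid.tobytes(): 1.0}, expected
    perm_w = 1.0 / factorial(n)

    def visit(g, order, i, prob, tallies):
        if prob == 0.0:
            return
        if i == len(order):
            dist[g.tobytes()] = dist.get(g.tobytes(), 0.0) + prob
            for k, v in tallies.items():
                expected[k] += prob * v
            return
        r, c = order[i]
        cell = g[r, c]
        sfx = "S" if cell == SENSITIVE else "R"
        # death branch
        if p_death > 0:
            g2 = g.copy()
            g2[r, c] = EMPTY
            t2 = dict(tallies)
            t2[f"deaths_{sfx}"] += 1
            visit(g2, order, i + 1, prob * p_death, t2)
        p_div = p_div_s if cell == SENSITIVE else p_div_r
        stay = (1.0 - p_death) * (1.0 - p_div)
        if stay > 0:
            visit(g, order, i + 1, prob * stay, tallies)
        p_att = (1.0 - p_death) * p_div
        if p_att > 0:
            empties = _empty_neighbours(g, r, c)
            t_att = dict(tallies)
            t_att[f"attempts_{sfx}"] += 1
            if not empties:
                t2 = dict(t_att)
                t2[f"blocked_{sfx}"] += 1
                visit(g, order, i + 1, prob * p_att, t2)
            else:
                kill = p_kill if cell == SENSITIVE else 0.0
                if kill > 0:
                    g2 = g.copy()
                    g2[r, c] = EMPTY
                    t2 = dict(t_att)
                    t2["drug_kills"] += 1
                    visit(g2, order, i + 1, prob * p_att * kill, t2)
                p_place = p_att * (1.0 - kill) / len(empties)
                for rr, cc in empties:
                    g2 = g.copy()
                    g2[rr, cc] = cell
                    t2 = dict(t_att)
                    t2[f"births_{sfx}"] += 1
                    visit(g2, order, i + 1, prob * p_place, t2)

    zero = {k: 0 for k in STAT_NAMES}
    for order in permutations(cells):
        visit(grid.copy(), order, 0, perm_w, zero)
    return dist, expected
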