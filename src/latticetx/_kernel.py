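"""Numba kernel for the per-step lattice update.

The kernel is reseeded on every call, so a step is a pure function of
(grid, probabilities, seed): runs are bitwise reproducible and matched
continuous/adaptive pairs can share per-step seed streams.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# StepStats slot layout (see simulate.StepStats)
N_STATS = 9
(
    I_ATTEMPTS_S,
    I_ATTEMPTS_R,
    I_BLOCKED_S,
    I_BLOCKED_R,
    I_DRUG_KILLS,
    I_DEATHS_S,
    I_DEATHS_R,
    I_BIRTHS_S,
    I_BIRTHS_R,
) = range(N_STATS)


@njit(cache=False)
def step_kernel(grid, p_death, p_div_s, p_div_r, p_kill, seed):  # pragma: no cover
    """Advance the grid by one step in place; return the event tallies.

    Only cells occupying a site at the start of the step act, in a uniformly
    random order.  Each still-alive cell first faces background death
    (probability ``p_death``), else attempts division (``p_div_s`` or
    ``p_div_r``).  An attempt with no empty von Neumann neighbour is blocked;
    an unblocked sensitive attempt is killed by drug with probability
    ``p_kill``; otherwise a daughter of the same type fills a uniformly chosen
    empty neighbour site immediately.
    """
    np.random.seed(seed)
    l = grid.shape[0]
    stats = np.zeros(N_STATS, dtype=np.int64)

    n = 0
    rows = np.empty(l * l, dtype=np.int32)
    cols = np.empty(l * l, dtype=np.int32)
    for i in range(l):
        for j in range(l):
            if grid[i, j] != 0:
                rows[n] = i
                cols[n] = j
                n += 1

    order = np.arange(n)
    for i in range(n - 1, 0, -1):  # Fisher-Yates
        j = np.random.randint(0, i + 1)
        tmp = order[i]
        order[i] = order[j]
        order[j] = tmp

    er = np.empty(4, dtype=np.int32)
    ec = np.empty(4, dtype=np.int32)
    for k in range(n):
        r = rows[order[k]]
        c = cols[order[k]]
        cell = grid[r, c]
        if np.random.random() < p_death:
            grid[r, c] = 0
            if cell == 1:
                stats[I_DEATHS_S] += 1
            else:
                stats[I_DEATHS_R] += 1
            continue
        p_div = p_div_s if cell == 1 else p_div_r
        if np.random.random() >= p_div:
            continue
        if cell == 1:
            stats[I_ATTEMPTS_S] += 1
        else:
            stats[I_ATTEMPTS_R] += 1
        n_empty = 0
        if r > 0 and grid[r - 1, c] == 0:
            er[n_empty] = r - 1
            ec[n_empty] = c
            n_empty += 1
        if r < l - 1 and grid[r + 1, c] == 0:
            er[n_empty] = r + 1
            ec[n_empty] = c
            n_empty += 1
        if c > 0 and grid[r, c - 1] == 0:
            er[n_empty] = r
            ec[n_empty] = c - 1
            n_empty += 1
        if c < l - 1 and grid[r, c + 1] == 0:
            er[n_empty] = r
            ec[n_empty] = c + 1
            n_empty += 1
        if n_empty == 0:
            if cell == 1:
                stats[I_BLOCKED_S] += 1
            else:
                stats[I_BLOCKED_R] += 1
            continue
        if cell == 1 and np.random.random() < p_kill:
            grid[r, c] = 0
            stats[I_DRUG_KILLS] += 1
            continue
        pick = np.random.randint(0, n_empty)
        grid[er[pick], ec[pick]] = cell
        if cell == 1:
            stats[I_BIRTHS_S] += 1
        else:
            stats[I_BIRTHS_R] += 1
    return stats
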