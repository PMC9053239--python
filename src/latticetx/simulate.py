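"""Stochastic simulation driver: single steps and full treated runs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernel
from .lattice import Lattice
from .params import ParameterError, SimParams
from .treatment import ControllerState, Protocol, detect_progression, dose

TIMESERIES_COLUMNS = [
    "t",
    "S",
    "R",
    "N",
    "D",
    "attempts_S",
    "attempts_R",
    "blocked_S",
    "blocked_R",
    "drug_kills",
    "deaths_S",
    "deaths_R",
    "births_S",
    "births_R",
]


@dataclass(frozen=True)
class StepStats:
    """Event tallies of one lattice step.

    ``births_S = attempts_S - blocked_S - drug_kills`` and
    ``births_R = attempts_R - blocked_R`` hold by construction.
    """

    attempts_S: int = 0
    attempts_R: int = 0
    blocked_S: int = 0
    blocked_R: int = 0
    drug_kills: int = 0
    deaths_S: int = 0
    deaths_R: int = 0
    births_S: int = 0
    births_R: int = 0

    @classmethod
    def from_array(cls, a: np.ndarray) -> "StepStats":
        return cls(*(int(x) for x in a))


@dataclass(frozen=True)
class Outcome:
    """Run outcome: progression status, time to progression (days, only when
    progressed) and the number of completed adaptive-therapy cycles."""

    status: str  # progressed | cured | censored
    ttp: Optional[float]
    n_cycles: int = 0


class TimeSeries:
    """Per-step record of a run: time, counts, dose and event tallies.

    When the run was asked to keep snapshots, ``snapshots`` holds
    ``(t, Lattice)`` pairs at the sampling stride.
    """

    def __init__(self, data: dict[str, np.ndarray], snapshots=None):
        self._data = {k: np.asarray(v) for k, v in data.items()}
        self.snapshots: list = snapshots or []

    def __getitem__(self, key: str) -> np.ndarray:
        return self._data[key]

    def __len__(self) -> int:
        return len(self._data["t"])

    @property
    def columns(self) -> list[str]:
        return list(self._data)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self._data, columns=TIMESERIES_COLUMNS)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _drug_kill_prob(D: float, params: SimParams) -> float:
    if not 0.0 <= D <= params.D_max:
        raise ParameterError(f"dose {D} outside [0, {params.D_max}]")
    return params.d_D * D / params.D_max


def step(lattice: Lattice, D: float, params: SimParams, rng) -> tuple[Lattice, StepStats]:
    """Advance the lattice by one time step ``dt`` at dose ``D`` (in place).

    ``rng`` is a :class:`numpy.random.Generator` (or a seed for one); one
    32-bit seed is drawn from it to drive the kernel.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    seed = int(rng.integers(0, 2**31))
    raw = _kernel.step_kernel(
        lattice.grid,
        params.delta_T * params.dt,
        params.r_S * params.dt,
        params.r_R * params.dt,
        _drug_kill_prob(D, params),
        seed,
    )
    stats = StepStats.from_array(raw)
    lattice.S += stats.births_S - stats.deaths_S - stats.drug_kills
    lattice.R += stats.births_R - stats.deaths_R
    return lattice, stats


def run_simulation(
    params: SimParams,
    protocol: Protocol,
    initial: Lattice,
    stop_on_progression: bool = True,
    snapshot_every: int | None = None,
) -> tuple[TimeSeries, Outcome]:
    """Run the lattice model under a dosing protocol.

    The controller is evaluated once per step from the current burden, then
    the lattice is advanced by ``dt``.  The run stops at progression
    (``N >= 1.2 * N0`` and ``t >= 150`` d), at cure (``N = 0``) or at
    ``t_end`` (censored).  Bitwise reproducible given
    ``(params.seed, protocol, initial)``.  With ``snapshot_every = k`` a copy
    of the lattice is kept every ``k`` steps (plus the initial state) for
    spatial metrics.
    """
    if initial.l != params.l:
        raise ParameterError("initial lattice size does not match params.l")
    lattice = initial
    baseline = float(lattice.N)
    state = ControllerState(on=True, baseline=baseline)
    n_steps = int(np.ceil(params.t_end / params.dt))
    # one independent 31-bit seed per step; matched arms share the stream
    step_seeds = np.random.SeedSequence(params.seed).generate_state(max(n_steps, 1)) >> 1

    p_death = params.delta_T * params.dt
    p_div_s = params.r_S * params.dt
    p_div_r = params.r_R * params.dt

    rows = np.zeros((n_steps + 1, len(TIMESERIES_COLUMNS)))
    rows[0, 1:4] = (lattice.S, lattice.R, lattice.N)
    n_rows = 1
    snapshots = [(0.0, lattice.copy())] if snapshot_every else None
    threshold = 1.2 * baseline
    status, ttp = "censored", None
    n_cycles = 0
    was_on = True

    for k in range(n_steps):
        D, state = dose(protocol, state, lattice.N, k * params.dt)
        if state.on and not was_on:
            n_cycles += 1
        was_on = state.on
        raw = _kernel.step_kernel(
            lattice.grid, p_death, p_div_s, p_div_r,
            _drug_kill_prob(D, params), int(step_seeds[k]),
        )
        lattice.S += int(raw[_kernel.I_BIRTHS_S] - raw[_kernel.I_DEATHS_S] - raw[_kernel.I_DRUG_KILLS])
        lattice.R += int(raw[_kernel.I_BIRTHS_R] - raw[_kernel.I_DEATHS_R])
        t = (k + 1) * params.dt
        rows[n_rows, 0] = t
        rows[n_rows, 1:4] = (lattice.S, lattice.R, lattice.N)
        rows[n_rows, 4] = D
        rows[n_rows, 5:] = raw
        n_rows += 1
        if snapshot_every and (k + 1) % snapshot_every == 0:
            snapshots.append((t, lattice.copy()))
        if lattice.N == 0:
            status = "cured"
            break
        if stop_on_progression and lattice.N >= threshold and t >= 150.0:
            status, ttp = "progressed", t
            break

    rows = rows[:n_rows]
    series = TimeSeries(
        {c: rows[:, i].copy() for i, c in enumerate(TIMESERIES_COLUMNS)},
        snapshots=snapshots,
    )
    if not stop_on_progression:
        status, ttp = detect_progression(series["t"], series["N"], baseline)
        if status != "progressed":
            ttp = None
    return series, Outcome(status=status, ttp=ttp, n_cycles=n_cycles)
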