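"""Non-spatial Lotka-Volterra twin of the lattice model.

Sensitive and resistant cells share a single logistic resource term with
carrying capacity ``K`` (the lattice site count when mirroring a lattice
configuration).  Drug multiplies the sensitive logistic growth term by
``(1 - 2 * d_D * D / D_max)``, so that at full dose with ``d_D = 0.75`` net
sensitive growth is negative:

    dS/dt = r_S (1 - (S+R)/K) (1 - 2 d_D D/D_max) S - delta_T S
    dR/dt = r_R (1 - (S+R)/K) R - delta_T R

Dose switching under adaptive protocols is handled with integrator events
(exact threshold crossings), unlike the lattice model's one-step overshoot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import SimParams
from .treatment import (
    PROGRESSION_FACTOR,
    PROGRESSION_MIN_DAYS,
    Protocol,
)


class IntegrationError(RuntimeError):
    """Raised when a piecewise integration segment fails."""


@dataclass(frozen=True)
class ODEParams:
    """Rates, carrying capacity and initial conditions of the mean-field twin."""

    r_S: float = 0.027
    r_R: float = 0.027
    delta_T: float = 0.0
    d_D: float = 0.75
    D_max: float = 1.0
    K: float = 10000.0
    S0: float = 7492.0
    R0: float = 8.0

    def __post_init__(self):
        if self.S0 < 0 or self.R0 < 0 or self.S0 + self.R0 > self.K:
            raise ValueError("initial conditions must satisfy 0 <= S0 + R0 <= K")
        if min(self.r_S, self.r_R, self.delta_T) < 0:
            raise ValueError("rates must be non-negative")

    @property
    def N0(self) -> float:
        return self.S0 + self.R0

    @classmethod
    def from_sim_params(cls, p: SimParams) -> "ODEParams":
        """Mirror a lattice configuration: K = l**2, same rates and seeding."""
        return cls(
            r_S=p.r_S,
            r_R=p.r_R,
            delta_T=p.delta_T,
            d_D=p.d_D,
            D_max=p.D_max,
            K=float(p.K),
            S0=float(p.N0 - p.R0),
            R0=float(p.R0),
        )


@dataclass
class ODESolution:
    """Dense solution of a protocol-driven run."""

    t: np.ndarray
    S: np.ndarray
    R: np.ndarray
    D: np.ndarray
    switch_times: list[float]

    @property
    def N(self) -> np.ndarray:
        return self.S + self.R

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "S": self.S, "R": self.R, "N": self.N, "D": self.D})

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def rhs(state, D: float, params: ODEParams) -> tuple[float, float]:
    """Right-hand side of the competition system at dose ``D``."""
    S, R = state
    crowd = 1.0 - (S + R) / params.K
    drug = 1.0 - 2.0 * params.d_D * D / params.D_max
    dS = params.r_S * crowd * drug * S - params.delta_T * S
    dR = params.r_R * crowd * R - params.delta_T * R
    return dS, dR


def solve_with_protocol(
    params: ODEParams,
    protocol: Protocol,
    t_end: float,
    method: str = "RK45",
    rtol: float = 1e-8,
    atol: float = 1e-8,
    grid_dt: float = 1.0,
    max_segments: int = 10000,
) -> ODESolution:
    """Integrate the system piecewise between dose-switch events.

    Adaptive thresholds are located by the integrator's event finder; the
    hysteresis state is carried across segments and the solution is
    continuous.  Output is reported on a uniform grid of spacing ``grid_dt``
    (switch times are also recorded exactly).
    """
    baseline = params.N0
    resume = protocol.resume_level if protocol.resume_level is not None else baseline
    lo = (1.0 - protocol.withdraw_frac) * baseline

    t_grid = np.arange(0.0, t_end + 0.5 * grid_dt, grid_dt)
    t_grid[-1] = min(t_grid[-1], t_end)
    ts, Ss, Rs, Ds = [], [], [], []
    switch_times: list[float] = []

    def f(t, y, D):
        return rhs(y, D, params)

    t0 = 0.0
    y0 = np.array([params.S0, params.R0], dtype=float)
    on = True
    segments = 0
    while t0 < t_end and segments < max_segments:
        segments += 1
        if protocol.kind == "continuous":
            D, t1 = protocol.D_max, t_end
            events = None
        elif protocol.kind == "external":
            D, t1 = 0.0, t_end
            for a, b in protocol.intervals or ():
                if a <= t0 < b:
                    D, t1 = protocol.D_max, min(b, t_end)
                    break
                if t0 < a:
                    t1 = min(a, t_end)
                    break
            events = None
        else:  # adaptive
            D = protocol.D_max if on else 0.0
            t1 = t_end
            if on:
                def ev(t, y, _D):
                    return y[0] + y[1] - lo
                ev.direction = -1.0
            else:
                def ev(t, y, _D):
                    return y[0] + y[1] - resume
                ev.direction = 1.0
            ev.terminal = True
            events = [ev]

        mask = (t_grid >= t0) & (t_grid <= t1)
        t_eval = t_grid[mask]
        sol = solve_ivp(
            f, (t0, t1), y0, method=method, args=(D,),
            events=events, dense_output=True, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed on [{t0}, {t1}] at dose {D}: {sol.message}"
            )
        t_stop = sol.t[-1]
        if t_eval.size:
            seg_t = t_eval[t_eval <= t_stop + 1e-12]
            if seg_t.size:
                y_seg = sol.sol(np.clip(seg_t, sol.t[0], t_stop))
                ts.append(seg_t)
                Ss.append(y_seg[0])
                Rs.append(y_seg[1])
                Ds.append(np.full(seg_t.size, D))
        if events is not None and sol.status == 1:  # threshold crossed
            switch_times.append(float(t_stop))
            on = not on
        y0 = sol.y[:, -1].copy()
        if t_stop <= t0:  # no forward progress (immediate re-switch)
            t_stop = np.nextafter(t0, np.inf)
        t0 = t_stop

    t_all = np.concatenate(ts) if ts else np.array([0.0])
    S_all = np.concatenate(Ss) if Ss else np.array([params.S0])
    R_all = np.concatenate(Rs) if Rs else np.array([params.R0])
    D_all = np.concatenate(Ds) if Ds else np.array([0.0])
    # drop duplicated grid points at segment joins; keep the later segment's
    # record so D(t) is the dose applied on [t, t+)
    keep = np.concatenate((np.diff(t_all) > 1e-12, [True]))
    return ODESolution(
        t=t_all[keep], S=np.maximum(S_all[keep], 0.0), R=np.maximum(R_all[keep], 0.0),
        D=D_all[keep], switch_times=switch_times,
    )


def ode_ttp(solution: ODESolution, baseline: Optional[float] = None):
    """Progression outcome of an ODE run, mirroring the lattice criterion.

    Returns ``(status, ttp)``: the first time ``N >= 1.2 * baseline`` with
    ``t >= 150`` d, located by linear interpolation on the dense output grid.
    """
    N = solution.N
    if baseline is None:
        baseline = float(N[0])
    threshold = PROGRESSION_FACTOR * baseline
    t = solution.t
    eligible = t >= PROGRESSION_MIN_DAYS
    above = (N >= threshold) & eligible
    if not above.any():
        if (N <= 1e-9).any():
            return "cured", None
        return "censored", None
    i = int(np.argmax(above))
    if i == 0 or N[i - 1] >= threshold:
        return "progressed", float(t[i])
    # interpolate the crossing within the bracketing grid interval
    t0, t1 = t[i - 1], t[i]
    n0v, n1v = N[i - 1], N[i]
    tc = t0 + (threshold - n0v) / (n1v - n0v) * (t1 - t0)
    return "progressed", float(max(tc, PROGRESSION_MIN_DAYS))
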