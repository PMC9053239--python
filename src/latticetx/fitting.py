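"""Fit the lattice model (or its ODE twin) to longitudinal normalised
tumour-burden series.

The objective is the root-mean-squared error between the observed normalised
burden and the model's normalised total cell number, averaged over stochastic
replicates run with common random numbers, and linearly interpolated to the
observation times.  Global optimisation uses basin-hopping (stochastic
perturbation plus local refinement), repeated from several random starting
points, with the best restart selected by AIC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import basinhopping

from .experiments import derive_seed, make_initial
from .ode import ODEParams, solve_with_protocol
from .params import SimParams
from .simulate import run_simulation
from .treatment import AT50, Protocol

FREE_PARAM_NAMES = ("n0", "f_R", "c_R", "d_T")

#: default box bounds for each fittable parameter
DEFAULT_BOUNDS = {
    "n0": (0.01, 1.0),
    "f_R": (0.0, 1.0),
    "c_R": (0.0, 1.0),
    "d_T": (0.0, 1.0),
}

#: cohort-mean values used by the reduced model variants
MODEL2_FIXED = {"c_R": 0.78, "d_T": 0.14}
MODEL3_FIXED = {"n0": 0.59, "f_R": 0.04}


@dataclass(frozen=True)
class PatientSeries:
    """A longitudinal burden series normalised to its value at treatment
    start, with optional recorded on-treatment intervals and hidden truth
    (for synthetic cohorts)."""

    times: np.ndarray
    burden: np.ndarray
    intervals: Optional[tuple[tuple[float, float], ...]] = None
    patient_id: str = ""
    truth: Optional[dict] = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        b = np.asarray(self.burden, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "burden", b)
        if t.size != b.size or t.size == 0:
            raise ValueError("times and burden must be equal-length, non-empty")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(b < 0):
            raise ValueError("burden must be non-negative")


@dataclass(frozen=True)
class FitConfig:
    """Which parameters are free, their bounds, and the search budgets."""

    free: tuple[str, ...] = ("c_R", "d_T")
    fixed: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=dict)
    engine: str = "ode"  # "ode" or "abm"
    n_replicates: int = 25  # stochastic replicates per candidate (abm engine)
    restarts: int = 10
    steps: Optional[int] = None  # basin-hopping iterations; default 50/75 by k
    seeding: str = "random"  # "random" or "disk"
    base_params: SimParams = field(default_factory=SimParams)

    def __post_init__(self):
        for name in self.free:
            if name not in FREE_PARAM_NAMES:
                raise ValueError(f"unknown free parameter {name!r}")
        if self.engine not in ("ode", "abm"):
            raise ValueError("engine must be 'ode' or 'abm'")
        if self.restarts < 1 or self.n_replicates < 1:
            raise ValueError("budgets must be positive")

    @property
    def n_free(self) -> int:
        return len(self.free)

    @property
    def n_steps(self) -> int:
        if self.steps is not None:
            return self.steps
        return 75 if self.n_free > 2 else 50

    def bound(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, DEFAULT_BOUNDS[name])


def model_config(model: int, **overrides) -> FitConfig:
    """The three standard variants: Model 1 frees all of (n0, f_R, c_R, d_T);
    Model 2 frees (n0, f_R) with cost/turnover fixed at the cohort means;
    Model 3 frees (c_R, d_T) with the initial composition fixed."""
    if model == 1:
        cfg = dict(free=FREE_PARAM_NAMES, fixed={})
    elif model == 2:
        cfg = dict(free=("n0", "f_R"), fixed=dict(MODEL2_FIXED))
    elif model == 3:
        cfg = dict(free=("c_R", "d_T"), fixed=dict(MODEL3_FIXED))
    else:
        raise ValueError("model must be 1, 2 or 3")
    cfg.update(overrides)
    return FitConfig(**cfg)


@dataclass
class FitResult:
    """Best fit of one patient series."""

    params: dict
    rmse: float
    aic: float
    n_obs: int
    n_free: int
    predicted: np.ndarray  # mean trajectory at the observation times
    spread: np.ndarray  # replicate standard deviation at the observation times
    restart_rmses: list[float]
    mean_cycle_days: Optional[float] = None


def _protocol_for(series: PatientSeries, fallback: Protocol = AT50) -> Protocol:
    """Dose from the recorded on/off intervals when the series carries them,
    else from the adaptive threshold controller."""
    if series.intervals is not None:
        return Protocol(kind="external", intervals=series.intervals)
    return fallback


def simulate_normalised(
    values: dict,
    series: PatientSeries,
    config: FitConfig,
    seeds: Sequence[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and s.d. of the model's normalised burden at the observation
    times, for parameter values ``values`` (a dict over the fittable names)."""
    horizon = float(series.times[-1]) + config.base_params.dt
    params = config.base_params.with_(t_end=horizon, **values)
    protocol = _protocol_for(series)
    if config.engine == "ode":
        sol = solve_with_protocol(ODEParams.from_sim_params(params), protocol, horizon)
        norm = sol.N / sol.N[0]
        pred = np.interp(series.times, sol.t, norm)
        return pred, np.zeros_like(pred)
    trajs = np.empty((len(seeds), series.times.size))
    for i, seed in enumerate(seeds):
        p = params.with_(seed=int(seed))
        initial = make_initial(p, config.seeding, np.random.default_rng(int(seed)))
        n0 = initial.N
        ts, _ = run_simulation(p, protocol, initial, stop_on_progression=False)
        trajs[i] = np.interp(series.times, ts["t"], ts["N"] / n0)
    return trajs.mean(axis=0), trajs.std(axis=0)


def objective_rmse(
    values: dict,
    series: PatientSeries,
    config: FitConfig,
    seeds: Sequence[int],
) -> float:
    """RMSE between the observed and the replicate-mean normalised burden.

    ``seeds`` are held fixed across optimiser evaluations (common random
    numbers), so the objective is deterministic in ``values``.
    """
    pred, _ = simulate_normalised(values, series, config, seeds)
    return float(np.sqrt(np.mean((pred - series.burden) ** 2)))


def aic_from_rss(rss: float, m: int, k: int) -> float:
    """Gaussian AIC up to constants: ``m ln(RSS/m) + 2k``."""
    return m * np.log(max(rss, 1e-300) / m) + 2 * k


def fit_patient(series: PatientSeries, config: FitConfig, rng) -> FitResult:
    """Multi-start basin-hopping fit of one series; returns the restart with
    the lowest AIC (equivalently RMSE, since the free-parameter count is
    fixed within a config)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    seeds = [int(rng.integers(0, 2**31)) for _ in range(config.n_replicates)]
    fixed = {name: config.fixed[name] for name in config.fixed}
    lo = np.array([config.bound(n)[0] for n in config.free])
    hi = np.array([config.bound(n)[1] for n in config.free])

    def unpack(x):
        values = dict(fixed)
        values.update({n: float(v) for n, v in zip(config.free, np.clip(x, lo, hi))})
        return values

    def fun(x):
        return objective_rmse(unpack(x), series, config, seeds)

    m = series.times.size
    k = config.n_free
    if k == 0:
        rmse = objective_rmse(fixed, series, config, seeds)
        pred, spread = simulate_normalised(fixed, series, config, seeds)
        aic = aic_from_rss(rmse**2 * m, m, 0)
        return FitResult(dict(fixed), rmse, aic, m, 0, pred, spread, [rmse])

    best_x, best_rmse = None, np.inf
    restart_rmses = []
    for _ in range(config.restarts):
        x0 = rng.uniform(lo, hi)
        res = basinhopping(
            fun,
            x0,
            niter=config.n_steps,
            minimizer_kwargs={
                "method": "Powell",
                "bounds": list(zip(lo, hi)),
                "options": {"xtol": 1e-4, "ftol": 1e-6},
            },
            seed=int(rng.integers(0, 2**31)),
            stepsize=0.25 * float(np.min(hi - lo)),
        )
        restart_rmses.append(float(res.fun))
        if res.fun < best_rmse:
            best_rmse = float(res.fun)
            best_x = np.clip(res.x, lo, hi)
    values = unpack(best_x)
    pred, spread = simulate_normalised(values, series, config, seeds)
    aic = aic_from_rss(best_rmse**2 * m, m, k)
    cyc = cycling_speed(series.times, pred, baseline=1.0)
    return FitResult(values, best_rmse, aic, m, k, pred, spread, restart_rmses, cyc[0])


def cycling_speed(
    times: np.ndarray,
    values: np.ndarray,
    baseline: float = 1.0,
    withdraw_frac: float = 0.5,
    fast_threshold_days: float = 365.0,
    crossing_tol: float = 0.02,
) -> tuple[Optional[float], str]:
    """Mean cycle length (days between successive upward baseline crossings
    after an excursion towards the withdrawal threshold) and a fast/slow
    class.

    A sampled series rarely touches the exact thresholds, so detection is
    inset: an excursion is registered at the corridor midpoint
    ``(1 - withdraw_frac/2) * baseline`` and a return within ``crossing_tol``
    of the baseline.  Returns ``(None, "undefined")`` when no cycle completes.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    lo = (1.0 - withdraw_frac / 2.0) * baseline
    hi = (1.0 - crossing_tol) * baseline
    below = False
    crossings = []
    for t, v in zip(times, values):
        if not below and v < lo:
            below = True
        elif below and v >= hi:
            below = False
            crossings.append(t)
    if not crossings:
        return None, "undefined"
    # cycle lengths: treatment start to first return, then between returns
    edges = np.concatenate(([times[0]], crossings))
    mean_len = float(np.mean(np.diff(edges)))
    return mean_len, ("fast" if mean_len < fast_threshold_days else "slow")


def generate_synthetic_cohort(
    truths: Sequence[dict],
    cadence: float = 30.0,
    noise: float = 0.0,
    rng=None,
    engine: str = "ode",
    t_end: float = 1500.0,
    base_params: Optional[SimParams] = None,
    protocol: Protocol = AT50,
    n_replicates: int = 1,
) -> list[PatientSeries]:
    """Simulate patients with known parameters under threshold-driven on/off
    treatment, sampled at a fixed cadence with multiplicative log-normal
    observation noise, normalised to baseline.

    This emulates roughly monthly burden measurements (default cadence 30 d)
    collected under an intermittent schedule; the generating parameters are
    attached as each series' ``truth``.
    """
    if rng is None or not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if base_params is None:
        base_params = SimParams()
    cohort = []
    for pi, truth in enumerate(truths):
        params = base_params.with_(t_end=t_end, **truth)
        times = np.arange(0.0, t_end + 0.5 * cadence, cadence)
        if engine == "ode":
            sol = solve_with_protocol(ODEParams.from_sim_params(params), protocol, t_end)
            burden = np.interp(times, sol.t, sol.N / sol.N[0])
            intervals = _ode_intervals(sol, t_end)
        else:
            seed = int(rng.integers(0, 2**31))
            trajs = []
            dose_t = dose_D = None
            for rep in range(n_replicates):
                s = derive_seed(seed, pi, rep)
                p = params.with_(seed=s)
                initial = make_initial(p, "random", np.random.default_rng(s))
                ts, _ = run_simulation(p, protocol, initial, stop_on_progression=False)
                trajs.append(np.interp(times, ts["t"], ts["N"] / ts["N"][0]))
                if rep == 0:
                    dose_t, dose_D = ts["t"], ts["D"]
            burden = np.mean(trajs, axis=0)
            from .treatment import intervals_from_dose

            intervals = intervals_from_dose(dose_t, dose_D)
        if noise > 0:
            burden = burden * rng.lognormal(mean=0.0, sigma=noise, size=burden.size)
        burden = burden / burden[0]
        cohort.append(
            PatientSeries(
                times=times,
                burden=burden,
                intervals=intervals,
                patient_id=f"synthetic-{pi:03d}",
                truth=dict(truth),
            )
        )
    return cohort


def _ode_intervals(sol, t_end: float) -> tuple[tuple[float, float], ...]:
    """On-treatment windows from an ODE solution's exact switch times
    (treatment starts on at t=0; switches alternate off/on)."""
    intervals = []
    start = 0.0
    on = True
    for s in sol.switch_times:
        if on:
            intervals.append((start, float(s)))
        else:
            start = float(s)
        on = not on
    if on:
        intervals.append((start, float(t_end)))
    return tuple(intervals)


# ---------------------------------------------------------------------------
# I/O


def read_cohort_csv(path) -> list[PatientSeries]:
    """Read patient series from a CSV with columns patient_id, day,
    psa_normalized and optionally on_treatment (0/1)."""
    df = pd.read_csv(path)
    out = []
    for pid, g in df.groupby("patient_id", sort=True):
        g = g.sort_values("day")
        intervals = None
        if "on_treatment" in g.columns:
            from .treatment import intervals_from_dose

            intervals = intervals_from_dose(g["day"].to_numpy(), g["on_treatment"].to_numpy())
        out.append(
            PatientSeries(
                times=g["day"].to_numpy(float),
                burden=g["psa_normalized"].to_numpy(float),
                intervals=intervals,
                patient_id=str(pid),
            )
        )
    return out


def write_cohort_csv(cohort: Sequence[PatientSeries], path) -> None:
    rows = []
    for s in cohort:
        on = np.zeros(s.times.size, dtype=int)
        if s.intervals:
            for a, b in s.intervals:
                on[(s.times >= a) & (s.times < b)] = 1
        for t, v, o in zip(s.times, s.burden, on):
            rows.append({"patient_id": s.patient_id, "day": t, "psa_normalized": v, "on_treatment": o})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_fit_json(result: FitResult, path) -> None:
    payload = {
        "params": result.params,
        "rmse": result.rmse,
        "aic": result.aic,
        "n_obs": result.n_obs,
        "n_free": result.n_free,
        "restart_rmses": result.restart_rmses,
        "mean_cycle_days": result.mean_cycle_days,
        "predicted": list(map(float, result.predicted)),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
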