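"""Reproducible experiment harnesses.

Matched continuous/adaptive pairs (same parameters, same initial lattice,
same per-step random streams), tidy parameter sweeps, nest-separation
studies, the resistant-only growth-law comparison against logistic growth,
and a replicate-convergence utility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .lattice import Lattice, Nest, seed_disk, seed_nests, seed_random, two_nests
from .params import DAYS_PER_MONTH, SimParams
from .simulate import Outcome, run_simulation
from .treatment import AT50, CONTINUOUS, Protocol


def derive_seed(base_seed: int, *indices: int) -> int:
    """Counter-based 31-bit seed for (condition, replicate) cells; stable
    under parallel execution order."""
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=tuple(int(i) for i in indices))
    return int(ss.generate_state(1)[0] >> 1)


def make_initial(params: SimParams, seeding="random", rng=None) -> Lattice:
    """Build an initial lattice: ``"random"``, ``"disk"``, or a sequence of
    :class:`Nest` rectangles."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if isinstance(seeding, str):
        if seeding == "random":
            return seed_random(params, rng)
        if seeding == "disk":
            return seed_disk(params, rng)
        raise ValueError(f"unknown seeding {seeding!r}")
    return seed_nests(params, seeding, rng)


@dataclass(frozen=True)
class PairResult:
    """Outcome of one matched continuous-vs-adaptive pair."""

    seed: int
    ttp_CT: Optional[float]
    ttp_AT: Optional[float]
    status_CT: str
    status_AT: str
    n_cycles_AT: int = 0

    @property
    def gain_days(self) -> float:
        """TTP gain of adaptive over continuous therapy (days); NaN when
        either arm is censored or cured (no finite TTP)."""
        if self.ttp_CT is None or self.ttp_AT is None:
            return float("nan")
        return self.ttp_AT - self.ttp_CT

    @property
    def gain_months(self) -> float:
        return self.gain_days / DAYS_PER_MONTH


def matched_pair(
    params: SimParams,
    seeding="random",
    seed: Optional[int] = None,
    protocol_at: Protocol = AT50,
    protocol_ct: Protocol = CONTINUOUS,
) -> PairResult:
    """Treat the same tumour (identical initial lattice and random streams)
    once continuously and once adaptively."""
    if seed is None:
        seed = params.seed
    params = params.with_(seed=int(seed))
    initial = make_initial(params, seeding, np.random.default_rng(int(seed)))
    _, out_ct = run_simulation(params, protocol_ct, initial.copy())
    _, out_at = run_simulation(params, protocol_at, initial.copy())
    return PairResult(
        seed=int(seed),
        ttp_CT=out_ct.ttp,
        ttp_AT=out_at.ttp,
        status_CT=out_ct.status,
        status_AT=out_at.status,
        n_cycles_AT=out_at.n_cycles,
    )


def _classify(pair: PairResult) -> str:
    if pair.status_AT == "cured" or pair.status_CT == "cured":
        return "cured"
    if pair.status_AT == "censored" or pair.status_CT == "censored":
        return "censored"
    return "AT_better" if pair.gain_days >= 0 else "CT_better"


@dataclass
class SweepResult:
    """Per-condition replicate table and summary for one sweep cell."""

    condition: dict
    pairs: list[PairResult]
    summary: dict = field(default_factory=dict)

    def summarise(self) -> dict:
        gains = np.array([p.gain_months for p in self.pairs])
        finite = gains[np.isfinite(gains)]
        cats = [_classify(p) for p in self.pairs]
        self.summary = {
            "n": len(self.pairs),
            "n_finite_gain": int(finite.size),
            "mean_gain_months": float(finite.mean()) if finite.size else float("nan"),
            "median_gain_months": float(np.median(finite)) if finite.size else float("nan"),
            "q1_gain_months": float(np.percentile(finite, 25)) if finite.size else float("nan"),
            "q3_gain_months": float(np.percentile(finite, 75)) if finite.size else float("nan"),
            "mean_ttp_CT": float(np.mean([p.ttp_CT for p in self.pairs if p.ttp_CT is not None] or [np.nan])),
            "mean_ttp_AT": float(np.mean([p.ttp_AT for p in self.pairs if p.ttp_AT is not None] or [np.nan])),
            "n_AT_better": cats.count("AT_better"),
            "n_CT_better": cats.count("CT_better"),
            "n_cured": cats.count("cured"),
            "n_censored": cats.count("censored"),
        }
        return self.summary

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rep, p in enumerate(self.pairs):
            row = dict(self.condition)
            row.update(
                replicate=rep,
                seed=p.seed,
                ttp_CT=p.ttp_CT,
                ttp_AT=p.ttp_AT,
                status_CT=p.status_CT,
                status_AT=p.status_AT,
                gain_days=p.gain_days,
                gain_months=p.gain_months,
                n_cycles_AT=p.n_cycles_AT,
                category=_classify(p),
            )
            rows.append(row)
        return pd.DataFrame(rows)


def sweep(
    conditions: Sequence[dict],
    n_reps: int,
    base_seed: int,
    base_params: Optional[SimParams] = None,
    protocol_at: Protocol = AT50,
) -> list[SweepResult]:
    """Run matched pairs over a grid of conditions.

    Each condition is a dict of :class:`SimParams` field overrides, plus the
    optional keys ``seeding`` ("random", "disk" or a separation integer under
    ``nest_separation`` for two 2x2 nests) and ``withdraw_frac``.  Per-run
    seeds derive deterministically from ``(base_seed, condition, replicate)``.
    """
    if base_params is None:
        base_params = SimParams()
    results = []
    for ci, cond in enumerate(conditions):
        cond = dict(cond)
        seeding = cond.pop("seeding", "random")
        if "nest_separation" in cond:
            seeding = two_nests(int(cond.pop("nest_separation")))
        wf = cond.pop("withdraw_frac", None)
        at = protocol_at if wf is None else Protocol(kind="adaptive", withdraw_frac=wf)
        params = base_params.with_(**cond)
        pairs = [
            matched_pair(params, seeding, derive_seed(base_seed, ci, rep), protocol_at=at)
            for rep in range(n_reps)
        ]
        res = SweepResult(condition={**cond, "condition": ci}, pairs=pairs)
        res.summarise()
        results.append(res)
    return results


def sweep_frame(results: Sequence[SweepResult]) -> pd.DataFrame:
    """Concatenate sweep cells into one tidy long-format table."""
    return pd.concat([r.to_frame() for r in results], ignore_index=True)


# ---------------------------------------------------------------------------
# growth-law comparison


def logistic_curve(t, x0: float, r: float, K: float):
    """Closed-form logistic growth ``K x0 e^{rt} / (K + x0 (e^{rt} - 1))``."""
    t = np.asarray(t, dtype=float)
    e = np.exp(r * t)
    return K * x0 * e / (K + x0 * (e - 1.0))


def logistic_time_to(x: float, x0: float, r: float, K: float) -> float:
    """Time for the logistic curve to grow from ``x0`` to ``x``."""
    if not 0 < x0 < K or not x0 <= x < K:
        raise ValueError("need 0 < x0 <= x < K")
    return np.log(x * (K - x0) / (x0 * (K - x))) / r


def _compact_nest(count: int) -> list[Nest]:
    """A single near-square rectangle of the given area at the domain centre
    (used for small initial counts, which grow as one compact colony)."""
    h = int(np.floor(np.sqrt(count)))
    while count % h:
        h -= 1
    return [Nest(height=h, width=count // h)]


@dataclass
class GrowthCurve:
    """Mean resistant-only growth trajectory for one initial count."""

    initial_count: int
    t: np.ndarray  # time after alignment onto the logistic reference clock
    mean_R: np.ndarray
    time_shift: float
    time_to_half_K: float  # on the aligned clock; NaN if never reached
    signed_area: float  # integral of (ABM mean - logistic) over overlap


def growth_law_comparison(
    params: SimParams,
    initial_counts: Sequence[int],
    n_reps: int,
    base_seed: int,
    reference_count: Optional[float] = None,
    compact_threshold: int = 8,
) -> tuple[list[GrowthCurve], Callable]:
    """Resistant-only, drug-free growth from different initial counts,
    aligned to the logistic reference.

    Counts up to ``compact_threshold`` are seeded as one compact central
    nest; larger counts are scattered uniformly.  Each mean trajectory is
    shifted in time so it starts at the moment the logistic curve (from
    ``reference_count``, default the smallest initial count) reaches its
    starting count.  Returns the curves and the reference function of time.
    """
    K = float(params.K)
    r = params.r_R
    drug_free = Protocol(kind="external", intervals=())
    ref0 = float(reference_count if reference_count is not None else min(initial_counts))
    reference = lambda t: logistic_curve(t, ref0, r, K)

    curves = []
    for gi, count in enumerate(initial_counts):
        p = params.with_(n0=count / K, f_R=1.0)
        n_steps = int(np.ceil(p.t_end / p.dt)) + 1
        acc = np.zeros(n_steps)
        lengths = np.zeros(n_steps, dtype=int)
        for rep in range(n_reps):
            seed = derive_seed(base_seed, gi, rep)
            if count <= compact_threshold:
                initial = seed_nests(p, _compact_nest(count), np.random.default_rng(seed))
            else:
                initial = seed_random(p, np.random.default_rng(seed))
            series, _ = run_simulation(p.with_(seed=seed), drug_free, initial, stop_on_progression=False)
            Rv = series["R"]
            acc[: Rv.size] += Rv
            lengths[: Rv.size] += 1
        mean_R = acc / np.maximum(lengths, 1)
        t = np.arange(n_steps) * p.dt
        # align onto the logistic clock
        shift = logistic_time_to(float(count), ref0, r, K) if count > ref0 else 0.0
        t_aligned = t + shift
        half = K / 2.0
        above = mean_R >= half
        t_half = float(t_aligned[np.argmax(above)]) if above.any() else float("nan")
        ref_vals = reference(t_aligned)
        signed_area = float(np.trapezoid(mean_R - ref_vals, t_aligned))
        curves.append(
            GrowthCurve(
                initial_count=count,
                t=t_aligned,
                mean_R=mean_R,
                time_shift=shift,
                time_to_half_K=t_half,
                signed_area=signed_area,
            )
        )
    return curves, reference


# ---------------------------------------------------------------------------
# replicate convergence


def convergence_check(
    params: SimParams,
    protocol: Protocol,
    n_values: Sequence[int],
    statistic: Callable[[np.ndarray], float] = np.mean,
    base_seed: int = 0,
    seeding="random",
    n_boot: int = 1000,
) -> pd.DataFrame:
    """Statistic of TTP versus replicate count, with bootstrap CIs.

    Runs ``max(n_values)`` adaptive-therapy replicates once and evaluates the
    statistic on nested prefixes; flags stabilisation where successive CIs
    overlap.
    """
    n_values = sorted(int(n) for n in n_values)
    n_max = n_values[-1]
    ttps = np.empty(n_max)
    for rep in range(n_max):
        seed = derive_seed(base_seed, 0, rep)
        p = params.with_(seed=seed)
        initial = make_initial(p, seeding, np.random.default_rng(seed))
        _, out = run_simulation(p, protocol, initial)
        ttps[rep] = out.ttp if out.ttp is not None else params.t_end
    rng = np.random.default_rng(base_seed)
    rows = []
    prev_ci = None
    for n in n_values:
        sample = ttps[:n]
        est = float(statistic(sample))
        boots = np.array([statistic(rng.choice(sample, size=n)) for _ in range(n_boot)])
        lo, hi = np.percentile(boots, [2.5, 97.5])
        stable = prev_ci is not None and not (hi < prev_ci[0] or lo > prev_ci[1])
        rows.append({"n": n, "statistic": est, "ci_lo": float(lo), "ci_hi": float(hi), "stable": stable})
        prev_ci = (lo, hi)
    return pd.DataFrame(rows)
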