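"""Dosing protocols, progression detection and cycle counting.

Two clinically motivated schedules are built in: continuous therapy at the
maximum tolerated dose, and threshold-adaptive therapy, which withdraws drug
once the burden has fallen a fraction ``withdraw_frac`` below its baseline and
reinstates it when the burden regrows to the baseline.  Externally recorded
on/off interval schedules (e.g. from a trial) are also supported.

Progression follows a RECIST-style rule: the first time the burden is at
least 20% above baseline, provided at least 150 days have passed since the
start of treatment (the floor absorbs brief early overshoots at the end of
the first off-cycles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

PROGRESSION_FACTOR = 1.2
PROGRESSION_MIN_DAYS = 150.0


@dataclass(frozen=True)
class Protocol:
    """A dosing rule.

    kind
        ``"continuous"`` (always on), ``"adaptive"`` (threshold hysteresis) or
        ``"external"`` (on inside the supplied intervals).
    withdraw_frac
        Adaptive only: fractional burden drop from baseline that triggers
        withdrawal (0.5 = the 50% rule).
    resume_level
        Adaptive only: absolute burden at which treatment restarts; ``None``
        means the baseline itself.
    D_max
        Dose applied while on treatment.
    intervals
        External only: sorted, non-overlapping ``(start_day, end_day)``
        on-treatment windows.
    """

    kind: str = "adaptive"
    withdraw_frac: float = 0.5
    resume_level: Optional[float] = None
    D_max: float = 1.0
    intervals: Optional[tuple[tuple[float, float], ...]] = None

    def __post_init__(self):
        if self.kind not in ("continuous", "adaptive", "external"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "adaptive" and not 0.0 < self.withdraw_frac < 1.0:
            raise ValueError("withdraw_frac must lie in (0, 1)")
        if self.kind == "external":
            iv = self.intervals or ()
            object.__setattr__(self, "intervals", tuple((float(a), float(b)) for a, b in iv))
            prev_end = -np.inf
            for a, b in self.intervals:
                if a >= b or a < prev_end:
                    raise ValueError("external intervals must be sorted and non-overlapping")
                prev_end = b


CONTINUOUS = Protocol(kind="continuous")
AT50 = Protocol(kind="adaptive", withdraw_frac=0.5)
AT30 = Protocol(kind="adaptive", withdraw_frac=0.3)


@dataclass
class ControllerState:
    """Hysteresis state of the dosing controller."""

    on: bool = True
    baseline: float = 0.0


def dose(protocol: Protocol, state: ControllerState, N: float, t: float) -> tuple[float, ControllerState]:
    """Evaluate the protocol at burden ``N`` and time ``t``.

    Returns the dose for the upcoming step and the updated controller state.
    For adaptive protocols the resumption condition is ``N >= resume_level``
    (exact equality with the baseline is unattainable on a stochastic
    trajectory).
    """
    if protocol.kind == "continuous":
        return protocol.D_max, state
    if protocol.kind == "external":
        on = any(a <= t < b for a, b in (protocol.intervals or ()))
        return (protocol.D_max if on else 0.0), replace_state(state, on=on)
    resume = protocol.resume_level if protocol.resume_level is not None else state.baseline
    on = state.on
    if on and N < (1.0 - protocol.withdraw_frac) * state.baseline:
        on = False
    elif not on and N >= resume:
        on = True
    return (protocol.D_max if on else 0.0), replace_state(state, on=on)


def replace_state(state: ControllerState, **kw) -> ControllerState:
    new = ControllerState(on=state.on, baseline=state.baseline)
    for k, v in kw.items():
        setattr(new, k, v)
    return new


def detect_progression(t: np.ndarray, N: np.ndarray, baseline: float) -> tuple[str, Optional[float]]:
    """Classify a burden trajectory.

    Returns ``(status, ttp)`` where status is ``"progressed"`` (first time
    ``N >= 1.2 * baseline`` with ``t >= 150`` d), ``"cured"`` (burden hit zero
    first) or ``"censored"``; ``ttp`` is the progression time or ``None``.
    """
    t = np.asarray(t, dtype=float)
    N = np.asarray(N, dtype=float)
    if t.size == 0:
        raise ValueError("empty series")
    threshold = PROGRESSION_FACTOR * baseline
    for ti, ni in zip(t, N):
        if ni == 0:
            return "cured", None
        if ni >= threshold and ti >= PROGRESSION_MIN_DAYS:
            return "progressed", float(ti)
    return "censored", None


def count_cycles(t: np.ndarray, N: np.ndarray, baseline: float, withdraw_frac: float = 0.5) -> int:
    """Number of completed adaptive-therapy cycles in a burden series.

    A cycle is the period between two sequential upward crossings of the
    baseline: the burden must first drop below the withdrawal threshold
    ``(1 - withdraw_frac) * baseline`` and then return to the baseline.
    """
    below = False
    cycles = 0
    lo = (1.0 - withdraw_frac) * baseline
    for ni in np.asarray(N, dtype=float):
        if not below and ni < lo:
            below = True
        elif below and ni >= baseline:
            below = False
            cycles += 1
    return cycles


def read_schedule_csv(path) -> Protocol:
    """Build an external protocol from a CSV of (start_day, end_day) rows."""
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.lower() in ("start_day", "end_day")]
    if len(cols) == 2:
        iv = list(zip(df[cols[0]], df[cols[1]]))
    else:
        iv = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return Protocol(kind="external", intervals=tuple(sorted(iv)))


def intervals_from_dose(t: Sequence[float], D: Sequence[float]) -> tuple[tuple[float, float], ...]:
    """Recover on-treatment (start, end) windows from a sampled dose signal."""
    t = np.asarray(t, dtype=float)
    on = np.asarray(D, dtype=float) > 0
    intervals = []
    start = None
    for ti, oi in zip(t, on):
        if oi and start is None:
            start = ti
        elif not oi and start is not None:
            intervals.append((start, ti))
            start = None
    if start is not None:
        intervals.append((start, float(t[-1]) + (float(t[-1]) - float(t[-2]) if t.size > 1 else 1.0)))
    return tuple(intervals)
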