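"""Model parameters for the on-lattice tumour simulator.

The model describes a small region of tumour tissue as an ``l x l`` square
lattice whose sites are empty or hold a single drug-sensitive or
drug-resistant cell.  Sensitive cells divide at rate ``r_S`` (per day),
resistant cells at ``r_R = (1 - c_R) * r_S`` where ``c_R`` is the cost of
resistance.  Both types die at the background rate ``delta_T = d_T * r_S``
(turnover ``d_T`` is expressed relative to the sensitive division rate).  A
sensitive cell caught in mitosis is killed by drug with probability
``d_D * D(t) / D_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

DAYS_PER_MONTH = 365.25 / 12  # 30.4375 d, used to report TTP gains in months

#: default simulation horizon: ten years
DEFAULT_T_END = 3650.0


class ParameterError(ValueError):
    """Raised when a parameter combination violates model constraints."""


@dataclass(frozen=True)
class SimParams:
    """All constants of the lattice model plus run controls.

    Parameters
    ----------
    l : int
        Lattice side length; carrying capacity of the mean-field twin is
        ``K = l**2`` sites.
    dt : float
        Time step in days.
    r_S : float
        Sensitive division rate (per day).
    c_R : float
        Resistance cost in [0, 1]; resistant rate is ``(1 - c_R) * r_S``.
    d_T : float
        Turnover: background death rate as a fraction of ``r_S`` (same for
        both cell types).
    d_D : float
        Probability that a mitotic sensitive cell is killed at full dose.
    D_max : float
        Maximum (normalised) dose.
    n0 : float
        Initial density as a fraction of ``l**2``, in (0, 1].
    f_R : float
        Initial resistant fraction of the seeded population, in [0, 1].
    t_end : float
        Simulation horizon in days.
    seed : int
        RNG seed for a run.
    """

    l: int = 100
    dt: float = 1.0
    r_S: float = 0.027
    c_R: float = 0.0
    d_T: float = 0.0
    d_D: float = 0.75
    D_max: float = 1.0
    n0: float = 0.75
    f_R: float = 0.001
    t_end: float = DEFAULT_T_END
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l < 1:
            raise ParameterError(f"lattice side must be >= 1, got {self.l}")
        if not 0.0 < self.n0 <= 1.0:
            raise ParameterError(f"n0 must be in (0, 1], got {self.n0}")
        if not 0.0 <= self.f_R <= 1.0:
            raise ParameterError(f"f_R must be in [0, 1], got {self.f_R}")
        if not 0.0 <= self.c_R <= 1.0:
            raise ParameterError(f"c_R must be in [0, 1], got {self.c_R}")
        if self.d_T < 0.0:
            raise ParameterError(f"d_T must be >= 0, got {self.d_T}")
        if self.r_S < 0.0:
            raise ParameterError(f"r_S must be >= 0, got {self.r_S}")
        if self.D_max <= 0.0:
            raise ParameterError(f"D_max must be > 0, got {self.D_max}")
        if not 0.0 <= self.d_D * self.D_max <= 1.0:
            raise ParameterError(
                f"d_D * D_max must lie in [0, 1], got {self.d_D * self.D_max}"
            )
        if self.dt <= 0.0:
            raise ParameterError(f"dt must be > 0, got {self.dt}")
        # rate * dt is used directly as a per-step probability
        if self.r_S * self.dt > 1.0 or self.delta_T * self.dt > 1.0:
            raise ParameterError(
                "per-step event probabilities exceed 1; reduce dt or the rates"
            )

    # ---- derived quantities -------------------------------------------------

    @property
    def r_R(self) -> float:
        """Resistant division rate ``(1 - c_R) * r_S`` (per day)."""
        return (1.0 - self.c_R) * self.r_S

    @property
    def delta_T(self) -> float:
        """Background death rate ``d_T * r_S`` (per day), equal for S and R."""
        return self.d_T * self.r_S

    @property
    def f_S(self) -> float:
        return 1.0 - self.f_R

    @property
    def K(self) -> int:
        """Carrying capacity of the mean-field twin: the site count."""
        return self.l * self.l

    @property
    def N0(self) -> int:
        """Initial cell number, round-half-even of ``n0 * l**2``."""
        return round(self.n0 * self.l * self.l)

    @property
    def R0(self) -> int:
        """Initial resistant count: round-half-even of ``f_R * N0``, floored
        at 1 whenever ``f_R > 0`` and the lattice is seeded at all."""
        n0 = self.N0
        if self.f_R == 0.0 or n0 == 0:
            return 0
        return max(1, round(self.f_R * n0))

    def with_(self, **changes) -> "SimParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)
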