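"""The one-step update rule: tallies, conservation, expectations, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from latticetx import (
    AT50,
    CONTINUOUS,
    Lattice,
    RESISTANT,
    SENSITIVE,
    SimParams,
    run_simulation,
    seed_random,
    step,
)

from _oracles import enumerate_step


def test_empty_lattice_is_inert(rng):
    p = SimParams(l=5, n0=0.2, f_R=0.0)
    lat = Lattice(np.zeros((5, 5), np.int8))
    _, stats = step(lat, 1.0, p, rng)
    assert lat.N == 0
    assert all(getattr(stats, f) == 0 for f in stats.__dataclass_fields__)


def test_full_lattice_blocks_everything(rng):
    p = SimParams(l=6, n0=1.0, f_R=0.5, d_T=0.0, r_S=0.8, dt=1.0)
    grid = np.full((6, 6), SENSITIVE, np.int8)
    grid[:3] = RESISTANT
    lat = Lattice(grid)
    _, stats = step(lat, 0.0, p, rng)
    assert lat.N == 36
    assert stats.blocked_S == stats.attempts_S
    assert stats.blocked_R == stats.attempts_R
    assert stats.births_S == stats.births_R == stats.deaths_S == stats.drug_kills == 0


@pytest.mark.parametrize(
    "dose_frac, expected_mean",
    [(0.0, 1.027), (1.0, 1 + 0.027 * (1 - 2 * 0.75))],
    ids=["drug-free", "full-dose"],
)
def test_single_cell_one_step_expectation(dose_frac, expected_mean, rng):
    """A lone sensitive cell divides w.p. r_S*dt; under full dose the mitotic
    cell is killed w.p. d_D, so E[N] = 1 + r_S*(1 - 2*d_D)."""
    p = SimParams(l=3, n0=1 / 9, f_R=0.0)
    n_rep = 100_000
    total = 0
    for _ in range(n_rep):
        grid = np.zeros((3, 3), np.int8)
        grid[1, 1] = SENSITIVE
        lat = Lattice(grid)
        step(lat, dose_frac * p.D_max, p, rng)
        total += lat.N
    se = np.sqrt(0.027 / n_rep)  # binomial-scale bound on the MC error
    assert total / n_rep == pytest.approx(expected_mean, abs=5 * se)


def test_successor_distribution_matches_enumeration(rng):
    """Empirical one-step distribution on a 3-cell 3x3 lattice agrees with
    exhaustive enumeration of the update rule (two sensitive, one resistant,
    death, drug kill and blocking all reachable)."""
    from scipy.stats import chisquare

    grid = np.zeros((3, 3), np.int8)
    grid[0, 0] = SENSITIVE
    grid[1, 1] = SENSITIVE
    grid[0, 1] = RESISTANT
    p = SimParams(l=3, dt=1.0, r_S=0.5, c_R=0.4, d_T=0.4, d_D=0.5, n0=3 / 9, f_R=1 / 3)
    dist, _ = enumerate_step(grid, 0.2, 0.5, 0.3, 0.5)
    n = 40_000
    counts = {}
    for _ in range(n):
        lat = Lattice(grid.copy())
        step(lat, 1.0, p, rng)
        key = lat.grid.tobytes()
        counts[key] = counts.get(key, 0) + 1
    obs, exp, o_tail, e_tail = [], [], 0, 0.0
    for key, prob in dist.items():
        e = prob * n
        if e >= 5:
            obs.append(counts.get(key, 0))
            exp.append(e)
        else:
            o_tail += counts.get(key, 0)
            e_tail += e
    if e_tail > 0:
        obs.append(o_tail)
        exp.append(e_tail)
    exp = np.array(exp) * sum(obs) / sum(exp)
    assert chisquare(obs, exp).pvalue > 0.01


def test_blocked_fraction_matches_enumeration_oracle(rng):
    """One-step blocking probability of a 2x2 resistant block in an empty
    4x4 lattice equals the exact expectation over attempt patterns."""
    grid = np.zeros((4, 4), np.int8)
    grid[1:3, 1:3] = RESISTANT
    p = SimParams(l=4, dt=1.0, r_S=0.5, c_R=0.0, d_T=0.0, n0=0.25, f_R=1.0)
    _, expected = enumerate_step(grid, 0.0, 0.5, 0.5, 0.0)
    n = 30_000
    blocked = attempts = 0
    for _ in range(n):
        lat = Lattice(grid.copy())
        _, stats = step(lat, 0.0, p, rng)
        blocked += stats.blocked_R
        attempts += stats.attempts_R
    frac = blocked / attempts
    oracle = expected["blocked_R"] / expected["attempts_R"]
    assert frac == pytest.approx(oracle, abs=4 * np.sqrt(0.25 / attempts))


@settings(max_examples=25, deadline=None)
@given(
    seed=st.integers(0, 2**31 - 1),
    d_T=st.sampled_from([0.0, 0.3, 0.8]),
    dose=st.sampled_from([0.0, 0.5, 1.0]),
)
def test_count_conservation_and_tally_identities(seed, d_T, dose):
    """N(after) = N(before) + births - deaths - drug kills, and the tally
    decompositions hold on every step."""
    p = SimParams(l=12, n0=0.6, f_R=0.3, r_S=0.4, dt=1.0, d_T=d_T, d_D=0.75)
    rng = np.random.default_rng(seed)
    lat = seed_random(p, rng)
    for _ in range(5):
        before = lat.N
        _, s = step(lat, dose, p, rng)
        assert lat.N == before + s.births_S + s.births_R - s.deaths_S - s.deaths_R - s.drug_kills
        assert s.births_R == s.attempts_R - s.blocked_R
        assert s.births_S == s.attempts_S - s.blocked_S - s.drug_kills
        assert s.blocked_S <= s.attempts_S and s.blocked_R <= s.attempts_R
        assert s.drug_kills <= s.attempts_S - s.blocked_S
        lat.recount()  # cached counts stay consistent with the grid
        assert lat.N == before + s.births_S + s.births_R - s.deaths_S - s.deaths_R - s.drug_kills


def test_blocking_probability_monotone_in_local_density():
    """Filling more neighbours of a focal resistant cell never decreases its
    expected blocked fraction (exact, via enumeration on a nested chain of
    3x3 configurations)."""
    neighbour_sites = [(0, 1), (1, 0), (2, 1), (1, 2)]
    fractions = []
    for k in range(5):
        grid = np.zeros((3, 3), np.int8)
        grid[1, 1] = RESISTANT
        for r, c in neighbour_sites[:k]:
            grid[r, c] = RESISTANT
        _, exp = enumerate_step(grid, 0.0, 0.5, 0.5, 0.0)
        fractions.append(exp["blocked_R"] / exp["attempts_R"])
    assert all(b >= a - 1e-12 for a, b in zip(fractions, fractions[1:]))
    assert fractions[0] == 0.0


def test_resistant_cells_never_drug_killed(rng):
    p = SimParams(l=10, n0=0.3, f_R=1.0, r_S=0.5, d_D=1.0)
    lat = seed_random(p, rng)
    n0 = lat.N
    for _ in range(20):
        _, s = step(lat, 1.0, p, rng)
        assert s.drug_kills == 0
    assert lat.N >= n0  # no deaths, no kills: growth only


def test_growth_absorbs_at_capacity(rng):
    p = SimParams(l=8, n0=0.2, f_R=0.0, r_S=0.9, d_T=0.0, dt=1.0)
    lat = seed_random(p, rng)
    prev = lat.N
    for _ in range(200):
        step(lat, 0.0, p, rng)
        assert lat.N >= prev
        prev = lat.N
    assert lat.N == 64


class TestRunSimulation:
    def test_frozen_dynamics_censored(self, rng):
        p = SimParams(l=10, n0=0.5, f_R=0.1, r_S=0.0, d_T=0.0, t_end=30.0)
        lat = seed_random(p, rng)
        series, out = run_simulation(p, CONTINUOUS, lat)
        assert out.status == "censored"
        assert (series["N"] == series["N"][0]).all()
        assert len(series) == 31

    def test_certain_kill_population_non_increasing(self, rng):
        p = SimParams(l=10, n0=0.5, f_R=0.0, d_T=0.0, d_D=1.0, t_end=100.0)
        lat = seed_random(p, rng)
        series, _ = run_simulation(p, CONTINUOUS, lat)
        assert (np.diff(series["N"]) <= 0).all()

    def test_determinism_bitwise(self):
        p = SimParams(l=15, n0=0.6, f_R=0.05, d_T=0.2, t_end=120.0, seed=99)
        lat = seed_random(p, np.random.default_rng(99))
        s1, o1 = run_simulation(p, AT50, lat.copy())
        s2, o2 = run_simulation(p, AT50, lat.copy())
        for col in s1.columns:
            assert np.array_equal(s1[col], s2[col])
        assert o1 == o2

    def test_adaptive_therapy_maintains_burden_corridor(self):
        """Without turnover, the burden under adaptive therapy only dips
        below the withdrawal threshold during an on-treatment step, and the
        controller withdraws immediately afterwards (one step of overshoot)."""
        p = SimParams(l=50, n0=0.75, f_R=0.01, d_T=0.0, t_end=700.0, seed=21)
        lat = seed_random(p, np.random.default_rng(21))
        baseline = lat.N
        series, out = run_simulation(p, AT50, lat)
        N, D = series["N"], series["D"]
        low = N < 0.5 * baseline
        # dips happen only while drug was applied on that step...
        assert (D[1:][low[1:]] > 0).all()
        # ...and drug is off on the following step (withdrawal triggered)
        dip_idx = np.nonzero(low[1:])[0] + 1
        follow = dip_idx[dip_idx + 1 < len(N)] + 1
        assert (D[follow] == 0).all()
        assert out.n_cycles >= 1

    def test_series_time_axis_and_count_sum(self, small_params, rng):
        lat = seed_random(small_params, rng)
        series, _ = run_simulation(small_params, AT50, lat)
        t = series["t"]
        assert np.allclose(np.diff(t), small_params.dt)
        assert np.array_equal(series["N"], series["S"] + series["R"])
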