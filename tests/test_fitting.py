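"""Burden-series fitting: objective, cohort generator, cycling, recovery."""

import numpy as np
import pytest

from latticetx import (
    FitConfig,
    PatientSeries,
    SimParams,
    cycling_speed,
    fit_patient,
    generate_synthetic_cohort,
    model_config,
    objective_rmse,
)
from latticetx.fitting import (
    MODEL2_FIXED,
    MODEL3_FIXED,
    aic_from_rss,
    read_cohort_csv,
    simulate_normalised,
    write_cohort_csv,
)


def toy_series(times=None, burden=None, intervals=((0.0, 1500.0),)):
    if times is None:
        times = np.arange(0.0, 361.0, 30.0)
    if burden is None:
        burden = np.ones_like(times)
    return PatientSeries(times=np.asarray(times, float), burden=np.asarray(burden, float),
                         intervals=intervals)


class TestPatientSeries:
    def test_validation(self):
        with pytest.raises(ValueError):
            PatientSeries(times=np.array([0.0, 0.0]), burden=np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            PatientSeries(times=np.array([0.0, 1.0]), burden=np.array([1.0, -1.0]))


class TestObjective:
    def test_rmse_matches_per_point_arithmetic(self):
        """RMSE agrees with an independent per-point re-implementation."""
        cfg = FitConfig(engine="ode", base_params=SimParams(l=40, n0=0.5, f_R=0.05))
        series = toy_series(times=np.array([30.0, 90.0, 150.0, 210.0, 300.0]),
                            burden=np.array([0.8, 0.5, 0.9, 1.1, 1.3]))
        values = {"c_R": 0.2, "d_T": 0.1}
        pred, _ = simulate_normalised(values, series, cfg, seeds=[0])
        expected = np.sqrt(sum((p - o) ** 2 for p, o in zip(pred, series.burden)) / 5)
        assert objective_rmse(values, series, cfg, seeds=[0]) == pytest.approx(expected, abs=1e-12)

    def test_self_consistency_near_zero(self):
        """A series that is the model's own trajectory fits with ~zero RMSE."""
        cfg = FitConfig(engine="ode", base_params=SimParams(n0=0.5, f_R=0.05))
        truth = {"c_R": 0.3, "d_T": 0.2}
        cohort = generate_synthetic_cohort(
            [dict(n0=0.5, f_R=0.05, **truth)], noise=0.0, rng=0, engine="ode", t_end=600.0,
        )
        assert objective_rmse(truth, cohort[0], cfg, seeds=[0]) < 1e-6

    def test_abm_objective_deterministic_under_common_random_numbers(self):
        cfg = FitConfig(engine="abm", n_replicates=3,
                        base_params=SimParams(l=30, n0=0.5, f_R=0.05))
        series = toy_series()
        v = {"c_R": 0.1, "d_T": 0.2}
        seeds = [11, 12, 13]
        assert objective_rmse(v, series, cfg, seeds) == objective_rmse(v, series, cfg, seeds)


class TestAIC:
    def test_formula(self):
        assert aic_from_rss(2.0, 10, 3) == pytest.approx(10 * np.log(0.2) + 6)

    def test_zero_free_parameters_degenerate_fit(self):
        cfg = FitConfig(free=(), fixed={"c_R": 0.2, "d_T": 0.1}, engine="ode",
                        base_params=SimParams(l=40, n0=0.5, f_R=0.05))
        series = toy_series()
        res = fit_patient(series, cfg, rng=np.random.default_rng(0))
        assert res.n_free == 0
        assert res.aic == pytest.approx(aic_from_rss(res.rmse**2 * res.n_obs, res.n_obs, 0))


class TestCyclingSpeed:
    def test_sawtooth_period(self):
        t = np.arange(0.0, 1081.0, 30.0)
        period = 180.0
        v = 0.75 + 0.5 * np.cos(2 * np.pi * t / period)  # dips to 0.25, peaks 1.25
        mean_len, cls = cycling_speed(t, v, baseline=1.0)
        assert mean_len == pytest.approx(period, abs=30.0)
        assert cls == "fast"

    def test_monotone_series_undefined(self):
        t = np.arange(0.0, 300.0, 30.0)
        assert cycling_speed(t, np.linspace(1, 2, t.size)) == (None, "undefined")

    def test_fast_cycler_has_shorter_cycles_than_slow(self):
        """High cost + low turnover cycles quickly; low cost + high turnover
        cycles slowly, because heavy turnover stalls the off-treatment
        regrowth of the sensitive population (lattice engine)."""
        fast_truth = dict(n0=0.59, f_R=0.04, c_R=0.8, d_T=0.1)
        slow_truth = dict(n0=0.59, f_R=0.04, c_R=0.1, d_T=0.6)
        cohort = generate_synthetic_cohort(
            [fast_truth, slow_truth], noise=0.0, rng=1, engine="abm",
            t_end=2500.0, cadence=10.0,
        )
        fast_len, _ = cycling_speed(cohort[0].times, cohort[0].burden)
        slow_len, _ = cycling_speed(cohort[1].times, cohort[1].burden)
        assert fast_len is not None
        assert slow_len is None or fast_len < slow_len


class TestSyntheticCohort:
    def test_baseline_normalised_to_one(self):
        truths = [dict(n0=0.5, f_R=0.04, c_R=0.4, d_T=0.2)] * 3
        cohort = generate_synthetic_cohort(truths, noise=0.2, rng=5, engine="ode", t_end=500.0)
        for s in cohort:
            assert s.burden[0] == pytest.approx(1.0)
            assert s.truth == truths[0]

    def test_noise_free_series_equals_trajectory(self):
        from latticetx.ode import ODEParams, solve_with_protocol
        from latticetx import AT50

        truth = dict(n0=0.5, f_R=0.04, c_R=0.3, d_T=0.1)
        cohort = generate_synthetic_cohort([truth], noise=0.0, rng=0, engine="ode",
                                           t_end=600.0, cadence=30.0)
        p = SimParams(t_end=600.0, **truth)
        sol = solve_with_protocol(ODEParams.from_sim_params(p), AT50, 600.0)
        expected = np.interp(cohort[0].times, sol.t, sol.N / sol.N[0])
        assert np.allclose(cohort[0].burden, expected, rtol=1e-9)

    def test_cohort_csv_roundtrip(self, tmp_path):
        truths = [dict(n0=0.5, f_R=0.04, c_R=0.4, d_T=0.2), dict(n0=0.5, f_R=0.04, c_R=0.1, d_T=0.3)]
        cohort = generate_synthetic_cohort(truths, noise=0.1, rng=2, engine="ode", t_end=400.0)
        path = tmp_path / "cohort.csv"
        write_cohort_csv(cohort, path)
        back = read_cohort_csv(path)
        assert len(back) == 2
        assert np.allclose(back[0].burden, cohort[0].burden)
        assert np.allclose(back[0].times, cohort[0].times)


class TestFitPatient:
    def test_recovers_parameters_on_noise_free_series(self):
        """Model-3 fit (free cost and turnover) recovers the generating
        values from a noise-free series driven by the recorded schedule."""
        truth = dict(c_R=0.35, d_T=0.25)
        cohort = generate_synthetic_cohort(
            [dict(**MODEL3_FIXED, **truth)], noise=0.0, rng=3, engine="ode", t_end=1200.0,
        )
        cfg = model_config(3, engine="ode", restarts=2, steps=4)
        res = fit_patient(cohort[0], cfg, rng=np.random.default_rng(7))
        assert res.params["c_R"] == pytest.approx(truth["c_R"], abs=0.1)
        assert res.params["d_T"] == pytest.approx(truth["d_T"], abs=0.1)
        assert res.rmse < 0.05

    def test_model_presets(self):
        assert model_config(1).free == ("n0", "f_R", "c_R", "d_T")
        assert model_config(1).n_steps == 75
        cfg2 = model_config(2)
        assert cfg2.free == ("n0", "f_R") and cfg2.fixed == MODEL2_FIXED
        assert cfg2.n_steps == 50
        cfg3 = model_config(3)
        assert cfg3.free == ("c_R", "d_T") and cfg3.fixed == MODEL3_FIXED
        with pytest.raises(ValueError):
            model_config(4)
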