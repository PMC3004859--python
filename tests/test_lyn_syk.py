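"""Lyn/Syk initiation model: forcing, steady states, simulation, sweeps
and parameter recovery."""

from dataclasses import replace

import numpy as np
import pytest

from bcrnet.lyn_syk import (
    OdeParameters,
    forcing,
    peak_response_sweep,
    recover_parameters,
    simulate,
    steady_state,
)
from bcrnet.synthetic import gen_trajectory


class TestParameters:
    def test_rejects_d1_not_exceeding_k2(self):
        with pytest.raises(ValueError, match="finite basal"):
            OdeParameters(d1=0.05, k2=0.05)

    def test_rejects_alpha_outside_unit_interval(self):
        with pytest.raises(ValueError, match="alpha"):
            OdeParameters(alpha=1.5)

    def test_json_round_trip(self, tmp_path, default_params):
        path = tmp_path / "params.json"
        default_params.to_json(path)
        assert OdeParameters.from_json(path) == default_params


class TestForcing:
    def test_ground_state_is_unity(self, default_params):
        p = replace(default_params, alpha=0.0)
        assert all(forcing(t, p) == 1.0 for t in (0.0, 5.0, 12.0, 50.0))

    def test_sine_maximum_dip(self, default_params):
        p = replace(default_params, alpha=0.5)
        t = p.t_trigger + p.omega / 4
        assert forcing(t, p) == pytest.approx(0.5)

    def test_pre_stimulus_is_unity(self, default_params):
        assert forcing(default_params.t_trigger - 1e-9, default_params) == 1.0

    def test_returns_to_unity_after_half_period(self, default_params):
        t = default_params.t_trigger + default_params.omega / 2 + 1e-9
        assert forcing(t, default_params) == 1.0


class TestSteadyState:
    # basal Lyn values cross-checked by long-time integration at alpha=0
    @pytest.mark.parametrize(
        "d1,expected_lp", [(0.25, 0.5), (1.1, 0.1 / 1.05)]
    )
    def test_lp_star_closed_form_matches_integration(self, d1, expected_lp):
        p = OdeParameters(k1=0.1, k2=0.05, d1=d1, alpha=0.0)
        lp_star, sm_star, sp_star = steady_state(p)
        assert lp_star == pytest.approx(expected_lp)
        # horizon spans many multiples of the slow Sm relaxation time 1/(k3*Lp*)
        t_end = 40.0 / (p.k3 * lp_star)
        traj = simulate(p, init=(0.01, 1.0, 0.0), t_end=t_end, dt_out=t_end / 6)
        assert traj.Lp[-1] == pytest.approx(lp_star, rel=1e-6)
        assert traj.Sp[-1] == pytest.approx(sp_star, rel=1e-5)

    def test_sp_star_independent_of_d1(self):
        # dSp/dt = 0 with dSm/dt = 0 forces k3*Sm*Lp = A, hence Sp* = A/d2
        expected = OdeParameters().A / OdeParameters().d2
        for d1 in (0.23, 0.5, 0.8, 1.2):
            assert steady_state(OdeParameters(d1=d1))[2] == pytest.approx(expected)

    def test_degenerate_rates_rejected(self, default_params):
        # d1 <= k2 is already rejected at construction; a vanishing k3
        # leaves Sm* undefined and must fail in the steady-state solve
        with pytest.raises(ValueError, match="k3"):
            steady_state(replace(default_params, k3=0.0))


class TestSimulate:
    def test_steady_state_is_fixed_point(self, default_params):
        p = replace(default_params, alpha=0.0)
        ss = steady_state(p)
        traj = simulate(p, init=ss, t_end=50.0, dt_out=1.0)
        for series, value in zip((traj.Lp, traj.Sm, traj.Sp), ss):
            assert np.allclose(series, value, rtol=1e-6)

    def test_lyn_rises_during_forcing_then_relaxes(self, default_params):
        p = default_params
        lp_star = steady_state(p)[0]
        traj = simulate(p, t_end=120.0, dt_out=0.05)
        window = (traj.t > p.t_trigger) & (traj.t <= p.t_trigger + p.omega / 2)
        assert traj.Lp[window].max() > lp_star * 1.2
        assert traj.Lp[-1] == pytest.approx(lp_star, rel=1e-4)

    def test_output_grid_independence(self, default_params):
        fine = simulate(default_params, t_end=40.0, dt_out=0.5)
        coarse = simulate(default_params, t_end=40.0, dt_out=1.0)
        shared = np.isin(fine.t, coarse.t)
        assert np.allclose(fine.Lp[shared], coarse.Lp, rtol=1e-6, atol=1e-8)

    def test_states_stay_non_negative_across_random_parameters(self, rng):
        for _ in range(20):
            k2 = rng.uniform(0.0, 0.2)
            p = OdeParameters(
                k1=rng.uniform(0.01, 0.5),
                k2=k2,
                k3=rng.uniform(0.001, 0.01),
                d1=k2 + rng.uniform(0.1, 1.0),
                d2=rng.uniform(0.1, 0.8),
                A=rng.uniform(0.01, 0.5),
                alpha=rng.uniform(0.0, 1.0),
            )
            traj = simulate(p, t_end=60.0, dt_out=0.5)
            assert min(traj.Lp.min(), traj.Sm.min(), traj.Sp.min()) >= 0.0


class TestPeakResponseSweep:
    def test_basal_lyn_strictly_decreasing_in_d1(self, default_params):
        sweep = peak_response_sweep(default_params, np.linspace(0.23, 1.2, 8))
        assert (np.diff(sweep.Lp_star) < 0).all()

    def test_inverse_basal_sensitivity(self, default_params):
        # the central prediction: the higher the basal Lyn activity, the
        # weaker the (fold) response to receptor engagement
        sweep = peak_response_sweep(default_params, np.linspace(0.23, 1.2, 8))
        ordered = sweep.sort_values("Lp_star")
        assert (np.diff(ordered.peak_fold) < 0).all()

    def test_no_forcing_peak_equals_basal(self, default_params):
        p = replace(default_params, alpha=0.0)
        sweep = peak_response_sweep(p, [0.3, 0.6, 1.0], t_end=30.0)
        assert np.allclose(sweep.peak, sweep.Lp_star, rtol=1e-6)
        assert np.allclose(sweep.peak_fold, 1.0, rtol=1e-6)


class TestRecoverParameters:
    def test_noise_free_d1_identifiable(self, default_params):
        grid = np.arange(0.0, 40.0 + 1e-9, 0.25)
        traj = gen_trajectory(default_params, grid, noise_sd=0.0)
        start = replace(default_params, d1=0.6)
        fit = recover_parameters(traj, start, ["d1"])
        assert fit.converged
        assert fit.estimates["d1"] == pytest.approx(default_params.d1, rel=1e-4)

    def test_no_free_parameters_returns_pure_residual(self, default_params):
        grid = np.arange(0.0, 20.0 + 1e-9, 0.5)
        traj = gen_trajectory(default_params, grid, noise_sd=0.0)
        fit = recover_parameters(traj, default_params, [])
        assert fit.estimates == {}
        assert fit.residual_norm == pytest.approx(0.0, abs=1e-6)

    def test_unknown_parameter_name_rejected(self, default_params):
        grid = np.arange(0.0, 10.0 + 1e-9, 0.5)
        traj = gen_trajectory(default_params, grid)
        with pytest.raises(ValueError, match="unknown"):
            recover_parameters(traj, default_params, ["omega"])


class TestGenTrajectory:
    def test_zero_noise_equals_simulation(self, default_params):
        grid = np.arange(0.0, 30.0 + 1e-9, 0.5)
        traj = gen_trajectory(default_params, grid, noise_sd=0.0, seed=1)
        ref = simulate(default_params, t_end=30.0, dt_out=0.5)
        assert np.array_equal(traj.Lp, ref.Lp)

    def test_reproducible_under_seed(self, default_params):
        grid = np.arange(0.0, 30.0 + 1e-9, 0.5)
        a = gen_trajectory(default_params, grid, noise_sd=0.01, seed=5)
        b = gen_trajectory(default_params, grid, noise_sd=0.01, seed=5)
        assert np.array_equal(a.Lp, b.Lp) and np.array_equal(a.Sp, b.Sp)

    def test_noise_floored_at_zero(self, default_params):
        grid = np.arange(0.0, 30.0 + 1e-9, 0.5)
        traj = gen_trajectory(default_params, grid, noise_sd=0.5, seed=2)
        assert min(traj.Lp.min(), traj.Sm.min(), traj.Sp.min()) >= 0.0
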