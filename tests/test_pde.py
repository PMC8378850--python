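"""Implicit density/oxygen solver: operators, conservation, convergence."""

import math

import numpy as np
import pytest

from aeroring.params import MeanFieldParams
from aeroring.pde import (
    PDESolution,
    ScalarField1D,
    advection_speed,
    consumption,
    front_position,
    measure_front_speed,
    simulate,
    step,
    total_mass,
)


def make_fields(n=400, dx=1.0, C_values=None, rho_values=None, geometry="planar"):
    origin = dx / 2 if geometry == "radial" else 0.0
    rho = ScalarField1D(
        rho_values if rho_values is not None else np.zeros(n), dx, geometry, origin
    )
    C = ScalarField1D(
        C_values if C_values is not None else np.full(n, 21.0), dx, geometry, origin
    )
    return rho, C


class TestScalarField:
    def test_rejects_bad_grids(self):
        with pytest.raises(ValueError):
            ScalarField1D(np.array([1.0, 2.0]), 1.0)
        with pytest.raises(ValueError):
            ScalarField1D(np.array([1.0, np.nan, 2.0]), 1.0)
        with pytest.raises(ValueError):
            ScalarField1D(np.zeros(5), -1.0)
        with pytest.raises(ValueError):
            ScalarField1D(np.zeros(5), 1.0, "radial", origin=-2.0)


class TestAdvection:
    def test_uniform_oxygen_gives_zero_advection(self, mf_params):
        _, C = make_fields()
        a = advection_speed(C, "go_or_grow", mf_params)
        assert np.all(a == 0.0)

    def test_below_lower_threshold_two_threshold_model_is_insensitive(self, mf_params):
        n = 100
        C = ScalarField1D(np.linspace(0.01, 0.09, n), 1.0)
        a2 = advection_speed(C, "two_threshold", mf_params)
        assert np.all(a2 == 0.0)
        # ... while the single-threshold model still advects at full speed
        a1 = advection_speed(C, "go_or_grow", mf_params)
        assert np.all(a1 == mf_params.a0)

    def test_piecewise_switch_at_upper_threshold(self, mf_params):
        n = 100
        C = ScalarField1D(np.linspace(0.3, 1.1, n), 1.0)
        a = advection_speed(C, "go_or_grow", mf_params)
        Cface = 0.5 * (C.values[1:] + C.values[:-1])
        assert np.all(a[Cface < 0.7] == mf_params.a0)
        assert np.all(a[Cface >= 0.7] == 0.0)

    def test_unknown_model_tag(self, mf_params):
        _, C = make_fields()
        with pytest.raises(ValueError, match="unknown model"):
            advection_speed(C, "nope", mf_params)


class TestConsumption:
    @pytest.mark.parametrize(
        "C,expected", [(0.0, 0.0), (0.1, 0.01), (0.05, 0.005), (21.0, 0.01)]
    )
    def test_capped_ramp(self, mf_params, C, expected):
        val = consumption(np.array([C]), mf_params)[0]
        assert val == pytest.approx(expected)


class TestStep:
    def test_pure_diffusion_conserves_mass(self, mf_params):
        """No growth (C < C0 uniform -> r = 0, a = 0): total mass drifts by
        < 1e-8 relative over 1000 steps."""
        n = 500
        rho, C = make_fields(
            n, C_values=np.full(n, 0.5), rho_values=np.exp(-((np.arange(n) - 250.0) ** 2) / 200.0)
        )
        # freeze oxygen uniform: no gradient, no advection; C<C0 disables growth
        m0 = total_mass(rho)
        for _ in range(1000):
            rho, _C = step(rho, C, mf_params, 0.02, "go_or_grow")
        assert abs(total_mass(rho) - m0) / m0 < 1e-8

    def test_radial_diffusion_conserves_mass(self, mf_params):
        n = 300
        vals = np.exp(-((np.arange(n) + 0.5 - 150.0) ** 2) / 200.0)
        rho, C = make_fields(n, C_values=np.full(n, 0.5), rho_values=vals,
                             geometry="radial")
        m0 = total_mass(rho)
        for _ in range(500):
            rho, _ = step(rho, C, mf_params, 0.02, "go_or_grow")
        assert abs(total_mass(rho) - m0) / m0 < 1e-8

    def test_no_consumers_leaves_saturated_oxygen_alone(self, mf_params):
        rho, C = make_fields(200)
        _, C2 = step(rho, C, mf_params, 0.02, "go_or_grow")
        assert np.allclose(C2.values, 21.0)

    def test_gaussian_variance_grows_at_2D_dt(self, mf_params):
        """Moment analysis: for pure diffusion d(var)/dt = 2 D."""
        n, dx = 2001, 1.0
        x = np.arange(n) * dx
        sig0 = 20.0
        rho, C = make_fields(n, dx, C_values=np.full(n, 0.5),
                             rho_values=np.exp(-((x - 1000.0) ** 2) / (2 * sig0**2)))
        dt, nsteps = 0.02, 500

        def variance(f):
            w = f.values / f.values.sum()
            mu = (x * w).sum()
            return ((x - mu) ** 2 * w).sum()

        v0 = variance(rho)
        for _ in range(nsteps):
            rho, _ = step(rho, C, mf_params, dt, "go_or_grow")
        growth = (variance(rho) - v0) / (nsteps * dt)
        assert growth == pytest.approx(2 * mf_params.D, rel=0.01)

    def test_mass_balance_with_growth(self, mf_params):
        """d/dt int(rho) = int(r(C) rho) when division is active."""
        n = 300
        rho, C = make_fields(n, rho_values=np.full(n, 100.0))
        dt = 0.02
        m0 = total_mass(rho)
        for _ in range(200):
            rho, _ = step(rho, C, mf_params, dt, "go_or_grow")
        expected = m0 * math.exp(mf_params.r0 * 200 * dt)
        assert total_mass(rho) == pytest.approx(expected, rel=1e-4)

    def test_mismatched_grids_rejected(self, mf_params):
        rho, _ = make_fields(100)
        _, C = make_fields(200)
        with pytest.raises(ValueError, match="share the grid"):
            step(rho, C, mf_params, 0.02)


class TestFrontMeasurement:
    def test_exact_line_recovered(self):
        t = np.arange(0.0, 100.0, 1.0)
        sol = PDESolution(times=t, rho_snapshots=[], C_snapshots=[],
                          front_times=t, front_positions=100.0 + 1.3 * t)
        assert measure_front_speed(sol, (0, 100)) == pytest.approx(1.3)

    def test_noisy_line_within_confidence(self, rng):
        t = np.arange(0.0, 400.0, 1.0)
        pos = 50.0 + 0.7 * t + rng.normal(0, 5.0, t.size)
        sol = PDESolution(times=t, rho_snapshots=[], C_snapshots=[],
                          front_times=t, front_positions=pos)
        slope = measure_front_speed(sol, (0, 400))
        se = 5.0 / math.sqrt(np.sum((t - t.mean()) ** 2))
        assert slope == pytest.approx(0.7, abs=4 * se)

    def test_stationary_front_gives_zero(self):
        t = np.arange(0.0, 50.0, 1.0)
        sol = PDESolution(times=t, rho_snapshots=[], C_snapshots=[],
                          front_times=t, front_positions=np.full(t.size, 77.0))
        assert measure_front_speed(sol, (0, 50)) == pytest.approx(0.0)

    def test_no_crossing_in_window_raises(self):
        t = np.arange(0.0, 50.0, 1.0)
        sol = PDESolution(times=t, rho_snapshots=[], C_snapshots=[],
                          front_times=t, front_positions=np.full(t.size, np.nan))
        with pytest.raises(ValueError):
            measure_front_speed(sol, (0, 50))

    def test_front_position_interpolates_crossing(self, mf_params):
        C = ScalarField1D(np.linspace(0.0, 1.4, 141), 1.0)
        # crossing of 0.7 exactly at x = 70
        assert front_position(C, 0.7) == pytest.approx(70.0)


class TestSimulate:
    def test_positivity_and_snapshot_bookkeeping(self, mf_params):
        p = MeanFieldParams(L=2000.0)
        n = 2001
        x = np.arange(n) * 1.0
        rho = ScalarField1D(np.where(x < 500, 300.0, 0.0), 1.0)
        C = ScalarField1D(np.full(n, 21.0), 1.0)
        sol = simulate(rho, C, p, t_end=20.0, dt=0.02, model="go_or_grow",
                       snapshot_every=10.0, front_every=1.0)
        assert len(sol.times) == len(sol.rho_snapshots) == len(sol.C_snapshots)
        for f in sol.rho_snapshots + sol.C_snapshots:
            assert np.all(f.values >= -1e-9)

    def test_convergence_of_front_speed_under_mesh_refinement(self):
        """Halving dx and dt changes the measured speed by < 2 %."""
        from aeroring.synth import gen_initial_profiles

        speeds = []
        for dx, dt in [(4.0, 0.08), (2.0, 0.04)]:
            p = MeanFieldParams(a0=1.0, L=5000.0)
            rho0, C0 = gen_initial_profiles("near_wave", p, dx=dx,
                                            front_at=1200.0, plateau_density=100.0)
            sol = simulate(rho0, C0, p, t_end=300.0, dt=dt, model="go_or_grow",
                           snapshot_every=150.0, front_every=5.0)
            speeds.append(measure_front_speed(sol, (150.0, 300.0)))
        assert abs(speeds[1] - speeds[0]) / speeds[1] < 0.02
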