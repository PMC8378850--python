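"""Closed-form wave theory: speed dichotomy, profiles, two-threshold search."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aeroring.params import MeanFieldParams
from aeroring.waves import (
    explicit_profile,
    fisher_speed,
    phi_heatmap,
    potts_unit_conversions,
    shape_speed_estimate,
    speed_formula,
    two_threshold_speed,
)

R0_DEFAULT = math.log(2) / 480.0


class TestSpeedFormula:
    def test_published_operating_point(self):
        res = speed_formula(1.0, R0_DEFAULT, 30.0)
        assert res.sigma == pytest.approx(1.04, abs=0.005)
        assert res.regime == "large_bias"
        assert 100 * res.phi == pytest.approx(40.0, abs=0.5)

    def test_no_bias_gives_fisher_speed_and_phi_one(self):
        res = speed_formula(0.0, R0_DEFAULT, 30.0)
        assert res.sigma == pytest.approx(fisher_speed(R0_DEFAULT, 30.0))
        assert res.phi == 1.0
        assert res.regime == "small_bias"

    def test_branches_agree_at_the_dichotomy(self):
        a0 = math.sqrt(R0_DEFAULT * 30.0)
        res = speed_formula(a0, R0_DEFAULT, 30.0)
        assert res.sigma == pytest.approx(a0 + R0_DEFAULT * 30.0 / a0)
        assert res.sigma == pytest.approx(2.0 * a0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        a0=st.floats(0.0, 5.0),
        r0=st.floats(1e-5, 1e-2),
        D=st.floats(1.0, 100.0),
        da=st.floats(0.0, 1.0),
    )
    def test_monotone_in_inputs_and_above_fisher(self, a0, r0, D, da):
        base = speed_formula(a0, r0, D).sigma
        assert base >= fisher_speed(r0, D) - 1e-12
        assert speed_formula(a0 + da, r0, D).sigma >= base - 1e-12
        assert speed_formula(a0, r0 * 1.5, D).sigma >= base - 1e-12
        assert speed_formula(a0, r0, D * 1.5).sigma >= base - 1e-12


class TestShapeEstimate:
    def test_published_example(self):
        # ring length 300 um, peak/bulk ratio 4, doubling time 8 h
        assert shape_speed_estimate(300.0, 4.0, R0_DEFAULT) == pytest.approx(
            0.9, abs=0.05
        )

    def test_zero_ring_length(self):
        assert shape_speed_estimate(0.0, 4.0, R0_DEFAULT) == 0.0

    def test_against_simulated_profile(self, mf_params):
        """On a simulated Go-or-Grow wave the estimate (ring length at
        half-peak, measured density ratio) lands within 25 % of the
        measured front speed."""
        from aeroring.pde import measure_front_speed, simulate
        from aeroring.synth import gen_initial_profiles

        p = MeanFieldParams(a0=1.0, L=6000.0)
        rho0, C0 = gen_initial_profiles("near_wave", p, dx=2.0, front_at=1500.0,
                                        plateau_density=100.0)
        sol = simulate(rho0, C0, p, t_end=400.0, dt=0.05, model="go_or_grow",
                       snapshot_every=200.0, front_every=5.0)
        sigma = measure_front_speed(sol, (200.0, 400.0))
        rho = sol.rho_snapshots[-1].values
        x = sol.rho_snapshots[-1].x
        peak = rho.max()
        bulk = rho[(x > 500) & (x < 1000)].mean()
        half = peak / 2.0
        above = np.where(rho >= half)[0]
        L_ring = x[above[-1]] - x[above[0]]
        est = shape_speed_estimate(L_ring, peak / bulk, p.r0)
        assert est == pytest.approx(sigma, rel=0.25)


class TestExplicitProfile:
    def test_decay_rate_is_a0_over_D(self):
        prof = explicit_profile(1.0, R0_DEFAULT, 30.0, "elementary")
        z = np.array([10.0, 50.0])
        ratio = prof(z[1]) / prof(z[0])
        assert ratio == pytest.approx(math.exp(-(1.0 / 30.0) * 40.0))

    def test_far_field_plateau(self):
        prof = explicit_profile(1.0, R0_DEFAULT, 30.0, "elementary", A=123.0)
        assert prof.plateau == pytest.approx(123.0)
        assert prof(np.array([-1e5]))[0] == pytest.approx(123.0)

    def test_ode_residual_vanishes_on_both_sides(self):
        """The profile satisfies -sigma rho' = D rho'' - a0 rho' (z<0) and
        -sigma rho' = D rho'' + r0 rho (z>0) pointwise."""
        a0, r0, D = 1.0, R0_DEFAULT, 30.0
        prof = explicit_profile(a0, r0, D, "elementary")
        sig = prof.sigma
        # z < 0: rho is constant, every term vanishes identically.
        # z > 0: rho = A e^{mu_- z} with mu_- = -a0/D; the residual per unit
        # rho is the characteristic polynomial D mu^2 + sigma mu + r0.
        mu = -a0 / D
        residual = D * mu**2 + sig * mu + r0
        assert abs(residual) < 1e-12
        # and on a fine grid, central differences agree to their truncation
        h = 1e-2
        for z0 in [1.0, 25.0]:
            z = np.array([z0 - h, z0, z0 + h])
            rho = prof(z)
            d1 = (rho[2] - rho[0]) / (2 * h)
            d2 = (rho[2] - 2 * rho[1] + rho[0]) / h**2
            res = sig * d1 + D * d2 + r0 * rho[1]
            assert abs(res) < 1e-6 * max(1.0, rho[1])

    def test_flux_jump_relation_at_origin(self):
        """D [rho'](0) = -a0 rho(0): the advective influx is absorbed by the
        kink of the growth-region exponential."""
        a0, D = 1.0, 30.0
        prof = explicit_profile(a0, R0_DEFAULT, D, "elementary")
        h = 1e-6
        d_right = (prof(np.array([h]))[0] - prof(np.array([0.0]))[0]) / h
        d_left = 0.0  # plateau
        assert D * (d_right - d_left) == pytest.approx(
            -a0 * prof(np.array([0.0]))[0], rel=1e-4
        )

    def test_small_bias_elementary_profile_rejected(self):
        with pytest.raises(ValueError, match="large-bias"):
            explicit_profile(0.1, R0_DEFAULT, 30.0, "elementary")


class TestTwoThreshold:
    def test_sigma_within_bracket_and_near_elementary_at_defaults(self, mf_params):
        sigma, h = two_threshold_speed(mf_params)
        lo = fisher_speed(mf_params.r0, mf_params.D)
        hi = speed_formula(mf_params.a0, mf_params.r0, mf_params.D).sigma
        assert lo <= sigma <= hi
        assert h > 0
        assert sigma == pytest.approx(hi, rel=1e-3)

    def test_scan_stays_within_15_percent_of_elementary(self):
        max_dev = 0.0
        for a0 in np.linspace(0.2, 2.0, 7):
            for td_h in np.linspace(4.0, 16.0, 5):
                p = MeanFieldParams(a0=float(a0), r0=math.log(2) / (td_h * 60.0))
                s2, _ = two_threshold_speed(p)
                s1 = speed_formula(p.a0, p.r0, p.D).sigma
                max_dev = max(max_dev, abs(s2 - s1) / s1)
        assert max_dev <= 0.15

    def test_limit_thresholds_merging_gives_fisher(self):
        """As C0p -> C0 the advection band vanishes and the front is a pure
        division-diffusion (Fisher) wave."""
        p = MeanFieldParams(C0p=0.699, C0=0.7)
        sigma, h = two_threshold_speed(p)
        assert sigma == pytest.approx(fisher_speed(p.r0, p.D), rel=0.01)

    def test_limit_deep_second_threshold_recovers_elementary(self):
        """Pushing C0p far below C0 sends the gap h to infinity and recovers
        the single-threshold speed."""
        p = MeanFieldParams(C0p=1e-4, C0=0.7)
        sigma, _ = two_threshold_speed(p)
        hi = speed_formula(p.a0, p.r0, p.D).sigma
        assert sigma == pytest.approx(hi, rel=1e-4)

    def test_small_bias_returns_fisher(self):
        p = MeanFieldParams(a0=0.05)
        sigma, h = two_threshold_speed(p)
        assert sigma == pytest.approx(fisher_speed(p.r0, p.D))
        assert math.isinf(h)


class TestPhiHeatmap:
    def test_separatrix_matches_regime_boundary(self):
        tds = np.linspace(120.0, 1200.0, 12)
        a0s = np.linspace(0.05, 2.0, 30)
        phi = phi_heatmap(a0s, tds, D=30.0)
        for i, td in enumerate(tds):
            crit = math.sqrt(math.log(2) / td * 30.0)
            pulled = a0s <= crit
            assert np.all(phi[i, pulled] == 1.0)
            assert np.all(phi[i, ~pulled] < 1.0)


class TestUnitConversions:
    def test_consumption_boundary_flux_and_division_probability(self):
        conv = potts_unit_conversions()
        assert conv["consumption_per_pixel"] == pytest.approx(0.1, rel=0.01)
        assert conv["boundary_flux_mol_m2_s"] == pytest.approx(6e-8, rel=0.01)
        assert conv["division_prob"] == pytest.approx(1.0 / 288000.0)
        assert conv["division_prob_printed"] == pytest.approx(3e-6)
        assert conv["mol_per_pixel_at_21"] == pytest.approx(1.25e-15, rel=0.01)
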