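"""Coupled gas exchange: supply-demand intersection, Penman-Monteith,
leaf energy balance."""

import numpy as np
import pytest

from leafgas import (BiochemParams, EnvironmentalDrivers, NoSolutionError,
                     demand_at_ci, ite_closed_form, penman_monteith,
                     photosyn_coupled, photosyn_eb, photosyn_given_ci,
                     photosyn_given_gs, supply_an, vpd_from_tair_empirical)
from leafgas.coupled import boundary_layer_conductance
from leafgas.fvcb import DomainError


class TestSupply:
    def test_zero_at_ci_equals_ca(self):
        assert supply_an(0.2, 400.0, 400.0) == 0.0

    def test_closed_stomata(self):
        assert supply_an(0.0, 400.0, 100.0) == 0.0

    def test_hand_arithmetic(self):
        assert supply_an(0.16, 400.0, 300.0) == pytest.approx(10.0)

    def test_negative_gs_rejected(self):
        with pytest.raises(DomainError):
            supply_an(-0.1, 400.0, 300.0)


class TestGivenCi:
    def test_compensation_point(self, env, params):
        gs25 = params.gammastar_at(25.0)
        sol = photosyn_given_ci(env, params, gs25)
        assert sol.an == pytest.approx(-params.rd_at(25.0), abs=1e-9)

    def test_matches_demand_function(self, env, params):
        for ci in (100.0, 250.0, 700.0):
            sol = photosyn_given_ci(env, params, ci)
            d = demand_at_ci(ci, params, tleaf=env.tleaf, par=env.par)
            assert sol.an == pytest.approx(d.an[0], abs=1e-12)

    def test_monotone_in_ci(self, env, params):
        an = [photosyn_given_ci(env, params, c).an
              for c in np.linspace(50, 1500, 60)]
        assert np.all(np.diff(an) >= -1e-9)


class TestGivenGs:
    def test_large_gs_reaches_ca(self, env, params):
        sol = photosyn_given_gs(env, params, 1e6)
        assert sol.ci == pytest.approx(env.ca, rel=1e-4)
        d = demand_at_ci(env.ca, params, tleaf=env.tleaf, par=env.par)
        assert sol.an == pytest.approx(d.an[0], rel=1e-4)

    def test_zero_gs_finds_net_compensation(self, env, params):
        sol = photosyn_given_gs(env, params, 0.0)
        assert sol.an == pytest.approx(0.0, abs=1e-9)
        # independent bisection on the demand function
        lo, hi = 1.0, 2000.0
        f = lambda c: demand_at_ci(c, params, tleaf=25.0,
                                   par=env.par).an[0]
        for _ in range(200):
            m = 0.5 * (lo + hi)
            if f(lo) * f(m) <= 0:
                hi = m
            else:
                lo = m
        assert sol.ci == pytest.approx(0.5 * (lo + hi), abs=1e-5)

    def test_residual_tiny_for_random_draws(self, env, rng):
        for _ in range(100):
            p = BiochemParams(vcmax25=rng.uniform(20, 150),
                              jmax25=rng.uniform(50, 300),
                              rd25=rng.uniform(0.3, 3.0))
            gs = rng.uniform(0.01, 1.0)
            e = EnvironmentalDrivers(par=rng.uniform(100, 2000),
                                     tleaf=rng.uniform(5, 40),
                                     ca=rng.uniform(200, 900))
            sol = photosyn_given_gs(e, p, gs)
            dem = demand_at_ci(sol.ci, p, tleaf=e.tleaf, par=e.par).an[0]
            assert abs(dem - supply_an(gs, e.ca, sol.ci)) < 1e-8


class TestCoupled:
    def test_three_equations_hold(self, env, params):
        from leafgas import gs_predict
        sol = photosyn_coupled(env, params, g0=0.01, g1=4.0)
        dem = demand_at_ci(sol.ci, params, tleaf=env.tleaf,
                           par=env.par).an[0]
        assert abs(dem - supply_an(sol.gs, env.ca, sol.ci)) < 1e-8
        gs_model = gs_predict("medlyn_opti", 0.01, 4.0, dem, env.ca,
                              d=env.vpd)
        assert abs(gs_model - sol.gs) < 1e-10

    def test_agrees_with_given_gs_mode(self, env, params):
        sol = photosyn_coupled(env, params, g0=0.0, g1=4.0)
        again = photosyn_given_gs(env, params, sol.gs)
        assert again.ci == pytest.approx(sol.ci, abs=1e-6)

    def test_ite_matches_closed_form(self, env, params):
        sol = photosyn_coupled(env, params, g0=0.0, g1=4.0)
        assert sol.ite == pytest.approx(
            ite_closed_form(env.ca, env.pa, 4.0, env.vpd), rel=1e-6)

    def test_night_with_zero_g0_flagged(self, params):
        env = EnvironmentalDrivers(par=0.0)
        with pytest.raises(NoSolutionError):
            photosyn_coupled(env, params, g0=0.0, g1=4.0)

    def test_night_with_positive_g0_uses_floor(self, params):
        env = EnvironmentalDrivers(par=0.0)
        sol = photosyn_coupled(env, params, g0=0.02, g1=4.0)
        assert sol.gs == pytest.approx(0.02)
        assert sol.an < 0.0
        assert sol.ci > env.ca  # respiring leaf accumulates CO2 inside

    def test_vpd_floor_clamped_with_warning(self, params):
        env = EnvironmentalDrivers(vpd=0.001)
        with pytest.warns(UserWarning):
            sol = photosyn_coupled(env, params, g0=0.0, g1=4.0)
        assert np.isfinite(sol.an)

    def test_continuity_in_ca(self, params):
        env0 = EnvironmentalDrivers()
        ans = []
        for ca in np.arange(250.0, 800.0, 1.0):
            sol = photosyn_coupled(
                EnvironmentalDrivers(ca=ca), params, g0=0.01, g1=4.0)
            ans.append(sol.an)
        steps = np.abs(np.diff(ans))
        assert steps.max() < 0.2  # no branch jumps

    def test_temperature_demo_shape(self, params):
        """Peaked An and monotonically declining Ci along the empirical
        field Tleaf-D trajectory."""
        tleafs = np.arange(5.0, 41.0, 5.0)
        an, ci = [], []
        for t in tleafs:
            sol = photosyn_coupled(
                EnvironmentalDrivers(tleaf=t,
                                     vpd=vpd_from_tair_empirical(t)),
                params, g0=0.0, g1=4.0)
            an.append(sol.an)
            ci.append(sol.ci)
        an, ci = np.array(an), np.array(ci)
        i = int(an.argmax())
        assert 0 < i < len(tleafs) - 1
        assert np.all(np.diff(an[:i + 1]) > 0)
        assert np.all(np.diff(an[i:]) < 0)
        assert np.all(np.diff(ci) < 0)


class TestPenmanMonteith:
    def test_zero_when_closed_and_dark(self):
        assert penman_monteith(0.0, 1.5, 25.0, 0.0, 1.0) == 0.0

    def test_perfect_coupling_limit(self):
        e = penman_monteith(0.0, 1.5, 25.0, 0.2, 1e6, pa=101.3)
        assert e == pytest.approx(0.2 * 1.5 / 101.3 * 1000.0, rel=5e-3)

    def test_increasing_in_d(self):
        es = [penman_monteith(300.0, d, 25.0, 0.3, 1.5) for d in
              np.linspace(0.2, 3.0, 30)]
        assert np.all(np.diff(es) > 0)

    def test_nonpositive_gbl_rejected(self):
        with pytest.raises(DomainError):
            penman_monteith(300.0, 1.5, 25.0, 0.3, 0.0)


class TestEnergyBalance:
    def test_tleaf_tracks_tair_at_infinite_wind_no_radiation(self, params):
        env = EnvironmentalDrivers(tleaf=25.0, rnet=0.0, wind=1e6,
                                   leaf_width=0.02)
        sol = photosyn_eb(env, params, g1=4.0)
        assert sol.converged
        assert abs(sol.tleaf - 25.0) < 0.01

    def test_energy_closure(self, params):
        env = EnvironmentalDrivers(tleaf=25.0, rnet=400.0, wind=2.0)
        sol = photosyn_eb(env, params, g1=4.0)
        assert sol.converged
        assert abs(sol.closure) < 0.5

    def test_radiation_warms_leaf(self, params):
        sols = [photosyn_eb(EnvironmentalDrivers(tleaf=25.0, rnet=r),
                            params, g1=4.0).tleaf
                for r in (0.0, 200.0, 400.0)]
        assert sols[0] < sols[1] < sols[2]

    def test_boundary_layer_formula(self):
        gbh, gbw = boundary_layer_conductance(2.0, 0.02)
        assert gbh == pytest.approx(0.135 * np.sqrt(100.0))
        assert gbw == pytest.approx(0.147 * np.sqrt(100.0))
        with pytest.raises(DomainError):
            boundary_layer_conductance(0.0, 0.02)
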