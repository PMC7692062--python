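"""Moving-boundary solver: boundary fluxes, fixed points, conservation,
grid convergence and failure modes."""

import numpy as np
import pytest

import drysphere as ds
from drysphere import thermophysical as tp
from drysphere.core import boundary_heat_flux, boundary_mass_flux, shrinkage_velocity

COMP = tp.ProductComposition()
ISO = tp.HendersonIsotherm()
STARTUP = ds.AmbientConditions(288.15, 0.8, 0.1)


def continuous_program(T=323.15, RH=0.15, U=1.28, t_h=30.0, startup=None):
    return ds.CycleProgram(stages=(ds.Stage(t_h, T, RH, U, "C"),), startup=startup)


class TestShrinkageVelocity:
    sigma = np.linspace(0.0, 1.0, 41)

    def test_uniform_profile_gives_zero(self):
        v = shrinkage_velocity(np.full(41, 0.8), 2e-10, self.sigma, 0.03, 1.0)
        np.testing.assert_allclose(v, 0.0, atol=1e-20)

    def test_rigid_solid_gives_zero(self):
        phi = 0.9 - 0.3 * self.sigma**2
        v = shrinkage_velocity(phi, 2e-10, self.sigma, 0.03, 0.0)
        np.testing.assert_allclose(v, 0.0)

    def test_linear_profile_recovers_slope(self):
        phi = 0.9 - 0.4 * self.sigma
        R, D, a0 = 0.03, 2e-10, 0.7
        v = shrinkage_velocity(phi, D, self.sigma, R, a0)
        np.testing.assert_allclose(v[1:-1], a0 * D * (-0.4) / R, rtol=1e-10)
        assert np.all(v <= 0)  # moisture decreasing outward -> inward motion


class TestBoundaryMassFlux:
    amb = ds.AmbientConditions(313.15, 0.4, 1.28)

    def test_zero_at_vapor_pressure_equilibrium(self):
        X_eq = ISO.moisture(self.amb.RH_inf, self.amb.T_inf)
        phi_eq = tp.phi_from_moisture(X_eq, COMP)
        F = boundary_mass_flux(phi_eq, self.amb.T_inf, self.amb, 0.02, ISO, COMP)
        # roundoff floor: typical drying fluxes are ~1e-8 m/s
        assert F == pytest.approx(0.0, abs=1e-15)

    def test_positive_into_dry_air(self):
        amb_dry = ds.AmbientConditions(313.15, 0.0, 1.28)
        assert boundary_mass_flux(0.5, 313.15, amb_dry, 0.02, ISO, COMP) > 0

    def test_condensation_for_cold_wet_air_on_dry_surface(self):
        amb_humid = ds.AmbientConditions(290.15, 0.8, 0.1)
        assert boundary_mass_flux(0.01, 290.15, amb_humid, 0.02, ISO, COMP) < 0

    def test_isothermal_limit_reduces_to_single_pressure_form(self):
        """At T_b = T_inf the flux collapses to
        (h_m Mw / rho_w) (pv/Rg T) (RH_b - RH_inf)."""
        T = 313.15
        phi_b, h_m = 0.4, 0.02
        amb = ds.AmbientConditions(T, 0.3, 1.28)
        F = boundary_mass_flux(phi_b, T, amb, h_m, ISO, COMP)
        rh_b = ISO.rh(tp.moisture_from_phi(phi_b, COMP), T)
        expected = h_m * tp.MW_WATER / COMP.rho_w * tp.saturation_pressure(T) / (
            tp.RG * T) * (rh_b - 0.3)
        assert F == pytest.approx(expected, rel=1e-12)


class TestBoundaryHeatFlux:
    amb = ds.AmbientConditions(313.15, 0.15, 1.28)

    def test_zero_without_evaporation_at_equal_temperature(self):
        assert boundary_heat_flux(313.15, self.amb, 20.0, 0.0, COMP) == 0.0

    def test_cold_sample_heats_without_evaporation(self):
        # outward flux negative = heat flows into the sample
        assert boundary_heat_flux(288.15, self.amb, 20.0, 0.0, COMP) < 0

    def test_evaporation_cools_at_equal_temperature(self):
        q = boundary_heat_flux(313.15, self.amb, 20.0, 1e-7, COMP)
        assert q > 0  # outward: surface temperature tendency negative


class TestSimulateFixedPointsAndBalances:
    def test_equilibrium_ambient_is_a_fixed_point(self):
        X0 = 0.3
        rh_eq = ISO.rh(X0, 313.15)
        params = ds.MaterialParams(X0=X0, d0=0.05, T0=313.15)
        prog = continuous_program(T=313.15, RH=rh_eq, U=1.0, t_h=10.0)
        traj = ds.simulate(params, prog, ds.SolverSettings(variant="full", n_nodes=64))
        assert np.abs(traj.profiles_phi - traj.profiles_phi[0]).max() < 1e-6
        assert abs(traj.R_ratio[-1] - 1.0) < 1e-9

    def test_moisture_monotone_under_continuous_drying(self):
        params = ds.MaterialParams(X0=5.55, d0=0.0524)
        traj = ds.simulate(
            params, continuous_program(t_h=20.0),
            ds.SolverSettings(variant="full", n_nodes=80),
        )
        assert np.all(np.diff(traj.X_ratio) <= 1e-9)
        assert traj.X_ratio[0] == pytest.approx(1.0, abs=1e-12)
        assert traj.V_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_water_balance_closes_against_boundary_outflow(self):
        """d/dt of the water inventory equals the evaporative surface flux:
        the cumulative loss matches the independently integrated outflow."""
        params = ds.MaterialParams(X0=5.55, d0=0.0524)
        traj = ds.simulate(
            params, continuous_program(t_h=25.0),
            ds.SolverSettings(variant="full", n_nodes=80),
        )
        loss = 1.0 - traj.X_ratio
        mism = np.abs(loss - traj.evaporated_ratio)
        assert mism[-1] < 1e-3 * max(loss[-1], 1e-12)

    def test_ideal_shrinkage_identity(self):
        """alpha0 = 1: volume loss tracks water loss, 1 - V/V0 = phi0 (1 - X/X0)."""
        params = ds.MaterialParams(X0=5.55, d0=0.0524, alpha0=1.0)
        traj = ds.simulate(
            params, continuous_program(t_h=25.0),
            ds.SolverSettings(variant="full", n_nodes=80),
        )
        dev = np.abs((1.0 - traj.V_ratio) - traj.phi0 * (1.0 - traj.X_ratio))
        assert dev.max() < 5e-3

    def test_rigid_solid_keeps_radius(self):
        params = ds.MaterialParams(X0=2.0, d0=0.03, alpha0=0.0)
        traj = ds.simulate(
            params, continuous_program(t_h=5.0),
            ds.SolverSettings(variant="isothermal", n_nodes=64),
        )
        assert np.abs(traj.R_ratio - 1.0).max() < 1e-12

    def test_boundary_temperature_dips_at_onset(self):
        """Evaporative cooling during the switch-on ramp pulls the surface
        slightly below the initial temperature before convective heating
        takes over."""
        params = ds.MaterialParams(X0=5.55, d0=0.0524)
        traj = ds.simulate(
            params, continuous_program(t_h=5.0, startup=STARTUP),
            ds.SolverSettings(variant="full", n_nodes=80),
        )
        assert traj.T_b.min() < params.T0 - 0.01
        assert traj.T_b[-1] > params.T0 + 10.0  # then heats toward T_inf

    def test_grid_convergence_of_final_moisture(self):
        params = ds.MaterialParams(X0=5.55, d0=0.0524)
        prog = continuous_program(t_h=30.0)
        finals = []
        for n in (100, 200):
            st = ds.SolverSettings(variant="isothermal", n_nodes=n,
                                   rtol=1e-6, atol=1e-9)
            finals.append(ds.simulate(params, prog, st).X_ratio[-1])
        assert abs(finals[1] - finals[0]) < 1e-3

    def test_deterministic_reruns_are_bitwise_identical(self):
        params = ds.MaterialParams(X0=5.55, d0=0.0524)
        st = ds.SolverSettings(variant="full", n_nodes=64)
        a = ds.simulate(params, continuous_program(t_h=5.0), st)
        b = ds.simulate(params, continuous_program(t_h=5.0), st)
        np.testing.assert_array_equal(a.X_ratio, b.X_ratio)
        np.testing.assert_array_equal(a.T_b, b.T_b)


class TestValidationAndErrors:
    def test_settings_validation(self):
        with pytest.raises(ValueError):
            ds.SolverSettings(variant="magic")
        with pytest.raises(ValueError):
            ds.SolverSettings(n_nodes=8)
        with pytest.raises(ValueError):
            ds.SolverSettings(rtol=-1.0)

    def test_material_validation(self):
        with pytest.raises(ValueError):
            ds.MaterialParams(X0=-1.0, d0=0.05)
        with pytest.raises(ValueError):
            ds.MaterialParams(X0=5.0, d0=0.05, alpha0=-0.5)

    def test_open_ended_program_requires_t_end(self):
        params = ds.MaterialParams(X0=5.0, d0=0.05)
        prog = ds.CycleProgram(
            stages=(ds.Stage(float("inf"), 313.15, 0.15, 1.28),), startup=None
        )
        with pytest.raises(ValueError, match="t_end"):
            ds.simulate(params, prog, ds.SolverSettings(variant="isothermal"))

    def test_phi0_derived_from_moisture(self):
        params = ds.MaterialParams(X0=5.64, d0=0.053)
        assert params.phi0 == pytest.approx(0.894, abs=1e-3)
        assert params.R0 == pytest.approx(0.0265)
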