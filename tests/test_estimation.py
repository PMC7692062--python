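"""Dehydration-curve fitting, rate curves, asymptotic-slope diffusivity and
Arrhenius calibration."""

import numpy as np
import pytest

import drysphere as ds
from drysphere.estimation import FitError

TRUE = ds.RateCurveFit(a0=0.05, a1=0.5, a2=0.3, b1=0.5, b2=0.1, b3=0.02)
T_GRID = np.linspace(0.0, 240.0, 121)


class TestFitDehydrationCurve:
    def test_noiseless_self_consistency(self):
        fit = ds.fit_dehydration_curve(T_GRID, TRUE(T_GRID))
        assert fit.rms < 1e-8
        assert fit.a0 == pytest.approx(0.05, abs=1e-6)
        # rate constants recovered up to permutation
        assert sorted([fit.b1, fit.b2, fit.b3]) == pytest.approx(
            [0.02, 0.1, 0.5], rel=1e-4
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_recovery(self, seed):
        t, x = ds.generate_synthetic_curve(TRUE, T_GRID, noise_sd=0.005, seed=seed)
        fit = ds.fit_dehydration_curve(t, x, n_starts=8, seed=seed)
        rms = np.sqrt(np.mean((fit(t) - x) ** 2))
        assert rms <= 0.01
        assert fit.a0 == pytest.approx(0.05, abs=0.02)

    def test_constant_series_rejected(self):
        with pytest.raises(FitError, match="no decay"):
            ds.fit_dehydration_curve(T_GRID, np.ones_like(T_GRID))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ds.fit_dehydration_curve(T_GRID[:5], TRUE(T_GRID[:5]))

    def test_curve_passes_through_one_at_origin(self):
        fit = ds.fit_dehydration_curve(T_GRID, TRUE(T_GRID))
        assert fit(0.0) == pytest.approx(1.0, abs=1e-12)


class TestDehydrationRate:
    def test_closed_form_at_origin(self):
        Xr, J = ds.dehydration_rate(TRUE, 0.0)
        assert Xr == pytest.approx(1.0)
        expected = (TRUE.a1 * TRUE.b1 + TRUE.a2 * TRUE.b2 + TRUE.a3 * TRUE.b3) / (
            1.0 - TRUE.a0
        )
        assert J == pytest.approx(expected)

    def test_vanishes_at_long_times(self):
        Xr, J = ds.dehydration_rate(TRUE, 2000.0)
        assert abs(Xr) < 1e-12 and abs(J) < 1e-12

    def test_rate_equals_numerical_derivative(self):
        t = np.linspace(0.5, 100.0, 400)
        h = 1e-4
        Xr, J = ds.dehydration_rate(TRUE, t)
        Xr_p, _ = ds.dehydration_rate(TRUE, t + h)
        Xr_m, _ = ds.dehydration_rate(TRUE, t - h)
        J_num = -(Xr_p - Xr_m) / (2 * h)
        np.testing.assert_allclose(J, J_num, rtol=1e-6, atol=1e-10)

    def test_moisture_ratio_bounded(self):
        Xr, _ = ds.dehydration_rate(TRUE, np.linspace(0, 500, 200))
        assert np.all(Xr >= -1e-12) and np.all(Xr <= 1.0 + 1e-12)


class TestAsymptoticDeff:
    def test_rigid_sphere_roundtrip_exact(self):
        """Synthetic perfectly linear rate curve: slope inversion recovers
        the diffusivity it encodes."""
        D, R0 = 2e-10, 0.0265
        slope_h = D * np.pi**2 / R0**2 * 3600.0  # V_inf/V0 = 1
        Xr = np.linspace(0.001, 0.19, 50)
        est = ds.asymptotic_deff((Xr, slope_h * Xr), R0=R0, V_ratio_inf=1.0)
        assert est.D_eff == pytest.approx(D, rel=1e-12)
        assert est.slope == pytest.approx(slope_h, rel=1e-12)

    def test_shrinkage_volume_factor(self):
        Xr = np.linspace(0.001, 0.19, 50)
        J = 0.05 * Xr
        rigid = ds.asymptotic_deff((Xr, J), R0=0.0265, V_ratio_inf=1.0)
        shrunk = ds.asymptotic_deff((Xr, J), R0=0.0265, V_ratio_inf=0.1)
        assert shrunk.D_eff / rigid.D_eff == pytest.approx(0.1 ** (2.0 / 3.0), rel=1e-12)

    def test_window_must_hold_points(self):
        Xr = np.linspace(0.5, 0.9, 30)  # nothing inside the asymptotic window
        with pytest.raises(ValueError, match="need >= 4"):
            ds.asymptotic_deff((Xr, 0.05 * Xr), R0=0.0265)

    def test_simulator_in_the_loop_recovery(self, run_rigid_iso_40):
        """Rigid isothermal simulated curve at 40 degC: the full pipeline
        (multi-exponential fit -> rate curve -> slope) recovers the input
        diffusivity to a few percent."""
        traj = run_rigid_iso_40
        fit = ds.fit_dehydration_curve(traj.times_h[::4], traj.X_ratio[::4])
        est = ds.asymptotic_deff(fit, R0=traj.R0, V_ratio_inf=1.0, T=313.15)
        D_true = ds.ArrheniusLaw(4.00012e-5, -3872.63)(313.15)
        assert est.D_eff == pytest.approx(D_true, rel=0.03)

    def test_rate_curve_asymptotically_linear(self, run_rigid_iso_40):
        """J vs Xr from a simulated continuous run: the local slope J/Xr is
        flat (<5% variation) in the small-Xr window."""
        traj = run_rigid_iso_40
        fit = ds.fit_dehydration_curve(traj.times_h[::4], traj.X_ratio[::4])
        t = np.linspace(0.0, traj.times_h[-1], 3000)
        Xr, J = ds.dehydration_rate(fit, t)
        mask = (Xr > 0.01) & (Xr < 0.1)
        local = J[mask] / Xr[mask]
        assert (local.max() - local.min()) / local.mean() < 0.05


class TestFitArrhenius:
    def test_two_point_regression_matches_printed_constants(self):
        law = ds.fit_arrhenius([(313.15, 1.703e-10), (323.15, 2.497e-10)])
        assert law.E_over_Rg == pytest.approx(-3872.63, rel=1e-3)
        assert law.D0 == pytest.approx(4.00012e-5, rel=1e-3)

    def test_flat_diffusivity_gives_zero_activation(self):
        law = ds.fit_arrhenius([(300.0, 1e-10), (330.0, 1e-10)])
        assert law.E_over_Rg == pytest.approx(0.0, abs=1e-8)
        assert law.D0 == pytest.approx(1e-10, rel=1e-10)

    def test_exact_through_two_points(self):
        law = ds.fit_arrhenius([(300.0, 1e-10), (330.0, 3e-10)])
        assert law(300.0) == pytest.approx(1e-10, rel=1e-10)
        assert law(330.0) == pytest.approx(3e-10, rel=1e-10)

    def test_identical_temperatures_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            ds.fit_arrhenius([(313.15, 1e-10), (313.15, 2e-10)])

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            ds.fit_arrhenius([(313.15, 1e-10)])


class TestGenerateSyntheticCurve:
    def test_zero_noise_exact(self):
        t, x = ds.generate_synthetic_curve(TRUE, T_GRID, noise_sd=0.0)
        np.testing.assert_array_equal(x, TRUE(T_GRID))

    def test_seed_reproducibility(self):
        _, x1 = ds.generate_synthetic_curve(TRUE, T_GRID, 0.005, seed=42)
        _, x2 = ds.generate_synthetic_curve(TRUE, T_GRID, 0.005, seed=42)
        np.testing.assert_array_equal(x1, x2)
        _, x3 = ds.generate_synthetic_curve(TRUE, T_GRID, 0.005, seed=43)
        assert not np.array_equal(x1, x3)

    def test_noise_amplitude_calibrated(self):
        sds = [
            np.std(ds.generate_synthetic_curve(TRUE, T_GRID, 0.005, seed=s)[1]
                   - TRUE(T_GRID))
            for s in range(100)
        ]
        assert np.mean(sds) == pytest.approx(0.005, rel=0.2)

    def test_trajectory_source_resampled(self, run_rigid_iso_40):
        t_new = np.linspace(0.0, 100.0, 21)
        t, x = ds.generate_synthetic_curve(run_rigid_iso_40, t_new, noise_sd=0.0)
        np.testing.assert_array_equal(t, t_new)
        assert x[0] == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(x) < 0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            ds.generate_synthetic_curve(TRUE, T_GRID, noise_sd=-0.1)
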