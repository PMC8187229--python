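"""Unit tests of the trajectory-analysis layer (helix fit, observables)."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ciliaswim import kinematics as kin
from ciliaswim.harness import SyntheticHelixSpec, generate_synthetic_helix


def straight_trajectory(v0=1.0, n=201, dt=0.1):
    t = np.arange(n) * dt
    nvec = np.tile([0.0, 0.0, 1.0], (n, 1))
    mvec = np.tile([1.0, 0.0, 0.0], (n, 1))
    center = np.outer(v0 * t, [0.0, 0.0, 1.0])
    return kin.Trajectory(times=t, center=center, axis=nvec, marker=mvec)


class TestPropulsionStats:
    def test_straight_motion(self):
        v, fl = kin.propulsion_stats(straight_trajectory(v0=0.7))
        assert v == pytest.approx(0.7, rel=1e-10)
        assert fl == pytest.approx(0.0, abs=1e-10)

    def test_sinusoidal_modulation_root_variance(self):
        # v_n(t) = v0 + A sin(2 pi t / tau_b) over whole periods -> (v0, A/sqrt 2)
        v0, amp, tau_b = 1.0, 0.4, 2.0
        dt = tau_b / 400
        t = np.arange(0, 4 * tau_b + dt / 2, dt)
        z = v0 * t - amp * tau_b / (2 * np.pi) * np.cos(2 * np.pi * t / tau_b)
        n = len(t)
        traj = kin.Trajectory(times=t, center=np.column_stack(
            [np.zeros(n), np.zeros(n), z]),
            axis=np.tile([0.0, 0.0, 1.0], (n, 1)),
            marker=np.tile([1.0, 0.0, 0.0], (n, 1)))
        v, fl = kin.propulsion_stats(traj, tau_b)
        assert v == pytest.approx(v0, rel=1e-3)
        assert fl == pytest.approx(amp / np.sqrt(2), rel=1e-2)

    def test_circular_motion_perpendicular_to_axis_has_zero_vn(self):
        t = np.arange(400) * 0.05
        center = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        traj = kin.Trajectory(times=t, center=center,
                              axis=np.tile([0.0, 0.0, 1.0], (len(t), 1)),
                              marker=np.tile([1.0, 0.0, 0.0], (len(t), 1)))
        v, _ = kin.propulsion_stats(traj)
        assert v == pytest.approx(0.0, abs=1e-10)

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            kin.propulsion_stats(straight_trajectory(n=41, dt=0.1), tau_b=10.0)


class TestSpinRate:
    def test_marker_rotating_about_static_axis(self):
        omega = 0.8
        t = np.arange(500) * 0.05
        n = np.tile([0.0, 0.0, 1.0], (len(t), 1))
        m = np.column_stack([np.cos(omega * t), np.sin(omega * t),
                             np.zeros_like(t)])
        traj = kin.Trajectory(times=t, center=np.zeros((len(t), 3)),
                              axis=n, marker=m)
        assert kin.spin_rate(traj) == pytest.approx(omega, rel=1e-10)

    def test_static_frame_has_zero_spin(self):
        assert kin.spin_rate(straight_trajectory()) == 0.0

    def test_twisted_ribbon_spin_locked_to_circling(self):
        # spin at the circling frequency: Omega_c / |Omega_n| = 1
        om = 0.5
        spec = SyntheticHelixSpec(alpha_deg=30.0, omega_c=om, omega_n=om,
                                  duration=150.0, dt=0.05)
        traj = generate_synthetic_helix(spec)
        ratio = om / abs(kin.spin_rate(traj))
        assert ratio == pytest.approx(1.0, rel=1e-3)


class TestAutocorrelation:
    def test_constant_axis_gives_unity(self):
        lags, c = kin.orientation_autocorr(straight_trajectory(), max_lag=5.0)
        np.testing.assert_allclose(c, 1.0, atol=1e-12)

    def test_pure_circling_limit(self):
        # alpha = 90 deg, no noise: C(tau) = cos(Omega_c tau)
        spec = SyntheticHelixSpec(alpha_deg=90.0, omega_c=0.7,
                                  duration=400.0, dt=0.05)
        traj = generate_synthetic_helix(spec)
        lags, c = kin.orientation_autocorr(traj, max_lag=30.0)
        np.testing.assert_allclose(c, np.cos(0.7 * lags), atol=5e-3)

    def test_alpha_zero_with_noise_decays_exponentially(self):
        spec = SyntheticHelixSpec(alpha_deg=0.0, omega_c=0.0, kappa=0.05,
                                  duration=2000.0, dt=0.25,
                                  noise="rotational_diffusion", seed=5)
        traj = generate_synthetic_helix(spec)
        lags, c = kin.orientation_autocorr(traj, max_lag=30.0)
        np.testing.assert_allclose(c, np.exp(-0.05 * lags), atol=0.08)


class TestHelixFit:
    def test_noiseless_recovery_to_machine_precision(self):
        alpha, om, ka = 30.0, 1.3, 0.01
        tau = np.linspace(0.0, 60.0, 1200)
        a = np.cos(np.deg2rad(alpha)) ** 2
        corr = (a + (1 - a) * np.cos(om * tau)) * np.exp(-ka * tau)
        fit = kin.fit_helix_correlation(tau, corr, span=500.0)
        assert fit.alpha_deg == pytest.approx(alpha, rel=1e-6)
        assert fit.omega_c == pytest.approx(om, rel=1e-6)
        assert fit.kappa == pytest.approx(ka, rel=1e-4)

    def test_alpha_zero_flags_omega_unidentifiable(self):
        tau = np.linspace(0.0, 50.0, 500)
        corr = np.exp(-0.05 * tau)
        fit = kin.fit_helix_correlation(tau, corr, span=200.0)
        assert not fit.omega_reliable
        assert fit.kappa == pytest.approx(0.05, rel=1e-4)

    def test_short_trajectory_flags_unreliable_kappa(self):
        tau = np.linspace(0.0, 5.0, 100)
        corr = (0.75 + 0.25 * np.cos(2.0 * tau)) * np.exp(-0.001 * tau)
        fit = kin.fit_helix_correlation(tau, corr, span=10.0)
        assert not fit.kappa_reliable

    def test_noisy_synthetic_recovery_within_five_percent(self):
        """Rotational-diffusion noise, 500 beat periods of data."""
        alpha, om, ka = 40.0, 0.9, 0.012
        spec = SyntheticHelixSpec(alpha_deg=alpha, omega_c=om, kappa=ka,
                                  duration=3000.0, dt=0.25,
                                  noise="rotational_diffusion", seed=42)
        traj = generate_synthetic_helix(spec)
        fit = kin.fit_trajectory_helix(traj)
        assert fit.alpha_deg == pytest.approx(alpha, rel=0.05)
        assert fit.omega_c == pytest.approx(om, rel=0.05)
        assert fit.kappa == pytest.approx(ka, rel=0.3)

    def test_parameter_recovery_unbiased_across_alpha_range(self):
        """Ensemble of noisy series spanning alpha in [10, 80] degrees."""
        rng = np.random.default_rng(7)
        rel_err_alpha, rel_err_om = [], []
        for i, alpha in enumerate(np.linspace(10.0, 80.0, 8)):
            spec = SyntheticHelixSpec(alpha_deg=float(alpha), omega_c=0.8,
                                      kappa=0.01, duration=2500.0, dt=0.5,
                                      noise="rotational_diffusion",
                                      seed=100 + i)
            fit = kin.fit_trajectory_helix(generate_synthetic_helix(spec))
            rel_err_alpha.append(fit.alpha_deg / alpha - 1.0)
            rel_err_om.append(fit.omega_c / 0.8 - 1.0)
        assert abs(np.mean(rel_err_alpha)) < 0.05
        assert abs(np.mean(rel_err_om)) < 0.05


class TestHelixGeometry:
    def test_printed_convention_example(self):
        # alpha=45 deg, v=1, Omega_c = 1 cycle/time
        fit = kin.HelixFit(alpha_deg=45.0, omega_c=2.0 * np.pi, kappa=0.0)
        geom = kin.helix_geometry(1.0, fit)
        assert geom.P_h == pytest.approx(np.sqrt(2) / 2)
        assert geom.R_h == pytest.approx(np.sqrt(2) / (4 * np.pi))
        assert geom.alpha_h_deg == pytest.approx(45.0)

    def test_straight_line_and_circle_limits(self):
        straight = kin.helix_geometry(
            1.0, kin.HelixFit(alpha_deg=0.0, omega_c=1.0, kappa=0.0))
        assert straight.R_h == 0.0
        circle = kin.helix_geometry(
            1.0, kin.HelixFit(alpha_deg=90.0, omega_c=1.0, kappa=0.0))
        assert circle.P_h == pytest.approx(0.0, abs=1e-12)

    def test_zero_frequency_with_finite_alpha_flagged(self):
        geom = kin.helix_geometry(
            1.0, kin.HelixFit(alpha_deg=30.0, omega_c=0.0, kappa=0.0))
        assert geom.flagged
        assert geom.R_h == 0.0 and np.isinf(geom.P_h)

    @given(alpha=st.floats(1.0, 89.0), v=st.floats(0.01, 10.0),
           om=st.floats(0.01, 10.0))
    def test_roundtrip_recovers_alpha(self, alpha, v, om):
        geom = kin.helix_geometry(
            v, kin.HelixFit(alpha_deg=alpha, omega_c=om, kappa=0.0))
        assert geom.alpha_h_deg == pytest.approx(alpha, rel=1e-12)
        # pitch/radius identity P_h/(2 pi R_h) = cot(alpha), exact
        assert geom.pitch_radius_ratio == pytest.approx(
            1.0 / np.tan(np.deg2rad(alpha)), rel=1e-12)


class TestPassiveScales:
    def test_rotational_diffusion_cubic_law(self):
        d1, _ = kin.rotational_diffusion_scale(1.0, 1.0)
        d2, _ = kin.rotational_diffusion_scale(2.0, 1.0)
        assert d1 == pytest.approx(1.0 / (8.0 * np.pi))
        assert d2 == pytest.approx(d1 / 8.0)

    def test_tau_rot_is_half_inverse_diffusion(self):
        d, tau = kin.rotational_diffusion_scale(3.0, 2.0, 1.5)
        assert tau == pytest.approx(1.0 / (2.0 * d))

    @pytest.mark.parametrize("factor,expected", [
        (4.0, 4.0 ** (1 / 3)), (1.0, 1.0), (8.0, 2.0)])
    def test_hydrodynamic_radius_from_reduction_factor(self, factor, expected):
        tau_rot = 10.0
        kappa = 1.0 / (factor * tau_rot)
        r_h, flagged = kin.hydrodynamic_radius(kappa, tau_rot, 1.0)
        assert r_h == pytest.approx(expected)
        assert not flagged

    def test_active_noise_dominance_flagged(self):
        # kappa tau_rot > 1: decorrelation faster than the passive body
        r_h, flagged = kin.hydrodynamic_radius(4.0, 0.5, 1.0)
        assert flagged

    def test_efficiency_scalings(self):
        assert kin.efficiency(0.0, 1.0, 1.0, 1.0) == 0.0
        assert kin.efficiency(1.0, 1.0, 1.0, 1.0) == pytest.approx(6 * np.pi)
        assert kin.efficiency(2.0, 1.0, 1.0, 1.0) == pytest.approx(
            4 * kin.efficiency(1.0, 1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            kin.efficiency(1.0, 0.0, 1.0, 1.0)

    def test_reynolds_numbers(self):
        re_s, re_c = kin.reynolds(10.0, 8.0, 11.0, 180.0, 17.0)
        assert re_c / re_s == pytest.approx(1.375 ** 2, rel=1e-12)
        re_s2, re_c2 = kin.reynolds(10.0, 8.0, 11.0, 360.0, 17.0)
        assert re_s2 == pytest.approx(re_s / 2)
        assert kin.reynolds(1.0, 2.0, 2.0, 1.0, 1.0)[0] == \
            kin.reynolds(1.0, 2.0, 2.0, 1.0, 1.0)[1]

    def test_cilia_number_scaling_exponent(self):
        assert kin.n_scaling_exponent(1.4) == pytest.approx(0.7)


class TestDiffusionEstimators:
    def test_msd_of_ballistic_series_is_quadratic(self):
        t = np.arange(200) * 0.1
        series = np.column_stack([t, np.zeros_like(t), np.zeros_like(t)])
        lags, m = kin.msd(series, 0.1, 5.0)
        np.testing.assert_allclose(m, lags ** 2, rtol=1e-8)

    def test_diffusion_recovery_from_random_walk(self):
        rng = np.random.default_rng(0)
        d_true = 0.25
        dt = 0.1
        steps = rng.normal(0.0, np.sqrt(2 * d_true * dt), size=(40000, 3))
        walk = np.cumsum(steps, axis=0)
        lags, m = kin.msd(walk, dt, 5.0)
        assert kin.diffusion_coefficient(lags, m) == pytest.approx(d_true,
                                                                   rel=0.05)
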