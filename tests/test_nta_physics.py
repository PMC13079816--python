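"""Tests for the nanoparticle-tracking physics chain."""

import numpy as np
import pytest

from nbviability import (
    MediumParams,
    Trajectory,
    classify_submicron,
    diffusion_from_msd,
    einstein_consistency_check,
    electroosmotic_correction,
    ensemble_msd,
    estimate_particles,
    mobility_to_zeta,
    msd,
    simulate_brownian,
    smoluchowski_zeta,
    stokes_einstein_diameter,
)
from nbviability.nta_physics import (
    DEFAULT_DT_S,
    K_B,
    M_TO_NM,
    UM2_S_TO_M2_S,
    read_trajectories,
    write_trajectories,
)

MEDIUM = MediumParams()  # 298.15 K, 8.9e-4 Pa s, eps_r 78.5


class TestSimulateBrownian:
    def test_frozen_particle(self):
        trajs = simulate_brownian(3, 0.0, n_steps=10, seed=1)
        for t in trajs:
            np.testing.assert_array_equal(t.positions_um, 0.0)

    def test_pure_drift_straight_line(self):
        dt = DEFAULT_DT_S
        (t,) = simulate_brownian(1, 0.0, n_steps=5, drift_um_s=(3.0, 0.0), seed=1)
        expected = np.outer(np.arange(6), [3.0 * dt, 0.0])
        np.testing.assert_allclose(t.positions_um, expected, atol=1e-12)

    def test_increment_variance(self):
        """Per-axis step variance = 2 D dt within 10% (chi-square bound)."""
        d_true, dt = 2.0, DEFAULT_DT_S
        trajs = simulate_brownian(100, d_true, dt_s=dt, n_steps=300, seed=5)
        steps = np.concatenate([np.diff(t.positions_um, axis=0) for t in trajs])
        assert steps.var(axis=0) == pytest.approx(2 * d_true * dt, rel=0.10)

    def test_deterministic_under_seed(self):
        a = simulate_brownian(2, 1.0, n_steps=20, seed=9)
        b = simulate_brownian(2, 1.0, n_steps=20, seed=9)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.positions_um, tb.positions_um)

    def test_depth_profile_assigns_depth_and_flow(self):
        (t,) = simulate_brownian(1, 0.0, n_steps=4, seed=2,
                                 depth_profile=lambda z: 10.0)
        assert t.depth is not None and 0 <= t.depth <= 1
        vx = np.diff(t.positions_um[:, 0]) / t.dt_s
        np.testing.assert_allclose(vx, 10.0, atol=1e-9)


class TestMSD:
    def test_frozen_msd_zero(self):
        t = Trajectory(0, np.zeros((10, 2)))
        np.testing.assert_array_equal(msd(t, 5), 0.0)

    def test_pure_drift_quadratic(self):
        """MSD(tau) = (v tau dt)^2 exactly for a straight-line track."""
        v, dt = 2.5, 0.1
        pos = np.outer(np.arange(20), [v * dt, 0.0])
        t = Trajectory(0, pos, dt_s=dt)
        curve = msd(t, 6)
        lags = np.arange(1, 7)
        np.testing.assert_allclose(curve, (v * lags * dt) ** 2, rtol=1e-12)

    def test_ensemble_slope_near_4d(self):
        d_true = 2.0
        trajs = simulate_brownian(100, d_true, n_steps=300, seed=11)
        curve = ensemble_msd(trajs, 20)
        tau = DEFAULT_DT_S * np.arange(1, 21)
        slope = np.polyfit(tau, curve, 1)[0]
        assert slope == pytest.approx(4 * d_true, rel=0.10)

    def test_max_lag_validation(self):
        t = Trajectory(0, np.zeros((5, 2)))
        with pytest.raises(ValueError):
            msd(t, 5)


class TestDiffusionFromMSD:
    def test_exact_line_recovered(self):
        d, dt = 1.7, DEFAULT_DT_S
        tau = dt * np.arange(1, 21)
        assert diffusion_from_msd(4 * d * tau, dt, 20) == pytest.approx(d, rel=1e-12)

    def test_offset_absorbed_by_intercept(self):
        d, dt = 1.7, DEFAULT_DT_S
        tau = dt * np.arange(1, 21)
        assert diffusion_from_msd(4 * d * tau + 0.5, dt, 20) == pytest.approx(
            d, rel=1e-9)

    def test_negative_slope_clamped(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert diffusion_from_msd(np.array([3.0, 2.0, 1.0]), 0.1) == 0.0

    def test_parameter_recovery_simulated(self):
        d_true = 2.0
        trajs = simulate_brownian(100, d_true, n_steps=300, seed=21)
        curve = ensemble_msd(trajs, 75)
        d_hat = diffusion_from_msd(curve, DEFAULT_DT_S)
        assert 1.8 <= d_hat <= 2.2


class TestStokesEinstein:
    def test_printed_style_evaluation(self):
        d = stokes_einstein_diameter(4.9e-12, MEDIUM)
        assert d * M_TO_NM == pytest.approx(100.15, abs=0.1)

    def test_inverse_proportionality(self):
        assert stokes_einstein_diameter(1e-12, MEDIUM) == pytest.approx(
            2 * stokes_einstein_diameter(2e-12, MEDIUM), rel=1e-12)

    def test_round_trip_identity(self):
        d_m = 200e-9
        d_coef = K_B * MEDIUM.temperature_K / (
            3 * np.pi * MEDIUM.viscosity_Pa_s * d_m)
        assert d_coef / UM2_S_TO_M2_S == pytest.approx(2.45, abs=0.01)
        assert stokes_einstein_diameter(d_coef, MEDIUM) == pytest.approx(
            d_m, rel=1e-9)

    def test_nonpositive_d_rejected(self):
        with pytest.raises(ValueError):
            stokes_einstein_diameter(0.0, MEDIUM)


class TestElectroosmoticCorrection:
    def test_uniform_profile(self):
        assert electroosmotic_correction(
            [(0.0, 5.0), (0.5, 5.0), (1.0, 5.0)]) == pytest.approx(5.0)

    def test_zero_mean_quadratic_integrates_out(self):
        # v(z) = 3 + 2*(6z^2 - 6z + 1); integral of the parenthesis is 0
        prof = [(z, 3.0 + 2.0 * (6 * z**2 - 6 * z + 1)) for z in (0.0, 0.5, 1.0)]
        assert electroosmotic_correction(prof) == pytest.approx(3.0, rel=1e-9)

    def test_linearity_in_added_zero_mean_quadratic(self):
        zs = np.linspace(0, 1, 7)
        base = [(z, 1.0 + 0.5 * z) for z in zs]  # fitted exactly by quadratic
        v0 = electroosmotic_correction(base)
        perturbed = [(z, v + 4.0 * (6 * z**2 - 6 * z + 1)) for z, v in base]
        assert electroosmotic_correction(perturbed) == pytest.approx(v0, rel=1e-9)

    def test_too_few_depths_rejected(self):
        with pytest.raises(ValueError):
            electroosmotic_correction([(0.0, 1.0), (1.0, 2.0)])


class TestSmoluchowski:
    def test_printed_style_evaluation(self):
        # mu = 2e-8 m^2/Vs with eta = 8.9e-4, eps_r = 78.5 -> ~ +25.6 mV
        zeta = mobility_to_zeta(2.0e-8, MEDIUM)
        assert zeta * 1e3 == pytest.approx(25.6, abs=0.05)

    def test_zero_velocity_zero_zeta(self):
        assert smoluchowski_zeta(0.0, 1e4, MEDIUM) == 0.0

    def test_field_sign_symmetry(self):
        z1 = smoluchowski_zeta(1e-5, 1e4, MEDIUM)
        z2 = smoluchowski_zeta(1e-5, -1e4, MEDIUM)
        assert z1 == pytest.approx(-z2)
        assert z1 > 0

    def test_zero_field_rejected(self):
        with pytest.raises(ValueError):
            smoluchowski_zeta(1e-5, 0.0, MEDIUM)


class TestEinsteinConsistency:
    def test_self_consistency_near_one(self):
        d_nm = 500.0
        d_coef = K_B * MEDIUM.temperature_K / (
            3 * np.pi * MEDIUM.viscosity_Pa_s * d_nm / M_TO_NM) / UM2_S_TO_M2_S
        # single long track covering the 10 s window at 33 fps
        (traj,) = simulate_brownian(1, d_coef, n_steps=660, seed=17)
        ratio, ok = einstein_consistency_check(traj, d_nm, MEDIUM)
        assert ratio == pytest.approx(1.0, abs=0.4)
        assert ok

    def test_frozen_trajectory_inconsistent(self):
        t = Trajectory(0, np.zeros((400, 2)))
        ratio, ok = einstein_consistency_check(t, 500.0, MEDIUM)
        assert ratio == 0.0
        assert not ok

    def test_linearity_in_inverse_diameter(self):
        d_coef = 1.0
        (traj,) = simulate_brownian(1, d_coef, n_steps=400, seed=3)
        r1, _ = einstein_consistency_check(traj, 800.0, MEDIUM)
        r2, _ = einstein_consistency_check(traj, 200.0, MEDIUM)
        assert r2 == pytest.approx(r1 / 4.0, rel=1e-9)

    def test_window_exceeding_track_rejected(self):
        t = Trajectory(0, np.zeros((10, 2)))
        with pytest.raises(ValueError):
            einstein_consistency_check(t, 100.0, MEDIUM, window_s=10.0)


class TestClassifySubmicron:
    @pytest.mark.parametrize("d_nm,expected", [
        (100.0, True),
        (999.9, True),
        (1000.0, False),  # strict "< 1 um" boundary
        (1500.0, False),
    ])
    def test_iso_ultrafine_boundary(self, d_nm, expected):
        assert classify_submicron(d_nm) is expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_submicron(0.0)


class TestRecovery:
    def test_diameter_recovery_100nm(self):
        """Median recovered diameter over 20 seeds within 10% of truth."""
        d_nm_true = 100.0
        d_coef = K_B * MEDIUM.temperature_K / (
            3 * np.pi * MEDIUM.viscosity_Pa_s * d_nm_true / M_TO_NM
        ) / UM2_S_TO_M2_S
        medians = []
        for seed in range(20):
            trajs = simulate_brownian(100, d_coef, n_steps=300, seed=seed)
            curve = ensemble_msd(trajs, 75)
            d_hat = diffusion_from_msd(curve, DEFAULT_DT_S)
            medians.append(
                stokes_einstein_diameter(d_hat * UM2_S_TO_M2_S, MEDIUM) * M_TO_NM)
        assert np.median(medians) == pytest.approx(d_nm_true, rel=0.10)

    def test_zeta_recovery_with_osmotic_flow(self):
        """Drift + zero-mean parabolic osmotic flow -> zeta within 10%."""
        field = 1e4  # V/m
        zeta_true_mv = 30.0
        mob = (zeta_true_mv / 1e3) * MEDIUM.relative_permittivity * (
            8.8541878128e-12) / MEDIUM.viscosity_Pa_s
        v_ep_um_s = mob * field * 1e6  # um/s
        osmotic = lambda z: 25.0 * (6 * z**2 - 6 * z + 1)  # zero depth-mean
        trajs = simulate_brownian(
            300, 1.0, n_steps=300, drift_um_s=(v_ep_um_s, 0.0),
            depth_profile=osmotic, seed=33)
        # apparent x-velocity per particle, profiled across depth bins
        prof = []
        for t in trajs:
            vx = (t.positions_um[-1, 0] - t.positions_um[0, 0]) / t.duration_s
            prof.append((t.depth, vx))
        v_hat_um_s = electroosmotic_correction(prof)
        zeta_hat = smoluchowski_zeta(v_hat_um_s / 1e6, field, MEDIUM)
        assert zeta_hat * 1e3 == pytest.approx(zeta_true_mv, rel=0.10)

    def test_zero_field_zeta_near_zero(self):
        trajs = simulate_brownian(300, 1.0, n_steps=300,
                                  depth_profile=lambda z: 0.0, seed=8)
        prof = [(t.depth,
                 (t.positions_um[-1, 0] - t.positions_um[0, 0]) / t.duration_s)
                for t in trajs]
        v_hat = electroosmotic_correction(prof)
        # pure diffusion: apparent velocity consistent with zero
        assert abs(v_hat) < 0.15  # um/s, noise floor for 300 tracks x 9 s


class TestTrajectoryIO:
    def test_roundtrip(self, tmp_path):
        trajs = simulate_brownian(3, 1.5, n_steps=10, seed=4,
                                  depth_profile=lambda z: 0.0)
        path = tmp_path / "tracks.csv"
        write_trajectories(trajs, path)
        back = read_trajectories(path)
        assert len(back) == 3
        for a, b in zip(trajs, back):
            assert a.particle_id == b.particle_id
            np.testing.assert_allclose(a.positions_um, b.positions_um, rtol=1e-12)
            assert b.depth == pytest.approx(a.depth)

    def test_estimates_table(self):
        trajs = simulate_brownian(5, 2.0, n_steps=200, seed=6)
        ests = estimate_particles(trajs, MEDIUM)
        assert len(ests) == 5
        for e in ests:
            assert e.D_um2_s >= 0
            if e.diameter_nm is not None:
                assert e.is_submicron == (e.diameter_nm < 1000.0)
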