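import numpy as np
import pytest

from jointkal import (FilterModel, FilterState, Measurement,
                      SingularGeometryError, ValidationError, ekf_smooth,
                      linear_kalman_filter, measurement_jacobian,
                      moving_mean_filter, predict, update)
from jointkal.synthetic import SceneConfig, generate_quarter_circle


def textbook_filter(traj, angles, dt, sigma_a, sigma_p, sigma_theta_deg,
                    x0, P0):
    """Straightforward reference Kalman/EKF written from the textbook formulas.

    Builds all matrices inline and uses explicit inverses; serves as an
    independent oracle for the package implementation.
    """
    F = np.eye(6)
    for i in range(3):
        F[i, i + 3] = dt
    Q = np.zeros((6, 6))
    for i in range(3):
        Q[i, i] = sigma_a**2 * dt**4 / 4
        Q[i, i + 3] = Q[i + 3, i] = sigma_a**2 * dt**3 / 2
        Q[i + 3, i + 3] = sigma_a**2 * dt**2
    x, P = np.array(x0, dtype=float), np.array(P0, dtype=float)
    out = []
    for f in range(len(traj)):
        x = F @ x
        P = F @ P @ F.T + Q
        P = 0.5 * (P + P.T)
        use_angle = angles is not None and np.isfinite(angles[f])
        if use_angle:
            px, pz = x[0], x[2]
            H = np.zeros((4, 6))
            H[0, 0] = H[1, 1] = H[2, 2] = 1
            H[3, 0] = pz / (px**2 + pz**2)
            H[3, 2] = -px / (px**2 + pz**2)
            R = np.diag([sigma_p**2] * 3 + [np.radians(sigma_theta_deg)**2])
            z = np.array([*traj[f], angles[f]])
            hx = np.array([x[0], x[1], x[2], np.arctan2(x[0], x[2])])
        else:
            H = np.zeros((3, 6))
            H[0, 0] = H[1, 1] = H[2, 2] = 1
            R = np.diag([sigma_p**2] * 3)
            z = np.asarray(traj[f], dtype=float)
            hx = x[:3]
        K = P @ H.T @ np.linalg.inv(H @ P @ H.T + R)
        innov = z - hx
        if use_angle:
            innov[3] = (innov[3] + np.pi) % (2 * np.pi) - np.pi
        x = x + K @ innov
        P = (np.eye(6) - K @ H) @ P
        P = 0.5 * (P + P.T)
        out.append(x[:3].copy())
    return np.array(out)


class TestPredict:
    def test_position_integrates_velocity(self):
        model = FilterModel()
        state = FilterState(x=[0, 0, 1, 0.3, 0, 0], P=np.eye(6))
        pred = predict(state, model)
        np.testing.assert_allclose(pred.position, [0.01, 0, 1], atol=1e-12)
        np.testing.assert_allclose(pred.velocity, [0.3, 0, 0], atol=1e-15)

    def test_zero_velocity_keeps_position(self):
        state = FilterState(x=[0.4, 0.5, 2.0, 0, 0, 0], P=np.eye(6))
        pred = predict(state, FilterModel())
        np.testing.assert_allclose(pred.position, [0.4, 0.5, 2.0], atol=1e-15)

    def test_zero_process_noise_conserves_zero_covariance(self):
        model = FilterModel(sigma_a=0.0)
        state = FilterState(x=np.zeros(6), P=np.zeros((6, 6)))
        pred = predict(state, model)
        np.testing.assert_allclose(pred.P, 0.0, atol=1e-15)


class TestMeasurementJacobian:
    def test_on_axis_bearing_row(self):
        state = FilterState(x=[0, 0, 1, 0, 0, 0], P=np.eye(6))
        H = measurement_jacobian(state)
        np.testing.assert_allclose(H[3], [1, 0, 0, 0, 0, 0], atol=1e-15)

    def test_diagonal_bearing_row(self):
        state = FilterState(x=[1, 0, 1, 0, 0, 0], P=np.eye(6))
        H = measurement_jacobian(state)
        np.testing.assert_allclose(H[3], [0.5, 0, -0.5, 0, 0, 0], atol=1e-15)

    def test_position_rows_are_selector(self):
        state = FilterState(x=[0.3, -0.2, 1.7, 0.1, 0.2, 0.3], P=np.eye(6))
        H = measurement_jacobian(state)
        np.testing.assert_array_equal(H[:3, :3], np.eye(3))
        np.testing.assert_array_equal(H[:3, 3:], np.zeros((3, 3)))

    def test_singular_geometry_raises(self):
        state = FilterState(x=[1, 0, 0, 0, 0, 0], P=np.eye(6))
        with pytest.raises(SingularGeometryError):
            measurement_jacobian(state)


class TestUpdate:
    def test_vanishing_measurement_noise_trusts_measurement(self):
        model = FilterModel(sigma_p=1e-9)
        state = FilterState(x=np.zeros(6), P=np.eye(6))
        new = update(state, Measurement(np.array([0.3, -0.1, 2.0])), model)
        np.testing.assert_allclose(new.position, [0.3, -0.1, 2.0], atol=1e-6)

    def test_vanishing_prior_covariance_keeps_prior(self):
        model = FilterModel()
        state = FilterState(x=[1, 2, 3, 0, 0, 0], P=np.zeros((6, 6)))
        new = update(state, Measurement(np.array([9.0, 9.0, 9.0])), model)
        np.testing.assert_allclose(new.x, state.x, atol=1e-12)

    def test_scalar_gain_half_for_equal_variances(self):
        # per-axis analogue of K = P/(P+R) = 0.5 when P = R = 1
        model = FilterModel(sigma_p=1.0)
        state = FilterState(x=np.zeros(6), P=np.diag([1.0] * 3 + [0.0] * 3))
        new = update(state, Measurement(np.array([1.0, 0.0, 0.0])), model)
        assert new.x[0] == pytest.approx(0.5, abs=1e-12)

    def test_covariance_stays_symmetric_psd_under_random_steps(self):
        rng = np.random.default_rng(42)
        model = FilterModel()
        state = FilterState(x=[0, 0, 2, 0, 0, 0], P=np.eye(6) * 0.01)
        for _ in range(1000):
            state = predict(state, model)
            if rng.uniform() < 0.7:
                pos = state.position + rng.normal(0, 0.05, 3)
                angle = rng.normal(np.arctan2(pos[0], pos[2]), 0.05)
                state = update(state, Measurement(pos, angle), model)
            np.testing.assert_allclose(state.P, state.P.T, atol=1e-12)
            assert np.linalg.eigvalsh(state.P).min() >= -1e-9


class TestEkfSmooth:
    def test_tracks_noiseless_constant_velocity(self):
        n = 60
        traj = np.zeros((n, 3))
        traj[:, 0] = 0.05 * np.arange(n)
        traj[:, 2] = 1.0
        out = ekf_smooth(traj, model=FilterModel())
        # after the velocity estimate converges, the exact model is reproduced
        np.testing.assert_allclose(out[40:], traj[40:], atol=1e-3)

    def test_reduces_variance_of_static_noise(self):
        reduced = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            traj = np.tile([0.2, 0.5, 2.0], (300, 1)) + rng.normal(0, 0.01, (300, 3))
            out = ekf_smooth(traj)
            if out[50:].var(axis=0).sum() < traj[50:].var(axis=0).sum():
                reduced += 1
        assert reduced == 10

    def test_single_frame_blends_init_and_measurement(self):
        model = FilterModel()
        traj = np.array([[0.5, 0.5, 2.0]])
        init = model.initial_state([0.0, 0.0, 2.0])
        out = ekf_smooth(traj, model=model, init=init)
        # posterior lies strictly between initialization and measurement
        assert 0.0 < out[0, 0] < 0.5

    def test_bearing_channel_improves_planar_accuracy(self):
        # scenes where the bearing is informative: coarse position jitter,
        # precise microphone bearing
        wins = []
        for seed in range(10):
            scene = generate_quarter_circle(SceneConfig(
                seed=seed, jitter_sigma=0.02, angle_noise_sigma=0.1,
                error_magnitude=0.0, occlusion_window=(0, 0)))
            model = FilterModel(sigma_p=0.02, sigma_theta_deg=0.1)
            obs = scene.observed.joint("wrist")
            truth = scene.truth.joint("wrist")
            with_angle = ekf_smooth(obs, scene.observed.sound_angle, model)
            without = ekf_smooth(obs, None, model)

            def planar(est):
                return np.hypot(est[:, 0] - truth[:, 0],
                                est[:, 2] - truth[:, 2]).mean()

            wins.append(planar(with_angle) <= planar(without))
        assert sum(wins) >= 9


class TestMovingMean:
    def test_constant_unchanged(self):
        traj = np.tile([1.0, 2.0, 3.0], (20, 1))
        np.testing.assert_allclose(moving_mean_filter(traj, 5), traj)

    def test_impulse_spreads_to_plateau(self):
        traj = np.zeros((11, 3))
        traj[5, 0] = 1.0
        out = moving_mean_filter(traj, 5)
        np.testing.assert_allclose(out[3:8, 0], 0.2, atol=1e-15)
        np.testing.assert_allclose(out[:3, 0], 0.0, atol=1e-15)
        np.testing.assert_allclose(out[8:, 0], 0.0, atol=1e-15)

    def test_window_one_is_identity(self):
        rng = np.random.default_rng(0)
        traj = rng.normal(size=(15, 3))
        np.testing.assert_array_equal(moving_mean_filter(traj, 1), traj)

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError):
            moving_mean_filter(np.zeros((10, 3)), 4)


class TestOracleEquivalence:
    def test_linear_kalman_matches_textbook_implementation(self):
        rng = np.random.default_rng(11)
        traj = np.cumsum(rng.normal(0, 0.02, (20, 3)), axis=0) + [0, 0, 2.0]
        model = FilterModel()
        init = model.initial_state(traj[0])
        ours = linear_kalman_filter(traj, model, init=init)
        oracle = textbook_filter(traj, None, model.dt, model.sigma_a,
                                 model.sigma_p, model.sigma_theta_deg,
                                 init.x, init.P)
        np.testing.assert_allclose(ours, oracle, atol=1e-9)

    def test_ekf_with_bearing_matches_textbook_implementation(self):
        rng = np.random.default_rng(12)
        traj = np.cumsum(rng.normal(0, 0.02, (20, 3)), axis=0) + [0.5, 0, 2.0]
        angles = np.arctan2(traj[:, 0], traj[:, 2]) + rng.normal(0, 0.02, 20)
        model = FilterModel()
        init = model.initial_state(traj[0])
        ours = ekf_smooth(traj, angles, model, init=init)
        oracle = textbook_filter(traj, angles, model.dt, model.sigma_a,
                                 model.sigma_p, model.sigma_theta_deg,
                                 init.x, init.P)
        np.testing.assert_allclose(ours, oracle, atol=1e-9)

    def test_linear_kalman_is_ekf_without_bearing(self):
        rng = np.random.default_rng(13)
        traj = rng.normal([0, 0, 2.0], 0.1, (25, 3))
        np.testing.assert_array_equal(linear_kalman_filter(traj),
                                      ekf_smooth(traj, None))
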