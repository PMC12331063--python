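"""Constant-velocity Kalman filter: steps, calibration, tracking, gap-filling."""

import numpy as np
import pytest

from dualskel import (
    FilterState,
    JointTracker,
    KalmanConfig,
    NoiseModel,
    calibrate_measurement_noise,
    fill_missing,
    predict_step,
    track_joint,
    update_step,
)
from dualskel.kalman import OBSERVATION_MATRIX, initial_state, transition_matrix
from dualskel.errors import CalibrationError, EmptyResultError
from dualskel.simulate import ExerciseSpec, RigSpec, generate_motion, observe_front


class ReferenceFilter:
    """Textbook filter written from the printed equations (independent oracle)."""

    def __init__(self, dt, R, q):
        self.A = np.eye(6)
        for i in range(3):
            self.A[i, i + 3] = dt
        self.H = np.hstack([np.eye(3), np.zeros((3, 3))])
        self.R = R
        self.Q = q * np.eye(6)

    def run(self, z0, measurements):
        x = np.concatenate([z0, np.zeros(3)])
        P = np.eye(6)
        states = [(x.copy(), P.copy())]
        for z in measurements:
            x = self.A @ x
            P = self.A @ P @ self.A.T + self.Q
            K = P @ self.H.T @ np.linalg.inv(self.H @ P @ self.H.T + self.R)
            x = x + K @ (z - self.H @ x)
            P = (np.eye(6) - K @ self.H) @ P
            states.append((x.copy(), P.copy()))
        return states


class TestPredict:
    def test_position_advanced_by_velocity(self):
        st = FilterState(x=[0, 0, 0, 1, 0, 0], P=np.eye(6))
        out = predict_step(st, KalmanConfig(dt=1 / 30), NoiseModel())
        assert np.allclose(out.position, [1 / 30, 0, 0], atol=1e-15)
        assert np.allclose(out.velocity, [1, 0, 0], atol=1e-15)

    def test_zero_velocity_keeps_position(self, rng):
        p = rng.normal(size=3)
        st = FilterState(x=np.concatenate([p, np.zeros(3)]), P=np.eye(6))
        out = predict_step(st, KalmanConfig(), NoiseModel())
        assert np.allclose(out.position, p, atol=1e-15)

    def test_matches_matrix_oracle(self, rng):
        x = rng.normal(size=6)
        P = rng.normal(size=(6, 6))
        P = P @ P.T
        noise = NoiseModel(q=1e-5)
        cfg = KalmanConfig(dt=0.04)
        out = predict_step(FilterState(x=x, P=P), cfg, noise)
        A = transition_matrix(0.04)
        assert np.allclose(out.x, A @ x, atol=1e-12)
        assert np.allclose(out.P, A @ P @ A.T + 1e-5 * np.eye(6), atol=1e-12)


class TestUpdate:
    def test_tiny_R_posterior_equals_measurement(self, rng):
        st = predict_step(initial_state(rng.normal(size=3)), KalmanConfig(), NoiseModel())
        z = rng.normal(size=3)
        out = update_step(st, z, NoiseModel(sigma2=(1e-12,) * 3))
        assert np.allclose(out.position, z, atol=1e-6)

    def test_huge_R_posterior_equals_prior(self, rng):
        st = predict_step(initial_state(rng.normal(size=3)), KalmanConfig(), NoiseModel())
        out = update_step(st, st.position + 5.0, NoiseModel(sigma2=(1e12,) * 3))
        assert np.allclose(out.x, st.x, atol=1e-6)

    def test_hundred_step_run_matches_reference_filter(self, rng):
        dt = 1 / 30
        noise = NoiseModel(sigma2=(1e-4, 2e-4, 3e-4), q=1e-6)
        truth0 = np.array([0.1, 1.0, 0.5])
        vel = np.array([0.3, -0.1, 0.2])
        meas = [
            truth0 + vel * (k * dt) + rng.normal(0, 0.01, 3) for k in range(1, 101)
        ]
        ref = ReferenceFilter(dt, np.diag(noise.sigma2), noise.q).run(truth0, meas)
        st = initial_state(truth0)
        for k, z in enumerate(meas, start=1):
            st = update_step(predict_step(st, KalmanConfig(dt=dt), noise), z, noise)
            assert np.allclose(st.x, ref[k][0], atol=1e-9)
            assert np.allclose(st.P, ref[k][1], atol=1e-9)


class TestNoiseCalibration:
    def _static(self, sigma, n_frames=900, seed=0):
        spec = ExerciseSpec(kind="static", duration=n_frames / 30.0)
        gt = generate_motion(spec, seed)
        rig = RigSpec(noise_sigma=sigma)
        return observe_front(type(gt)(world=gt.world, rig=rig, exercise=spec, seed=seed))

    def test_noiseless_static_zero_R(self):
        seq = self._static((0.0, 0.0, 0.0), n_frames=60)
        noise = calibrate_measurement_noise(seq, "right_wrist")
        assert np.allclose(noise.sigma2, 0.0, atol=1e-20)

    def test_recovers_injected_variances(self):
        seq = self._static((0.01, 0.02, 0.03))
        noise = calibrate_measurement_noise(seq, "right_wrist")
        expect = np.array([1e-4, 4e-4, 9e-4])
        assert np.all(np.abs(np.array(noise.sigma2) - expect) <= 0.15 * expect)

    def test_translation_invariant(self):
        seq = self._static((0.01, 0.01, 0.01), n_frames=120)
        shifted = seq.with_positions(seq.positions + np.array([1.0, -2.0, 0.5]))
        a = calibrate_measurement_noise(seq, "head")
        b = calibrate_measurement_noise(shifted, "head")
        assert np.allclose(a.sigma2, b.sigma2, atol=1e-15)

    def test_too_few_frames_raises(self):
        seq = self._static((0.01,) * 3, n_frames=10)
        with pytest.raises(CalibrationError):
            calibrate_measurement_noise(seq, "head")


class TestTrackJoint:
    def _line(self, n, dt=1 / 30):
        v = np.array([0.2, -0.05, 0.4])
        return [np.array([0.0, 1.0, 0.0]) + v * k * dt for k in range(n)]

    def test_converges_on_exact_constant_velocity(self):
        obs = self._line(150)
        out = track_joint(obs, KalmanConfig(), NoiseModel())
        assert np.linalg.norm(out[-1].position - obs[-1]) < 1e-3
        assert len(out) == len(obs)

    def test_predicts_through_single_gap(self):
        obs = self._line(100)
        obs[50] = None
        out = track_joint(obs, KalmanConfig(), NoiseModel())
        truth = self._line(100)[50]
        assert not out[50].was_observed
        assert np.linalg.norm(out[50].position - truth) < 1e-3

    def test_stationary_fixed_point(self):
        p = np.array([0.3, 1.2, -0.5])
        out = track_joint([p] * 200, KalmanConfig(), NoiseModel())
        assert np.allclose(out[-1].position, p, atol=1e-6)

    def test_all_absent_raises(self):
        with pytest.raises(EmptyResultError):
            track_joint([None, None], KalmanConfig(), NoiseModel())

    def test_translation_equivariance(self, rng):
        obs = [rng.normal(0, 0.3, 3) + [0, 1, 0] for _ in range(50)]
        shift = np.array([2.0, -1.0, 0.7])
        a = track_joint(obs, KalmanConfig(), NoiseModel())
        b = track_joint([o + shift for o in obs], KalmanConfig(), NoiseModel())
        for pa, pb in zip(a, b):
            assert np.allclose(pb.position - pa.position, shift, atol=1e-9)


class TestCovarianceHealth:
    def test_P_symmetric_psd_over_random_cycles(self, rng):
        noise = NoiseModel(sigma2=tuple(rng.uniform(1e-6, 1e-2, 3)), q=1e-6)
        cfg = KalmanConfig()
        st = initial_state(rng.normal(size=3))
        for i in range(2000):
            st = predict_step(st, cfg, noise)
            if rng.random() < 0.7:
                st = update_step(st, rng.normal(0, 0.1, 3), noise)
            if i % 100 == 0:
                st.check(tol=1e-9)
        st.check(tol=1e-9)

    def test_innovations_shrink_on_exact_model(self):
        dt = 1 / 30
        noise = NoiseModel(sigma2=(1e-4,) * 3, q=1e-12)
        obs = [np.array([0.0, 0.0, 0.0]) + np.array([0.5, 0, 0]) * k * dt
               for k in range(90)]
        st = initial_state(obs[0])
        innov = []
        for z in obs[1:]:
            pred = predict_step(st, KalmanConfig(dt=dt), noise)
            innov.append(np.linalg.norm(z - OBSERVATION_MATRIX @ pred.x))
            st = update_step(pred, z, noise)
        rms = [np.sqrt(np.mean(np.square(innov[i:i + 15]))) for i in range(0, 75, 15)]
        assert all(b <= a + 1e-12 for a, b in zip(rms, rms[1:]))


class TestFillMissing:
    def test_front_priority(self):
        tracker = JointTracker()
        val, tag = fill_missing(np.array([1.0, 2.0, 3.0]), np.array([9.0, 9.0, 9.0]), tracker)
        assert tag == "front"
        assert np.allclose(val, [1, 2, 3], atol=1e-12)

    def test_side_with_depth_adjustment(self):
        tracker = JointTracker()
        val, tag = fill_missing(None, np.array([0.2, 1.0, 0.8]), tracker,
                                e_d_joint=-0.1, alpha=1.0)
        assert tag == "side+aEd"
        assert np.allclose(val, [0.2, 1.0, 0.7], atol=1e-12)

    def test_kalman_bridges_gap_during_linear_motion(self):
        dt = 1 / 30
        v = np.array([0.3, 0.0, -0.2])
        tracker = JointTracker(KalmanConfig(dt=dt), NoiseModel())
        for k in range(100):
            fill_missing(np.array([0, 1, 0]) + v * k * dt, None, tracker)
        val, tag = fill_missing(None, None, tracker)
        assert tag == "kalman"
        truth = np.array([0, 1, 0]) + v * 100 * dt
        assert np.linalg.norm(val - truth) < 1e-3
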