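"""Session calibration and end-to-end stream fusion."""

import numpy as np
import pytest

from dualskel import (
    DepthBiasModel,
    DepthDiscrepancy,
    ExerciseSpec,
    FusionConfig,
    GroundTruth,
    JointObservation,
    JointTracker,
    RigSpec,
    SkeletonFrame,
    calibrate_session,
    combine_frames,
    depth_error_series,
    fuse_streams,
    observe_front,
    observe_side,
    simulate_pair,
)
from dualskel.errors import ConfigError
from dualskel.fusion import TAG_FRONT, TAG_KALMAN, TAG_SIDE
from dualskel.simulate import default_rig


@pytest.fixture(scope="module")
def default_session():
    front, side, gt = simulate_pair(ExerciseSpec(kind="arm_flexion"), default_rig(), seed=2)
    return front, side, gt


class TestCalibrateSession:
    def test_recovers_injected_session_parameters(self, flexion_truth):
        k_e, b_e = 0.25, -0.22  # sign-changing body tilt, zero near hip height
        rig = RigSpec(
            true_theta=88.0,
            true_T=(0.12, -0.02, -0.1),
            time_offset=-7,
            front_depth_bias=(k_e, b_e),
            noise_sigma=(0.005,) * 3,
        )
        gt = GroundTruth(world=flexion_truth.world, rig=rig,
                         exercise=flexion_truth.exercise, seed=9)
        cal = calibrate_session(observe_front(gt), observe_side(gt), FusionConfig())
        assert cal.alignment.params.theta == pytest.approx(88.0, abs=2.0)
        assert np.allclose(cal.alignment.params.T[:2], rig.true_T[:2], atol=0.02)
        assert cal.offset_difference == -7
        assert cal.bias.k_e == pytest.approx(k_e, abs=0.05)
        # a constant depth offset splits between T_z and b_e; the composite
        # front-depth correction map is the identifiable quantity
        assert cal.alignment.params.T[2] + cal.bias.b_e == pytest.approx(
            rig.true_T[2] + b_e, abs=0.02
        )
        assert cal.alignment.params.T[2] == pytest.approx(rig.true_T[2], abs=0.05)

    def test_null_calibration_on_identical_geometry(self, flexion_truth):
        rig = RigSpec(true_theta=90.0, true_T=(0.0, 0.0, 0.0))
        gt = GroundTruth(world=flexion_truth.world, rig=rig,
                         exercise=flexion_truth.exercise, seed=0)
        cal = calibrate_session(observe_front(gt), observe_side(gt), FusionConfig())
        assert cal.alignment.params.theta == pytest.approx(90.0, abs=1e-3)
        assert np.linalg.norm(cal.alignment.params.T) < 1e-6
        assert cal.offset_difference == 0
        assert abs(cal.bias.k_e) < 1e-6 and abs(cal.bias.b_e) < 1e-6

    def test_deterministic_calibration_file(self, tmp_path, default_session):
        front, side, _ = default_session
        a = calibrate_session(front, side)
        b = calibrate_session(front, side)
        pa, pb = tmp_path / "a.yaml", tmp_path / "b.yaml"
        a.save(pa)
        b.save(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_calibration_yaml_round_trip(self, tmp_path, default_session):
        from dualskel import SessionCalibration

        front, side, _ = default_session
        cal = calibrate_session(front, side)
        p = tmp_path / "cal.yaml"
        cal.save(p)
        back = SessionCalibration.load(p)
        assert back.alignment.params.theta == pytest.approx(cal.alignment.params.theta)
        assert back.offset_difference == cal.offset_difference
        assert back.bias.k_e == pytest.approx(cal.bias.k_e)
        assert np.allclose(back.noise.sigma2, cal.noise.sigma2)


def _frame(**joints):
    return SkeletonFrame(0, 0.0, {
        name: (JointObservation(pos) if pos is not None
               else JointObservation((np.nan,) * 3, 0.0, False))
        for name, pos in joints.items()
    })


class TestCombineFrames:
    def _parts(self):
        bias = DepthBiasModel(k_e=0.0, b_e=0.0)
        e_d = DepthDiscrepancy(per_joint_signed={"a": -0.1}, e_d_total=0.1)
        return bias, e_d, {}

    def test_both_present_xy_front_z_side(self):
        bias, e_d, trackers = self._parts()
        fused, prov = combine_frames(
            _frame(a=(0.1, 1.2, 0.5)), _frame(a=(0.11, 1.19, 0.80)),
            bias, e_d, trackers,
        )
        assert np.allclose(fused.joints["a"].xyz, [0.1, 1.2, 0.80], atol=1e-12)
        assert prov == {"a": TAG_FRONT}

    def test_side_only_gets_depth_adjustment(self):
        bias, e_d, trackers = self._parts()
        fused, prov = combine_frames(
            _frame(a=None), _frame(a=(0.2, 1.0, 0.8)), bias, e_d, trackers,
            FusionConfig(alpha=1.0),
        )
        assert prov == {"a": TAG_SIDE}
        assert fused.joints["a"].xyz[2] == pytest.approx(0.7, abs=1e-12)

    def test_front_only_depth_corrected(self):
        e_d = DepthDiscrepancy(per_joint_signed={}, e_d_total=0.0)
        bias = DepthBiasModel(k_e=0.3, b_e=-0.1)
        fused, prov = combine_frames(
            _frame(a=(0.0, 1.5, 1.0)), _frame(a=None), bias, e_d, {},
        )
        assert fused.joints["a"].xyz[2] == pytest.approx(0.65, abs=1e-12)
        assert prov == {"a": TAG_FRONT}

    def test_ablation_both_absent_stays_absent(self):
        bias, e_d, trackers = self._parts()
        fused, prov = combine_frames(
            _frame(a=None), _frame(a=None), bias, e_d, trackers,
            FusionConfig(kalman_on=False),
        )
        assert not fused.joints["a"].present
        assert prov == {}

    def test_kalman_prediction_fills_after_history(self):
        bias, e_d, _ = self._parts()
        trackers = {"a": JointTracker()}
        for k in range(30):
            combine_frames(_frame(a=(0.1 * k, 1.0, 0.0)), _frame(a=None),
                           DepthBiasModel(0.0, 0.0), e_d, trackers)
        fused, prov = combine_frames(_frame(a=None), _frame(a=None),
                                     DepthBiasModel(0.0, 0.0), e_d, trackers)
        assert prov == {"a": TAG_KALMAN}
        assert fused.joints["a"].present


class TestFuseStreams:
    def test_frame_count_is_offset_overlap(self, default_session):
        front, side, _ = default_session
        fused = fuse_streams(front, side)
        d = fused.calibration.offset_difference
        expect = min(front.frame_count, side.frame_count - d) - max(0, -d)
        assert fused.sequence.frame_count == expect

    def test_provenance_complete_and_exclusive(self, default_session):
        front, side, _ = default_session
        fused = fuse_streams(front, side)
        seq = fused.sequence
        for t in range(seq.frame_count):
            for j in range(len(seq.catalog)):
                if seq.present[t, j]:
                    assert fused.provenance[t, j] in (TAG_FRONT, TAG_SIDE, TAG_KALMAN)
                else:
                    assert fused.provenance[t, j] is None

    def test_fused_beats_front_only_depth(self, default_session):
        front, side, gt = default_session
        fused = fuse_streams(front, side).sequence
        for joint in ("right_elbow", "right_wrist"):
            e_front = depth_error_series(front, gt.world, joint).mean()
            e_fused = depth_error_series(fused, gt.world, joint).mean()
            assert e_fused < e_front

    def test_sync_ablation_increases_error(self, flexion_truth):
        rig = default_rig(time_offset=10)
        gt = GroundTruth(world=flexion_truth.world, rig=rig,
                         exercise=flexion_truth.exercise, seed=6)
        front, side = observe_front(gt), observe_side(gt)
        e_sync = np.mean([
            depth_error_series(fuse_streams(front, side, FusionConfig()).sequence,
                               gt.world, j).mean()
            for j in ("right_elbow", "right_wrist")
        ])
        e_nosync = np.mean([
            depth_error_series(
                fuse_streams(front, side, FusionConfig(sync_on=False)).sequence,
                gt.world, j,
            ).mean()
            for j in ("right_elbow", "right_wrist")
        ])
        assert e_nosync > e_sync

    def test_frame_rate_mismatch_rejected(self, default_session):
        front, side, _ = default_session
        bad = side.copy()
        bad.frame_rate = 25.0
        with pytest.raises(ConfigError):
            fuse_streams(front, bad)

    def test_exact_transformed_copy_recovers_front_truth(self, flexion_truth):
        rig = RigSpec(true_theta=91.0, true_T=(-0.1, 0.02, -0.3))
        gt = GroundTruth(world=flexion_truth.world, rig=rig,
                         exercise=flexion_truth.exercise, seed=0)
        fused = fuse_streams(observe_front(gt), observe_side(gt)).sequence
        idx = fused.frame_indices
        assert np.nanmax(np.abs(fused.positions - gt.world.positions[idx])) < 1e-6
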