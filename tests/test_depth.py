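import numpy as np
import pytest
from scipy.interpolate import CubicSpline

from gaitcal import (DegenerateGeometryError, DistortionConfig,
                     MissingLandmarkError, ankle_angle_kinect,
                     compute_kinect_angles, forward_kinect,
                     hip_angles_kinect, knee_angle_kinect,
                     pelvis_frame_kinect, resample_uniform,
                     thigh_frame_kinect)
from gaitcal.prep import LandmarkSeries


class TestPelvisFrameKinect:
    def test_upright_canonical(self):
        # lab: +X anterior, +Y up, +Z right
        f = pelvis_frame_kinect([0, 1, 0], [0, 1.3, 0],
                                [0, 0.95, -0.1], [0, 0.95, 0.1])
        assert np.allclose(f.y, [0, 1, 0], atol=1e-12)
        assert np.allclose(f.x, [1, 0, 0], atol=1e-12)   # anterior
        assert np.allclose(f.z, [0, 0, 1], atol=1e-12)   # right

    def test_rotation_equivariance(self, random_rotation):
        R = random_rotation
        args = [np.array(p, float) for p in
                ([0, 1, 0], [0.05, 1.3, 0.02], [0.01, 0.95, -0.1],
                 [0, 0.96, 0.11])]
        f0 = pelvis_frame_kinect(*args)
        f1 = pelvis_frame_kinect(*(R @ a for a in args))
        assert np.allclose(f1.matrix, R @ f0.matrix, atol=1e-9)

    def test_degenerate_spine(self):
        with pytest.raises(DegenerateGeometryError):
            pelvis_frame_kinect([0, 1, 0], [0, 1, 0],
                                [0, 1, -0.1], [0, 1, 0.1])

    def test_spine_parallel_to_hip_line(self):
        with pytest.raises(DegenerateGeometryError):
            pelvis_frame_kinect([0, 1, 0], [0, 1, 0.3],
                                [0, 1, -0.1], [0, 1, 0.1])


class TestThighFrameKinect:
    def test_canonical_slightly_flexed(self):
        hip = np.array([0, 0.9, 0.1])
        knee = np.array([0.0, 0.5, 0.1])
        ankle = np.array([-0.05, 0.1, 0.1])   # ankle behind the knee
        f = thigh_frame_kinect(hip, knee, ankle)
        assert np.allclose(f.y, [0, 1, 0], atol=1e-12)
        assert np.allclose(f.origin, knee)
        # plane normal points left for a flexed right knee
        assert f.z @ np.array([0, 0, 1]) < 0

    def test_rotation_equivariance(self, random_rotation):
        R = random_rotation
        args = [np.array(p, float) for p in
                ([0.02, 0.9, 0.1], [0, 0.5, 0.12], [-0.05, 0.1, 0.1])]
        f0 = thigh_frame_kinect(*args)
        f1 = thigh_frame_kinect(*(R @ a for a in args))
        assert np.allclose(f1.matrix, R @ f0.matrix, atol=1e-9)

    def test_collinear_without_history_raises(self):
        with pytest.raises(DegenerateGeometryError):
            thigh_frame_kinect([0, 1, 0], [0, 0.5, 0], [0, 0, 0])

    def test_collinear_carries_previous_normal(self):
        prev = thigh_frame_kinect([0, 0.9, 0.1], [0, 0.5, 0.1],
                                  [-0.05, 0.1, 0.1])
        f = thigh_frame_kinect([0, 1, 0], [0, 0.5, 0], [0, 0, 0],
                               prev_z=prev.z)
        assert np.allclose(f.y, [0, 1, 0], atol=1e-12)
        assert abs(np.linalg.norm(f.z) - 1) < 1e-9


class TestVectorAngles:
    def test_knee_straight_leg(self):
        assert knee_angle_kinect([0, 1, 0], [0, 0, 0], [0, -1, 0]) \
            == pytest.approx(0.0, abs=1e-10)

    def test_knee_right_angle(self):
        assert knee_angle_kinect([0, 1, 0], [0, 0, 0], [1, 0, 0]) \
            == pytest.approx(90.0, abs=1e-10)

    def test_knee_matches_arccos_oracle(self, rng):
        for _ in range(25):
            hip, knee, ankle = rng.normal(size=(3, 3))
            u = hip - knee
            v = ankle - knee
            expected = 180.0 - np.degrees(np.arccos(
                np.clip(u @ v / np.linalg.norm(u) / np.linalg.norm(v),
                        -1, 1)))
            assert knee_angle_kinect(hip, knee, ankle) \
                == pytest.approx(expected, abs=1e-9)

    def test_knee_zero_length_raises(self):
        with pytest.raises(DegenerateGeometryError):
            knee_angle_kinect([0, 0, 0], [0, 0, 0], [0, -1, 0])

    def test_ankle_perpendicular_is_zero(self):
        assert ankle_angle_kinect([0, 1, 0], [0, 0, 0], [1, 0, 0]) \
            == pytest.approx(0.0, abs=1e-10)

    def test_ankle_120_degrees_gives_30(self):
        foot = [np.sin(np.radians(120)), np.cos(np.radians(120)), 0.0]
        assert ankle_angle_kinect([0, 1, 0], [0, 0, 0], foot) \
            == pytest.approx(30.0, abs=1e-9)

    def test_ankle_matches_arccos_oracle(self, rng):
        for _ in range(25):
            knee, ankle, foot = rng.normal(size=(3, 3))
            u = knee - ankle
            v = foot - ankle
            expected = np.degrees(np.arccos(
                np.clip(u @ v / np.linalg.norm(u) / np.linalg.norm(v),
                        -1, 1))) - 90.0
            assert ankle_angle_kinect(knee, ankle, foot) \
                == pytest.approx(expected, abs=1e-9)

    def test_scale_invariance(self, rng):
        pts = rng.normal(size=(3, 3))
        k0 = knee_angle_kinect(*pts)
        a0 = ankle_angle_kinect(*pts)
        assert knee_angle_kinect(*(7.3 * pts)) == pytest.approx(k0, abs=1e-9)
        assert ankle_angle_kinect(*(7.3 * pts)) == pytest.approx(a0, abs=1e-9)

    def test_rotation_invariance(self, rng, random_rotation):
        pts = rng.normal(size=(3, 3))
        R = random_rotation
        rpts = pts @ R.T
        assert knee_angle_kinect(*rpts) == pytest.approx(
            knee_angle_kinect(*pts), abs=1e-6)
        assert ankle_angle_kinect(*rpts) == pytest.approx(
            ankle_angle_kinect(*pts), abs=1e-6)


class TestHipAnglesKinect:
    def _pose(self, flexion=0.0):
        """Landmark set for a neutral/flexed right hip, slightly bent knee."""
        from gaitcal.geometry import NEUTRAL_AXES, compose_xyz, rot_x

        pelvis = {"spine_base": np.array([0., 1.0, 0.]),
                  "spine_mid": np.array([0., 1.25, 0.]),
                  "hip_l": np.array([0., 0.95, -0.1]),
                  "hip_r": np.array([0., 0.95, 0.1])}
        T = NEUTRAL_AXES @ compose_xyz(flexion, 0.0, 0.0)
        S = T @ rot_x(-8.0)             # small knee flexion, non-degenerate
        knee = pelvis["hip_r"] - 0.4 * T[:, 2]
        ankle = knee - 0.38 * S[:, 2]
        return pelvis, knee, ankle

    def test_neutral_pose_zero(self):
        pelvis, knee, ankle = self._pose(0.0)
        pf = pelvis_frame_kinect(**pelvis)
        tf = thigh_frame_kinect(pelvis["hip_r"], knee, ankle)
        out = hip_angles_kinect(pf, tf)
        assert out.flexion == pytest.approx(0.0, abs=1e-9)
        assert out.adduction == pytest.approx(0.0, abs=1e-9)
        assert out.rotation == pytest.approx(0.0, abs=1e-9)

    def test_pure_flexion_30(self):
        pelvis, knee, ankle = self._pose(30.0)
        pf = pelvis_frame_kinect(**pelvis)
        tf = thigh_frame_kinect(pelvis["hip_r"], knee, ankle)
        out = hip_angles_kinect(pf, tf)
        assert out.flexion == pytest.approx(30.0, abs=1e-9)
        assert out.adduction == pytest.approx(0.0, abs=1e-9)

    def test_matches_marker_euler_on_identical_frames(self, random_rotation):
        # identical proximal/distal anatomical frames -> identical output of
        # the shared Euler machinery
        from gaitcal import euler_joint_angles
        from gaitcal.marker import SegmentFrame

        f = SegmentFrame.from_matrix(np.zeros(3), random_rotation)
        out = euler_joint_angles(f, f)
        assert (out.flexion, out.adduction, out.rotation) \
            == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)


class TestComputeKinectAngles:
    def test_identity_distortion_roundtrip(self, two_cycle_cfg,
                                           two_cycle_angles):
        series = forward_kinect(two_cycle_angles, two_cycle_cfg,
                                DistortionConfig())
        uniform = resample_uniform(series, 100.0)
        out = compute_kinect_angles(uniform)
        truth = CubicSpline(two_cycle_angles.time, two_cycle_angles.values,
                            axis=0)(out.time)
        rmse = np.sqrt(np.mean((out.values - truth) ** 2, axis=0))
        assert np.all(rmse < 0.5)

    def test_affine_distortion_recovered_as_distorted(self, two_cycle_cfg,
                                                      two_cycle_angles):
        dist = DistortionConfig(gains=(0.7, 1, 1, 1, 1),
                                offsets=(-10.0, 0, 0, 0, 0))
        series = forward_kinect(two_cycle_angles, two_cycle_cfg, dist)
        out = compute_kinect_angles(resample_uniform(series, 100.0))
        truth = CubicSpline(two_cycle_angles.time, two_cycle_angles.values,
                            axis=0)(out.time)
        expected_hip = 0.7 * truth[:, 0] - 10.0
        rmse = np.sqrt(np.mean((out.values[:, 0] - expected_hip) ** 2))
        assert rmse < 0.5

    def test_static_pose_near_constant(self, two_cycle_cfg):
        from gaitcal import FourierSeries, GaitProfileConfig, \
            generate_true_angles
        from gaitcal.prep import DOF_NAMES

        profiles = {d: FourierSeries() for d in DOF_NAMES}
        profiles["knee_flexion"] = FourierSeries(8.0)   # avoid degeneracy
        cfg = GaitProfileConfig(profiles=profiles, n_cycles=1)
        ta = generate_true_angles(cfg)
        series = forward_kinect(ta, cfg, DistortionConfig())
        out = compute_kinect_angles(resample_uniform(series, 100.0))
        assert np.max(np.abs(out.values - out.values[0])) < 1e-6

    def test_missing_spine_mid_named(self, two_cycle_cfg, two_cycle_angles):
        series = forward_kinect(two_cycle_angles, two_cycle_cfg,
                                DistortionConfig())
        del series.landmarks["spine_mid"]
        with pytest.raises(MissingLandmarkError, match="spine_mid"):
            compute_kinect_angles(resample_uniform(series, 100.0))

    def test_rigid_rotation_invariance(self, two_cycle_cfg, two_cycle_angles,
                                       random_rotation):
        R = random_rotation
        series = forward_kinect(two_cycle_angles, two_cycle_cfg,
                                DistortionConfig())
        uniform = resample_uniform(series, 100.0)
        rotated = LandmarkSeries(
            "depth", uniform.time,
            {n: p @ R.T for n, p in uniform.landmarks.items()},
            uniform.nominal_rate)
        a0 = compute_kinect_angles(uniform)
        a1 = compute_kinect_angles(rotated)
        assert np.max(np.abs(a0.values - a1.values)) < 1e-6
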