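"""Rigid transforms, pose parameterization, projection and triangulation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fluorokin.geometry import (GimbalLockError, Pose6DOF, ProjectionModel,
                                RigidTransform, cardan_zxy_compose,
                                pose_to_transform, rigid_point_fit,
                                transform_to_cardan_zxy, transform_to_pose,
                                triangulate_rsa, wrap_angle_deg)


def make_camera(n=64, spacing=2.0, sid=700.0, sdd=1000.0):
    half = (n - 1) / 2.0 * spacing
    u, v = np.array([0.0, 0.0, 1.0]), np.array([0.0, -1.0, 0.0])
    centre = np.array([sid - sdd, 0.0, 0.0])
    return ProjectionModel(np.array([sid, 0.0, 0.0]), centre - half * u - half * v,
                           u, v, (spacing, spacing), (n, n))


class TestPose:
    def test_identity(self):
        T = pose_to_transform(Pose6DOF())
        assert np.allclose(T.rotation, np.eye(3))
        assert np.allclose(T.translation, 0)

    def test_pure_translation(self):
        T = pose_to_transform(Pose6DOF(1, 2, 3))
        assert np.allclose(T.rotation, np.eye(3))
        assert np.allclose(T.translation, [1, 2, 3])

    def test_single_axis_closed_form(self):
        # alpha=30 equals the hand-written x-axis rotation matrix
        c, s = np.cos(np.radians(30)), np.sin(np.radians(30))
        Rx = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        assert np.allclose(pose_to_transform(Pose6DOF(alpha=30)).rotation, Rx)

    def test_round_trip_1000_random_poses(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            v = np.concatenate([rng.uniform(-50, 50, 3), rng.uniform(-170, 170, 2),
                                [rng.uniform(-85, 85)]])[[0, 1, 2, 3, 5, 4]]
            p = Pose6DOF.from_vector(v)
            back = transform_to_pose(pose_to_transform(p))
            assert np.abs(back.to_vector() - p.to_vector()).max() < 1e-8

    def test_angle_wrapping(self):
        assert wrap_angle_deg(190.0) == pytest.approx(-170.0)
        assert wrap_angle_deg(-180.0) == pytest.approx(180.0)
        assert Pose6DOF(gamma=365.0).gamma == pytest.approx(5.0)

    def test_gimbal_lock_raises(self):
        T = pose_to_transform(Pose6DOF(beta=90))
        with pytest.raises(GimbalLockError):
            transform_to_pose(T)


class TestCardanZXY:
    def test_identity(self):
        assert transform_to_cardan_zxy(RigidTransform.identity()) == (0, 0, 0)

    def test_pure_z(self):
        R = Rotation.from_euler("z", 25, degrees=True).as_matrix()
        z, x, y = transform_to_cardan_zxy(R)
        assert (z, x, y) == pytest.approx((25, 0, 0), abs=1e-10)

    def test_round_trip(self):
        R = cardan_zxy_compose(10, -5, 7)
        assert transform_to_cardan_zxy(R) == pytest.approx((10, -5, 7), abs=1e-9)

    def test_compose_reproduces_rotation(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ang = rng.uniform(-80, 80, 3)
            R = cardan_zxy_compose(*ang)
            assert np.abs(cardan_zxy_compose(*transform_to_cardan_zxy(R)) - R).max() < 1e-9

    def test_gimbal_flags_degenerate_axis(self):
        R = cardan_zxy_compose(10, 90, 5)
        with pytest.raises(GimbalLockError, match="x axis"):
            transform_to_cardan_zxy(R)


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_inverse(self):
        rng = np.random.default_rng(0)
        T1 = RigidTransform.from_rotvec_deg(rng.uniform(-90, 90, 3), rng.uniform(-10, 10, 3))
        T2 = RigidTransform.from_rotvec_deg(rng.uniform(-90, 90, 3), rng.uniform(-10, 10, 3))
        p = rng.uniform(-5, 5, (10, 3))
        assert np.allclose((T1 @ T2).apply(p), T1.apply(T2.apply(p)))
        assert np.allclose((T1 @ T1.inverse()).apply(p), p)


class TestProjection:
    def test_principal_ray_hits_principal_point(self):
        cam = make_camera()
        on_axis = cam.source + 0.5 * (cam.pixel_to_point(cam.principal_point) - cam.source)
        assert np.allclose(cam.project_points(on_axis), cam.principal_point)

    def test_point_on_detector_projects_to_itself(self):
        cam = make_camera()
        px = np.array([10.0, 40.0])
        assert np.allclose(cam.project_points(cam.pixel_to_point(px)), px)

    def test_matches_symbolic_line_plane_intersection(self, rng):
        cam = make_camera()
        for _ in range(20):
            p = rng.uniform(-60, 60, 3)
            got = cam.project_points(p)
            # brute-force oracle: solve source + t (p - source) on the plane
            n = np.cross(cam.u_axis, cam.v_axis)
            t = ((cam.detector_origin - cam.source) @ n) / ((p - cam.source) @ n)
            hit = cam.source + t * (p - cam.source)
            exp = np.array([(hit - cam.detector_origin) @ cam.u_axis,
                            (hit - cam.detector_origin) @ cam.v_axis]) / cam.pixel_spacing
            assert np.allclose(got, exp, atol=1e-9)

    def test_rigid_motion_invariance(self, rng):
        cam = make_camera()
        T = RigidTransform.from_rotvec_deg([15, -30, 40], [10, -5, 20])
        moved = ProjectionModel(T.apply(cam.source), T.apply(cam.detector_origin),
                                T.rotation @ cam.u_axis, T.rotation @ cam.v_axis,
                                cam.pixel_spacing, cam.resolution)
        pts = rng.uniform(-50, 50, (25, 3))
        assert np.allclose(moved.project_points(T.apply(pts)), cam.project_points(pts),
                           atol=1e-8)


class TestRigidPointFit:
    def test_identity_and_exact_recovery(self, rng):
        src = rng.uniform(-30, 30, (12, 3))
        T0, rms0 = rigid_point_fit(src, src)
        assert rms0 < 1e-12 and np.allclose(T0.rotation, np.eye(3))
        T = RigidTransform.from_rotvec_deg([20, -35, 50], [4, 5, -6])
        Tf, rms = rigid_point_fit(src, T.apply(src))
        assert rms < 1e-9
        assert np.abs(Tf.rotation - T.rotation).max() < 1e-9
        assert np.abs(Tf.translation - T.translation).max() < 1e-9

    def test_noisy_residual_matches_sigma(self):
        rng = np.random.default_rng(42)
        src = rng.uniform(-30, 30, (10, 3))
        T = RigidTransform.from_rotvec_deg([10, 5, -8], [1, 2, 3])
        dst = T.apply(src) + rng.normal(0, 0.1, (10, 3))
        _, rms = rigid_point_fit(src, dst)
        assert 0.05 < rms < 0.15  # within [0.5, 1.5] sigma

    def test_collinear_raises(self):
        line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            rigid_point_fit(line, line)

    def test_zero_residual_iff_exact_rigid_image(self, rng):
        src = rng.uniform(-20, 20, (8, 3))
        dst = src.copy()
        dst[0] += 1.0  # non-rigid perturbation
        _, rms = rigid_point_fit(src, dst)
        assert rms > 1e-3


class TestTriangulateRSA:
    def _pair(self):
        camA = make_camera()
        u, v = np.array([-1.0, 0.0, 0.0]), np.array([0.0, -1.0, 0.0])
        half = 63.0 / 2 * 2.0
        centre = np.array([0.0, 0.0, -300.0])
        camB = ProjectionModel(np.array([0.0, 0.0, 700.0]), centre - half * u - half * v,
                               u, v, (2.0, 2.0), (64, 64))
        return camA, camB

    def test_exact_recovery(self, rng):
        cams = self._pair()
        for _ in range(10):
            p = rng.uniform(-40, 40, 3)
            rec, res = triangulate_rsa((cams[0].project_points(p), cams[1].project_points(p)), cams)
            assert np.abs(rec - p).max() < 1e-6
            assert res < 1e-8

    def test_isocenter_symmetric(self):
        cams = self._pair()
        p = np.zeros(3)
        rec, _ = triangulate_rsa((cams[0].project_points(p), cams[1].project_points(p)), cams)
        assert np.abs(rec).max() < 1e-9

    def test_noise_bound(self):
        cams = self._pair()
        rng = np.random.default_rng(5)
        p = np.array([10.0, -20.0, 5.0])
        mag = cams[0].magnification_at(p)
        errs = []
        for _ in range(50):
            obs = [cams[i].project_points(p) + rng.normal(0, 0.5, 2) for i in range(2)]
            rec, _ = triangulate_rsa(obs, cams)
            errs.append(np.linalg.norm(rec - p))
        assert max(errs) < 2 * (2.0 * 0.5 / mag) * 2 * mag  # < 2 * px_spacing * mag

    def test_parallel_rays_raise(self):
        cam = make_camera()
        with pytest.raises(ValueError, match="parallel"):
            triangulate_rsa((np.array([32.0, 32.0]), np.array([32.0, 32.0])), (cam, cam))
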