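import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import random_marker_pose, rotation_angle_deg

from arscope import (
    Correspondence,
    MarkerSpec,
    Pose,
    compose_homography,
    estimate_homography_dlt,
    pose_from_homography,
    project,
    refine_pose_lm,
    register_marker_pose,
    render_marker_scene,
    validation_camera,
)
from arscope.calibration import CameraModel, intrinsic_matrix
from arscope.errors import BehindCameraError, FramingError, UnderdeterminedError
from arscope.pose import Homography, reprojection_rms


def _grid_correspondences(pose, cam, n=4, half_mm=40.0):
    g = np.linspace(-half_mm, half_mm, n)
    M = np.stack([*np.meshgrid(g, g), np.zeros((n, n))], axis=-1).reshape(-1, 3)
    m = project(M, pose, cam)
    return [Correspondence(Mi, mi) for Mi, mi in zip(M, m)]


class TestHomographyDLT:
    def test_identity_map(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        corr = [Correspondence((x, y, 0.0), (x, y)) for x, y in pts]
        H = estimate_homography_dlt(corr).H
        assert np.allclose(H / H[2, 2], np.eye(3), atol=1e-9)

    def test_recovers_known_map_on_unit_square(self):
        H_gt = np.array([[2.0, 0, 1], [0, 2, -1], [0, 0, 1]])
        pts = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        mapped = (np.c_[pts, np.ones(4)] @ H_gt.T)
        mapped = mapped[:, :2] / mapped[:, 2:3]
        corr = [Correspondence((x, y, 0.0), m) for (x, y), m in zip(pts, mapped)]
        H = estimate_homography_dlt(corr).H
        H_gt_c = H_gt / np.linalg.norm(H_gt)
        assert np.max(np.abs(H - H_gt_c)) < 1e-9

    def test_three_points_underdetermined(self):
        corr = [Correspondence((x, y, 0.0), (x, y))
                for x, y in [(0, 0), (1, 0), (0, 1)]]
        with pytest.raises(UnderdeterminedError):
            estimate_homography_dlt(corr)


class TestPoseFromHomography:
    def test_identity_pose_forward_composition(self):
        K = intrinsic_matrix(validation_camera())
        H = K @ np.stack([np.array([1.0, 0, 0]), np.array([0.0, 1, 0]),
                          np.array([0.0, 0, 1])], axis=1)
        p = pose_from_homography(Homography(H), K)
        assert np.allclose(p.R, np.eye(3), atol=1e-10)
        assert np.allclose(p.t, [0, 0, 1], atol=1e-10)

    def test_compose_then_decompose_recovers_pose(self):
        rng = np.random.default_rng(3)
        K = intrinsic_matrix(validation_camera())
        for _ in range(25):
            ax = rng.normal(size=3)
            ang = rng.uniform(0, np.radians(78))
            R = Rotation.from_rotvec(ax / np.linalg.norm(ax) * ang).as_matrix()
            t = np.array([rng.uniform(-100, 100), rng.uniform(-100, 100),
                          rng.uniform(300, 2000)])
            pose = Pose(R=R, t=t)
            rec = pose_from_homography(compose_homography(pose, K), K)
            assert np.radians(rotation_angle_deg(pose.R, rec.R)) < 1e-6
            assert np.linalg.norm(pose.t - rec.t) / np.linalg.norm(pose.t) < 1e-6

    def test_scale_invariance_including_negative(self):
        K = intrinsic_matrix(validation_camera())
        pose = Pose(R=Rotation.from_euler('xyz', [10, -15, 40], degrees=True).as_matrix(),
                    t=np.array([20.0, -5.0, 700.0]))
        H = compose_homography(pose, K).H
        p1 = pose_from_homography(Homography(H), K)
        p2 = pose_from_homography(Homography(-7.0 * H), K)
        assert np.allclose(p1.R, p2.R, atol=1e-12)
        assert np.allclose(p1.t, p2.t, atol=1e-9)

    def test_returned_rotation_is_orthonormal(self):
        rng = np.random.default_rng(8)
        K = intrinsic_matrix(validation_camera())
        for _ in range(10):
            pose = random_marker_pose(rng)
            rec = pose_from_homography(compose_homography(pose, K), K)
            assert np.max(np.abs(rec.R.T @ rec.R - np.eye(3))) < 1e-8
            assert abs(np.linalg.det(rec.R) - 1.0) < 1e-8


class TestProjection:
    def test_optical_axis_point_hits_principal_point(self):
        cam = validation_camera()
        cam_nodist = CameraModel(f=cam.f, s=cam.s, u=cam.u, v=cam.v, a=cam.a,
                                 image_size=cam.image_size)
        px = project(np.zeros(3), Pose(R=np.eye(3), t=np.array([0.0, 0, 1])),
                     cam_nodist)
        assert px == pytest.approx([349.727, 279.897])

    def test_behind_camera_raises_with_indices(self):
        cam = validation_camera()
        pose = Pose(R=np.eye(3), t=np.array([0.0, 0.0, -1.0]))
        with pytest.raises(BehindCameraError) as exc:
            project(np.zeros((1, 3)), pose, cam)
        assert exc.value.indices == [0]

    def test_agrees_with_explicit_matrix_oracle(self, simple_camera):
        rng = np.random.default_rng(5)
        pose = random_marker_pose(rng)
        pts = rng.uniform(-50, 50, size=(20, 3))
        px = project(pts, pose, simple_camera)
        P = intrinsic_matrix(simple_camera) @ np.hstack([pose.R, pose.t[:, None]])
        h = (np.c_[pts, np.ones(20)] @ P.T)
        oracle = h[:, :2] / h[:, 2:3]
        assert np.max(np.abs(px - oracle)) < 1e-10


class TestLMRefinement:
    def test_ground_truth_is_fixed_point(self, simple_camera):
        rng = np.random.default_rng(1)
        pose = random_marker_pose(rng)
        corr = _grid_correspondences(pose, simple_camera)
        refined = refine_pose_lm(pose, corr, simple_camera)
        assert np.max(np.abs(pose.R - refined.R)) < 1e-10
        assert np.max(np.abs(pose.t - refined.t)) < 1e-8
        assert reprojection_rms(refined, corr, simple_camera) < 1e-9

    def test_converges_from_perturbed_start(self, simple_camera):
        rng = np.random.default_rng(2)
        pose = random_marker_pose(rng, tilt_max_deg=30)
        corr = _grid_correspondences(pose, simple_camera)
        dR = Rotation.from_rotvec(np.radians(5.0) * np.array([1, 0, 0])).as_matrix()
        pose0 = Pose(R=dR @ pose.R, t=pose.t * 1.05)
        refined = refine_pose_lm(pose0, corr, simple_camera)
        assert reprojection_rms(refined, corr, simple_camera) < 1e-6

    def test_objective_never_increases_over_noisy_trials(self, simple_camera):
        rng = np.random.default_rng(4)
        for trial in range(50):
            pose = random_marker_pose(rng, tilt_max_deg=45)
            corr = _grid_correspondences(pose, simple_camera)
            noisy = [Correspondence(c.M, c.m + rng.normal(0, 1.0, size=2))
                     for c in corr]
            obj0 = reprojection_rms(pose, noisy, simple_camera)
            refined = refine_pose_lm(pose, noisy, simple_camera)
            assert reprojection_rms(refined, noisy, simple_camera) <= obj0 + 1e-12


class TestEndToEndRegistration:
    def test_fronto_parallel_depth_within_half_percent(self):
        cam = validation_camera()
        spec = MarkerSpec(code_id=0xA5C3)
        pose = Pose(R=np.eye(3), t=np.array([0.0, 0.0, 500.0]))
        img, _ = render_marker_scene(cam, pose, spec)
        reg = register_marker_pose(img, cam, spec)
        assert reg.ok and reg.code_id == 0xA5C3
        assert abs(reg.pose.t[2] - 500.0) / 500.0 < 0.005

    def test_image_without_marker_gives_no_registration(self):
        cam = validation_camera()
        blank = np.full((480, 640), 255, dtype=np.uint8)
        reg = register_marker_pose(blank, cam, MarkerSpec(code_id=1))
        assert not reg.ok and reg.pose is None
        assert reg.failure

    def test_random_viewing_angles_pose_error_below_half_degree(self, simple_camera):
        spec = MarkerSpec(code_id=0x1B7)
        rng = np.random.default_rng(42)
        n_ok = 0
        attempts = 0
        while n_ok < 20 and attempts < 60:
            attempts += 1
            pose = random_marker_pose(rng, tilt_max_deg=60)  # 30-90 deg camera angle
            try:
                img, _ = render_marker_scene(simple_camera, pose, spec,
                                             seed=attempts)
            except FramingError:
                continue
            reg = register_marker_pose(img, simple_camera, spec)
            assert reg.ok, reg.failure
            assert rotation_angle_deg(pose.R, reg.pose.R) < 0.5
            n_ok += 1
        assert n_ok == 20

    def test_end_to_end_reprojection_rms_subpixel(self, simple_camera):
        spec = MarkerSpec(code_id=0x1B7)
        pose = Pose(R=Rotation.from_euler('x', 25, degrees=True).as_matrix(),
                    t=np.array([10.0, -5.0, 450.0]))
        img, _ = render_marker_scene(simple_camera, pose, spec)
        reg = register_marker_pose(img, simple_camera, spec)
        assert reg.ok and reg.rms_px < 0.5
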