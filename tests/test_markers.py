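import numpy as np
import pytest

from arscope import (
    MarkerSpec,
    Pose,
    adaptive_threshold,
    decode_marker,
    detect_marker,
    detect_marker_quad,
    generate_marker,
    render_marker_scene,
)
from arscope.markers import refine_corners_subpixel
from arscope.errors import MarkerCapacityError
from scipy.spatial.transform import Rotation


class TestGeneration:
    def test_zero_payload_is_white_except_orientation_cells(self):
        spec = MarkerSpec(grid=4, code_id=0x0000)
        img = generate_marker(spec, pixels_per_cell=1)
        interior = img[1:-1, 1:-1]
        # orientation cells: TL black, TR black, BL white
        assert interior[0, 0] == 0 and interior[0, -1] == 0
        assert interior[-1, 0] == 255
        # all other interior cells are white
        mask = np.ones_like(interior, dtype=bool)
        mask[0, 0] = mask[0, -1] = False
        assert np.all(interior[mask] == 255)
        # black border, strictly binary
        assert np.all(img[0] == 0) and np.all(img[:, 0] == 0)
        assert set(np.unique(img)) <= {0, 255}

    def test_payload_overflowing_orientation_layout_raises(self):
        with pytest.raises(MarkerCapacityError):
            generate_marker(MarkerSpec(grid=4, code_id=0xFFFF))

    def test_full_payload_without_orientation_cells_is_all_black(self):
        spec = MarkerSpec(grid=4, code_id=0xFFFF, orientation_cells=False)
        img = generate_marker(spec, pixels_per_cell=2)
        assert np.all(img == 0)

    def test_fronto_parallel_generate_decode_round_trip(self):
        spec = MarkerSpec(grid=5, code_id=0xA5C3)
        marker = generate_marker(spec, pixels_per_cell=16)
        pad = 32
        frame = np.full((marker.shape[0] + 2 * pad,) * 2, 255, dtype=np.uint8)
        frame[pad:-pad, pad:-pad] = marker
        corners = detect_marker_quad(adaptive_threshold(frame))
        assert corners is not None
        code, rot = decode_marker(frame, corners, spec)
        assert code == 0xA5C3 and rot == 0


class TestAdaptiveThreshold:
    def test_constant_image_falls_to_black(self):
        img = np.full((10, 12), 128, dtype=np.uint8)
        out = adaptive_threshold(img)
        assert not out.any()  # equality with the mean classifies black

    def test_two_level_image_splits_exactly(self):
        img = np.empty((4, 10), dtype=np.uint8)
        img[:, :5] = 50
        img[:, 5:] = 200
        out = adaptive_threshold(img)
        assert np.array_equal(out, img == 200)  # threshold 125

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            adaptive_threshold(np.zeros((5, 5)), roi=(2, 2, 2, 4))

    def test_gradient_illumination_preserves_cell_classes(self, simple_camera):
        """Marker-interior classification under a 0.6-1.4x linear gradient
        matches the unshaded render when thresholding over the marker ROI."""
        spec = MarkerSpec(code_id=0x2D71)
        pose = Pose(R=np.eye(3), t=np.array([0.0, 0.0, 420.0]))
        flat, gt = render_marker_scene(simple_camera, pose, spec)
        shaded, _ = render_marker_scene(simple_camera, pose, spec,
                                        lighting_gradient=(0.6, 1.4))
        x0, y0 = np.floor(gt.corners_px.min(axis=0)).astype(int)
        x1, y1 = np.ceil(gt.corners_px.max(axis=0)).astype(int) + 1
        roi = (y0, x0, y1, x1)
        bin_flat = adaptive_threshold(flat, roi=roi)
        bin_shaded = adaptive_threshold(shaded, roi=roi)
        # compare classes at the exact cell centres of the interior grid
        from arscope._homography import apply_homography, dlt_homography
        S = spec.total_cells
        H = dlt_homography(np.array([[0, 0], [S, 0], [S, S], [0, S]], float),
                           gt.corners_px)
        b = spec.border_cells
        rr, cc = np.meshgrid(np.arange(spec.grid), np.arange(spec.grid))
        centres = apply_homography(H, np.stack(
            [b + cc.ravel() + 0.5, b + rr.ravel() + 0.5], axis=1))
        ij = np.rint(centres[:, ::-1]).astype(int)
        agree = bin_flat[ij[:, 0], ij[:, 1]] == bin_shaded[ij[:, 0], ij[:, 1]]
        assert agree.mean() >= 0.99

    def test_decode_invariant_under_gradient(self, simple_camera):
        spec = MarkerSpec(code_id=0x2D71)
        pose = Pose(R=np.eye(3), t=np.array([0.0, 0.0, 420.0]))
        shaded, _ = render_marker_scene(simple_camera, pose, spec,
                                        lighting_gradient=(0.6, 1.4))
        det = detect_marker(shaded, spec)
        assert det is not None and det.code_id == 0x2D71


class TestQuadDetection:
    def test_noiseless_corners_subpixel_accuracy(self, simple_camera):
        spec = MarkerSpec(code_id=0x0B2)
        pose = Pose(R=np.eye(3), t=np.array([0.0, 0.0, 450.0]))
        img, gt = render_marker_scene(simple_camera, pose, spec)
        corners = detect_marker_quad(adaptive_threshold(img))
        corners = refine_corners_subpixel(img, corners)
        rms = np.sqrt(np.mean(np.sum((corners - gt.corners_px) ** 2, axis=1)))
        assert rms < 0.5

    def test_noisy_corners_within_one_pixel(self, simple_camera):
        spec = MarkerSpec(code_id=0x0B2)
        pose = Pose(R=np.eye(3), t=np.array([0.0, 0.0, 450.0]))
        img, gt = render_marker_scene(simple_camera, pose, spec,
                                      noise_sigma=2.0 / 255.0, seed=11)
        corners = detect_marker_quad(adaptive_threshold(img))
        corners = refine_corners_subpixel(img, corners)
        rms = np.sqrt(np.mean(np.sum((corners - gt.corners_px) ** 2, axis=1)))
        assert rms < 1.0

    def test_blank_image_gives_failure_result(self):
        assert detect_marker_quad(np.ones((100, 100), dtype=bool)) is None
        assert detect_marker_quad(np.zeros((100, 100), dtype=bool)) is None

    def test_inplane_rotation_recovers_same_corner_set(self, simple_camera):
        spec = MarkerSpec(code_id=0x0B2)
        p0 = Pose(R=np.eye(3), t=np.array([0.0, 0.0, 450.0]))
        R90 = Rotation.from_euler('z', 90, degrees=True).as_matrix()
        p1 = Pose(R=R90, t=p0.t)
        img0, gt0 = render_marker_scene(simple_camera, p0, spec)
        img1, gt1 = render_marker_scene(simple_camera, p1, spec)
        c0 = refine_corners_subpixel(img0, detect_marker_quad(adaptive_threshold(img0)))
        c1 = refine_corners_subpixel(img1, detect_marker_quad(adaptive_threshold(img1)))
        # same physical square: corner sets agree after optimal matching
        d = np.linalg.norm(c0[:, None, :] - c1[None, :, :], axis=2)
        assert np.max(np.min(d, axis=1)) < 0.5

    def test_detection_is_deterministic(self, simple_camera):
        spec = MarkerSpec(code_id=0x31F)
        pose = Pose(R=np.eye(3), t=np.array([0.0, 0.0, 450.0]))
        img, _ = render_marker_scene(simple_camera, pose, spec)
        b = adaptive_threshold(img)
        c1 = detect_marker_quad(b)
        c2 = detect_marker_quad(b.copy())
        assert np.array_equal(c1, c2)


class TestDecoding:
    def test_rotation_canonicalization_indices(self, simple_camera):
        spec = MarkerSpec(code_id=0xA5C3)
        for k, theta in enumerate([0, 90, 180, 270]):
            R = Rotation.from_euler('z', theta, degrees=True).as_matrix()
            img, _ = render_marker_scene(
                simple_camera, Pose(R=R, t=np.array([0.0, 0.0, 500.0])), spec)
            corners = detect_marker_quad(adaptive_threshold(img))
            code, rot = decode_marker(img, corners, spec)
            assert code == 0xA5C3
            assert rot == k

    def test_corrupted_payload_cells_do_not_decode_to_original(self):
        spec = MarkerSpec(grid=5, code_id=0x1234)
        ppc = 16
        marker = generate_marker(spec, pixels_per_cell=ppc)
        # invert 4 payload cells (avoid the orientation corners)
        for (r, c) in [(1, 1), (1, 2), (2, 3), (3, 2)]:
            r0 = (spec.border_cells + r) * ppc
            c0 = (spec.border_cells + c) * ppc
            block = marker[r0:r0 + ppc, c0:c0 + ppc]
            marker[r0:r0 + ppc, c0:c0 + ppc] = 255 - block
        pad = 32
        frame = np.full((marker.shape[0] + 2 * pad,) * 2, 255, dtype=np.uint8)
        frame[pad:-pad, pad:-pad] = marker
        corners = detect_marker_quad(adaptive_threshold(frame))
        decoded = decode_marker(frame, corners, spec)
        # no error correction: either decode failure or a mismatched code
        assert decoded is None or decoded[0] != 0x1234

    def test_round_trip_over_random_codes_and_poses(self, small_camera):
        from conftest import random_marker_pose
        from arscope.errors import FramingError

        rng = np.random.default_rng(7)
        ok = tried = 0
        while ok < 50 and tried < 150:
            tried += 1
            code = int(rng.integers(0, 2 ** 16))
            spec = MarkerSpec(code_id=code)
            pose = random_marker_pose(rng, tz_range=(180.0, 240.0),
                                      lateral=(15.0, 10.0))
            try:
                img, gt = render_marker_scene(small_camera, pose, spec,
                                              seed=tried, supersample=2)
            except FramingError:
                continue
            extent = gt.corners_px.max(axis=0) - gt.corners_px.min(axis=0)
            if extent.max() < 100:
                continue
            det = detect_marker(img, spec)
            assert det is not None and det.code_id == code
            ok += 1
        assert ok == 50
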