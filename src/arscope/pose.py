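"""Homography-based camera pose estimation and nonlinear refinement.

A planar fiducial of known geometry induces a plane-to-image homography
H ~ K (R1 R2 t). Given calibrated intrinsics K, the pose is recovered by
decomposing K^-1 H into the first two rotation columns and the translation,
completing the rotation with the cross product R3 = R1 x R2, and projecting
onto SO(3). The pose is then refined by minimizing the sum of squared pixel
reprojection errors with a Levenberg-Marquardt iteration over an axis-angle
rotation increment and the translation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _homography
from .calibration import CameraModel, distort_point, intrinsic_matrix, undistort_point
from .errors import (
    BehindCameraError,
    DegenerateGeometryError,
    GeometryError,
    NonConvergenceError,
    UnderdeterminedError,
)


@dataclass(frozen=True)
class Correspondence:
    """A 3D world/marker point M (mm) paired with its 2D pixel observation m."""

    M: np.ndarray
    m: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "M", np.asarray(self.M, dtype=float).reshape(3))
        object.__setattr__(self, "m", np.asarray(self.m, dtype=float).reshape(2))
        if not (np.all(np.isfinite(self.M)) and np.all(np.isfinite(self.m))):
            raise ValueError("correspondence coordinates must be finite")


@dataclass(frozen=True)
class Homography:
    """A 3x3 plane-to-image projective map stored in canonical scale.

    Canonical scale: unit Frobenius norm, positive [2][2] entry when nonzero.
    """

    H: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "H", _homography.canonicalize(self.H))

    def apply(self, pts):
        return _homography.apply_homography(self.H, pts)


@dataclass(frozen=True)
class Pose:
    """Rigid camera pose: x_cam = R @ x_world + t.

    R must be a proper rotation (orthonormal, det +1, within 1e-8); t shares
    the length unit of the world points (mm throughout this package).
    """

    R: np.ndarray
    t: np.ndarray
    scale: float = 1.0  # homogeneous scale bookkeeping from the decomposition

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float).reshape(3, 3)
        t = np.asarray(self.t, dtype=float).reshape(3)
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-8:
            raise ValueError("R is not orthonormal within 1e-8")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("R must have determinant +1")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)

    def transform(self, points3d) -> np.ndarray:
        pts = np.asarray(points3d, dtype=float).reshape(-1, 3)
        return pts @ self.R.T + self.t


def estimate_homography_dlt(correspondences: Sequence[Correspondence]) -> Homography:
    """Total-least-squares DLT homography from planar (Z=0) correspondences."""
    corr = list(correspondences)
    if len(corr) < 4:
        raise UnderdeterminedError(
            f"homography estimation needs >=4 correspondences, got {len(corr)}")
    M = np.stack([c.M for c in corr])
    if np.any(np.abs(M[:, 2]) > 1e-12):
        raise ValueError("homography estimation requires Z = 0 world points")
    m = np.stack([c.m for c in corr])
    return Homography(_homography.dlt_homography(M[:, :2], m))


def pose_from_homography(H: Homography | np.ndarray, K: np.ndarray) -> Pose:
    """Decompose a plane-to-image homography into a camera pose.

    K^-1 H = (R1 R2 t) up to scale; the scale is fixed by the geometric mean
    of |R1|, |R2|, the sign by requiring the plane origin in front of the
    camera, and (R1 R2 R1xR2) is projected onto SO(3) by SVD.
    """
    Hm = H.H if isinstance(H, Homography) else _homography.canonicalize(H)
    K = np.asarray(K, dtype=float)
    if abs(np.linalg.det(K)) < 1e-12:
        raise DegenerateGeometryError("singular intrinsic matrix")
    M = np.linalg.solve(K, Hm)
    n1, n2 = np.linalg.norm(M[:, 0]), np.linalg.norm(M[:, 1])
    if n1 < 1e-15 or n2 < 1e-15:
        raise DegenerateGeometryError("homography is rank deficient under K^-1")
    lam = np.sqrt(n1 * n2)
    M = M / lam
    if abs(M[2, 2]) < 1e-15:
        raise GeometryError("plane origin at zero depth: sign is ambiguous")
    if M[2, 2] < 0:
        M = -M
    r1, r2, t = M[:, 0], M[:, 1], M[:, 2]
    R0 = np.stack([r1, r2, np.cross(r1, r2)], axis=1)
    U, _, Vt = np.linalg.svd(R0)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    return Pose(R=R, t=t, scale=lam)


def compose_homography(pose: Pose, K: np.ndarray) -> Homography:
    """Forward construction H = K (R1 R2 t) of the plane-to-image map."""
    M = np.stack([pose.R[:, 0], pose.R[:, 1], pose.t], axis=1)
    return Homography(np.asarray(K, dtype=float) @ M)


def project(points3d, pose: Pose, cam: CameraModel) -> np.ndarray:
    """Project world points to pixels: pinhole K[R|t] plus lens distortion.

    Raises BehindCameraError (listing offending indices) if any point has
    non-positive depth in the camera frame.
    """
    pts = np.asarray(points3d, dtype=float)
    single = pts.ndim == 1
    Pc = pose.transform(pts.reshape(-1, 3))
    bad = np.flatnonzero(Pc[:, 2] <= 1e-12)
    if bad.size:
        raise BehindCameraError(bad)
    n = Pc[:, :2] / Pc[:, 2:3]
    nd = distort_point(n, cam.distortion)
    px = np.empty_like(nd)
    px[:, 0] = cam.f * nd[:, 0] + cam.s * nd[:, 1] + cam.u
    px[:, 1] = cam.a * cam.f * nd[:, 1] + cam.v
    return px[0] if single else px


def reprojection_rms(pose: Pose, correspondences: Sequence[Correspondence],
                     cam: CameraModel) -> float:
    M = np.stack([c.M for c in correspondences])
    m = np.stack([c.m for c in correspondences])
    proj = project(M, pose, cam)
    return float(np.sqrt(np.mean(np.sum((proj - m) ** 2, axis=1))))


def _rotvec_to_matrix(w: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(w)
    if theta < 1e-12:
        Wx = _skew(w)
        return np.eye(3) + Wx  # first order is exact enough below 1e-12
    k = w / theta
    Kx = _skew(k)
    return np.eye(3) + np.sin(theta) * Kx + (1 - np.cos(theta)) * (Kx @ Kx)


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]],
                     [v[2], 0.0, -v[0]],
                     [-v[1], v[0], 0.0]])


def refine_pose_lm(pose0: Pose, correspondences: Sequence[Correspondence],
                   cam: CameraModel, max_iter: int = 100,
                   rel_tol: float = 1e-10) -> Pose:
    """Levenberg-Marquardt refinement of a pose against reprojection error.

    The rotation is updated by a left-multiplied axis-angle increment
    (R <- exp(w) R), translation additively; the damped normal equations use
    the analytic Jacobian through the projection and distortion chain.
    Damping starts at 1e-3, x10 on a rejected step, /10 on an accepted one.
    The returned pose never has a larger objective than ``pose0``.
    """
    corr = list(correspondences)
    if len(corr) < 4:
        raise UnderdeterminedError("pose refinement requires >=4 correspondences")
    M = np.stack([c.M for c in corr])
    m_obs = np.stack([c.m for c in corr])
    c = cam.distortion

    def residual_and_jacobian(R, t):
        Pc = M @ R.T + t
        if np.any(Pc[:, 2] <= 1e-12):
            return None, None
        x, y, z = Pc[:, 0], Pc[:, 1], Pc[:, 2]
        nx, ny = x / z, y / z
        r2 = nx * nx + ny * ny
        radial = 1.0 + c.alpha1 * r2 + c.alpha2 * r2 * r2
        xd = nx * radial + 2 * c.beta1 * nx * ny + c.beta2 * (r2 + 2 * nx * nx)
        yd = ny * radial + c.beta1 * (r2 + 2 * ny * ny) + 2 * c.beta2 * nx * ny
        px = cam.f * xd + cam.s * yd + cam.u
        py = cam.a * cam.f * yd + cam.v
        res = np.stack([px, py], axis=1) - m_obs

        # d(distorted)/d(normalized): 2x2 per point.
        dr2_dx, dr2_dy = 2 * nx, 2 * ny
        drad_dx = (c.alpha1 + 2 * c.alpha2 * r2) * dr2_dx
        drad_dy = (c.alpha1 + 2 * c.alpha2 * r2) * dr2_dy
        dxd_dx = radial + nx * drad_dx + 2 * c.beta1 * ny + c.beta2 * (dr2_dx + 4 * nx)
        dxd_dy = nx * drad_dy + 2 * c.beta1 * nx + c.beta2 * dr2_dy
        dyd_dx = ny * drad_dx + c.beta1 * dr2_dx + 2 * c.beta2 * ny
        dyd_dy = radial + ny * drad_dy + c.beta1 * (dr2_dy + 4 * ny) + 2 * c.beta2 * nx

        # pixel = A @ distorted + const, A = [[f, s], [0, a f]]
        a11, a12, a22 = cam.f, cam.s, cam.a * cam.f
        J_pix_n = np.empty((len(M), 2, 2))
        J_pix_n[:, 0, 0] = a11 * dxd_dx + a12 * dyd_dx
        J_pix_n[:, 0, 1] = a11 * dxd_dy + a12 * dyd_dy
        J_pix_n[:, 1, 0] = a22 * dyd_dx
        J_pix_n[:, 1, 1] = a22 * dyd_dy

        # d(normalized)/d(camera point)
        J_n_P = np.zeros((len(M), 2, 3))
        J_n_P[:, 0, 0] = 1.0 / z
        J_n_P[:, 0, 2] = -x / z ** 2
        J_n_P[:, 1, 1] = 1.0 / z
        J_n_P[:, 1, 2] = -y / z ** 2

        J_pix_P = J_pix_n @ J_n_P  # (N, 2, 3)

        # d(camera point)/d(w) for left increment exp(w) R: -[R M + t - t]x = -[RM]x
        RM = M @ R.T
        J = np.empty((len(M), 2, 6))
        for i in range(len(M)):
            J[i, :, :3] = J_pix_P[i] @ (-_skew(RM[i]))
            J[i, :, 3:] = J_pix_P[i]
        return res.reshape(-1), J.reshape(-1, 6)

    R, t = pose0.R.copy(), pose0.t.copy()
    res, J = residual_and_jacobian(R, t)
    if res is None:
        raise BehindCameraError(range(len(corr)))
    cost = float(res @ res)
    lam = 1e-3
    for _ in range(max_iter):
        JTJ = J.T @ J
        g = J.T @ res
        step_ok = False
        for _inner in range(25):
            A = JTJ + lam * np.diag(np.maximum(np.diag(JTJ), 1e-12))
            try:
                delta = np.linalg.solve(A, -g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            R_new = _rotvec_to_matrix(delta[:3]) @ R
            # re-project onto SO(3) to stop drift
            U, _, Vt = np.linalg.svd(R_new)
            R_new = U @ Vt
            t_new = t + delta[3:]
            res_new, J_new = residual_and_jacobian(R_new, t_new)
            if res_new is None:
                lam *= 10
                continue
            cost_new = float(res_new @ res_new)
            if not np.isfinite(cost_new):
                raise NonConvergenceError("pose refinement objective became non-finite")
            if cost_new <= cost:
                step_ok = True
                break
            lam *= 10
        if not step_ok:
            break
        rel = (cost - cost_new) / max(cost, 1e-300)
        R, t, res, J, cost = R_new, t_new, res_new, J_new, cost_new
        lam = max(lam / 10, 1e-12)
        if rel < rel_tol:
            break
    return Pose(R=R, t=t)


# ---------------------------------------------------------------------------
# End-to-end marker registration
# ---------------------------------------------------------------------------

@dataclass
class RegistrationResult:
    """Outcome of the detect -> decode -> pose pipeline.

    ``pose`` is None when no registration was possible; ``failure`` then
    carries a human-readable reason.
    """

    pose: Pose | None
    code_id: int | None = None
    rotation_index: int | None = None
    corners_px: np.ndarray | None = None
    rms_px: float | None = None
    failure: str | None = None

    @property
    def ok(self) -> bool:
        return self.pose is not None


def register_marker_pose(image, cam: CameraModel, spec) -> RegistrationResult:
    """Full pipeline: threshold, detect quad, decode, undistort, DLT, LM refine.

    ``image`` is a grayscale raster (uint8 or float) containing at most one
    marker. Failures (no quad, undecodable code) are returned as a
    no-registration result rather than raised.
    """
    from . import markers  # local import: markers has no dependency on pose

    gray = np.asarray(image)
    binary = markers.adaptive_threshold(gray)
    corners = markers.detect_marker_quad(binary)
    if corners is None:
        return RegistrationResult(pose=None, failure="no marker quad detected")
    # Second pass with the Pintaric-style ROI: re-threshold over the quad's
    # bounding rectangle, which is robust to illumination gradients.
    x0, y0 = np.floor(corners.min(axis=0)).astype(int)
    x1, y1 = np.ceil(corners.max(axis=0)).astype(int) + 1
    roi = (max(y0, 0), max(x0, 0), min(y1, gray.shape[0]), min(x1, gray.shape[1]))
    binary_roi = markers.adaptive_threshold(gray, roi=roi)
    refined = markers.detect_marker_quad(binary_roi)
    if refined is not None:
        corners = refined
    # Subpixel: refit the four edges against the grayscale intensity ramp.
    corners = markers.refine_corners_subpixel(gray, corners)

    decoded = markers.decode_marker(gray, corners, spec)
    if decoded is None:
        return RegistrationResult(pose=None, corners_px=corners,
                                  failure="marker code could not be decoded")
    code_id, rotation_index = decoded
    canonical_corners = markers.canonicalize_corners(corners, rotation_index)

    # Undistort corners so that the DLT relates ideal pinhole coordinates.
    K = intrinsic_matrix(cam)
    ph = np.hstack([canonical_corners, np.ones((4, 1))])
    n = (np.linalg.solve(K, ph.T).T)[:, :2]
    n_ideal = undistort_point(n, cam.distortion)
    ideal_px = np.stack([
        cam.f * n_ideal[:, 0] + cam.s * n_ideal[:, 1] + cam.u,
        cam.a * cam.f * n_ideal[:, 1] + cam.v,
    ], axis=1)

    plane = markers.marker_plane_corners(spec)  # (4, 3) mm, Z=0
    corr_dlt = [Correspondence(M, m) for M, m in zip(plane, ideal_px)]
    H = estimate_homography_dlt(corr_dlt)
    pose0 = pose_from_homography(H, K)

    corr = [Correspondence(M, m) for M, m in zip(plane, canonical_corners)]
    pose = refine_pose_lm(pose0, corr, cam)
    return RegistrationResult(pose=pose, code_id=code_id,
                              rotation_index=rotation_index,
                              corners_px=canonical_corners,
                              rms_px=reprojection_rms(pose, corr, cam))
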