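"""Camera intrinsics, lens distortion and plane-based (Zhang) calibration.

The camera is the classic 5-parameter pinhole

    K = [[f, s, u],
         [0, a*f, v],
         [0, 0, 1]]

with focal length ``f`` (px), skew ``s``, principal point ``(u, v)`` and
aspect ratio ``a``, plus a 2-radial/2-tangential polynomial lens distortion
acting in normalized image coordinates. Calibration follows the standard
plane-based recipe: per-view homographies, absolute-conic constraints for a
closed-form intrinsic estimate, per-view extrinsics, a linear distortion fit,
and a joint nonlinear refinement of everything against reprojection error.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.optimize
from scipy.spatial.transform import Rotation

from ._homography import dlt_homography
from .errors import (
    InsufficientViewsError,
    NonConvergenceError,
    SingularSystemError,
)


@dataclass(frozen=True)
class DistortionCoeffs:
    """Radial (alpha1, alpha2) and tangential (beta1, beta2) lens distortion.

    Coefficients act on normalized (dimensionless) image coordinates; the
    all-zero vector is the identity map.
    """

    alpha1: float = 0.0
    alpha2: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0

    def __post_init__(self):
        vals = (self.alpha1, self.alpha2, self.beta1, self.beta2)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("distortion coefficients must be finite")

    @property
    def is_zero(self) -> bool:
        return self.alpha1 == self.alpha2 == self.beta1 == self.beta2 == 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2, self.beta1, self.beta2])


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera with 5 intrinsic parameters and lens distortion.

    ``f`` focal length (px), ``s`` skew (px), ``(u, v)`` principal point (px),
    ``a`` dimensionless aspect ratio (vertical focal length is ``a*f``).
    """

    f: float
    u: float
    v: float
    s: float = 0.0
    a: float = 1.0
    distortion: DistortionCoeffs = field(default_factory=DistortionCoeffs)
    image_size: tuple[int, int] | None = None  # (width, height) px

    def __post_init__(self):
        if not (self.f > 0):
            raise ValueError("focal length must be positive")
        if not (self.a > 0):
            raise ValueError("aspect ratio must be positive")
        if self.image_size is not None:
            w, h = self.image_size
            if not (0 <= self.u < w and 0 <= self.v < h):
                raise ValueError("principal point outside the sensor")

    @property
    def K(self) -> np.ndarray:
        return intrinsic_matrix(self)


def intrinsic_matrix(cam: CameraModel) -> np.ndarray:
    """Assemble the 3x3 intrinsic matrix from the named camera fields."""
    return np.array([
        [cam.f, cam.s, cam.u],
        [0.0, cam.a * cam.f, cam.v],
        [0.0, 0.0, 1.0],
    ])


def validation_camera() -> CameraModel:
    """Intrinsics of the webcam used in the original phantom-jar validation.

    Adopted parsing of the printed calibration: f = 518.550, s = 0,
    u = 349.727, vertical focal length 1.33 x 517.48, v = 279.897, on a
    640x480 sensor, with the published radial/tangential coefficients.
    """
    return CameraModel(
        f=518.550,
        s=0.0,
        u=349.727,
        v=279.897,
        a=(1.33 * 517.48) / 518.550,
        distortion=DistortionCoeffs(
            alpha1=-0.323276,
            alpha2=0.112309,
            beta1=-0.000341309,
            beta2=-0.00175445,
        ),
        image_size=(640, 480),
    )


# ---------------------------------------------------------------------------
# Distortion model
# ---------------------------------------------------------------------------

def distort_point(p_normalized, c: DistortionCoeffs):
    """Apply radial+tangential distortion to normalized image coordinates.

    Accepts a single 2-vector or an (N, 2) array; returns the same shape.
    """
    p = np.asarray(p_normalized, dtype=float)
    single = p.ndim == 1
    pts = p.reshape(-1, 2)
    x, y = pts[:, 0], pts[:, 1]
    r2 = x * x + y * y
    radial = 1.0 + c.alpha1 * r2 + c.alpha2 * r2 * r2
    xd = x * radial + 2.0 * c.beta1 * x * y + c.beta2 * (r2 + 2.0 * x * x)
    yd = y * radial + c.beta1 * (r2 + 2.0 * y * y) + 2.0 * c.beta2 * x * y
    out = np.stack([xd, yd], axis=1)
    return out[0] if single else out


def undistort_point(p_distorted, c: DistortionCoeffs, tol: float = 1e-10,
                    max_iter: int = 50):
    """Invert the distortion map by fixed-point iteration.

    Contracts for the moderate distortion magnitudes of webcam lenses; raises
    NonConvergenceError if the residual has not dropped below ``tol``
    (normalized units) after ``max_iter`` sweeps.
    """
    p = np.asarray(p_distorted, dtype=float)
    single = p.ndim == 1
    target = p.reshape(-1, 2)
    if c.is_zero:
        out = target.copy()
        return out[0] if single else out
    est = target.copy()
    for _ in range(max_iter):
        err = distort_point(est, c) - target
        est = est - err
        if np.max(np.abs(err)) < tol:
            break
    else:
        raise NonConvergenceError(
            f"undistortion did not converge below {tol} in {max_iter} iterations")
    return est[0] if single else est


# ---------------------------------------------------------------------------
# Checkerboard observations
# ---------------------------------------------------------------------------

@dataclass
class CheckerboardObservation:
    """One calibration view: planar board points paired with detected pixels.

    ``object_points`` are (N, 3) board coordinates in mm with Z = 0 (row-major
    over the nx x ny inner corners); ``image_points`` are the matching (N, 2)
    pixel positions. ``pose_true`` optionally carries the synthetic
    ground-truth extrinsics for generated fixtures.
    """

    nx: int
    ny: int
    square_mm: float
    object_points: np.ndarray
    image_points: np.ndarray
    pose_true: object | None = None

    def __post_init__(self):
        self.object_points = np.asarray(self.object_points, dtype=float)
        self.image_points = np.asarray(self.image_points, dtype=float)
        n = self.nx * self.ny
        if self.object_points.shape != (n, 3):
            raise ValueError(f"expected {n} object points with 3 coordinates")
        if self.image_points.shape != (n, 2):
            raise ValueError(f"expected {n} image points")
        if np.any(self.object_points[:, 2] != 0.0):
            raise ValueError("board points must lie in the Z=0 plane")


def board_object_points(nx: int, ny: int, square_mm: float) -> np.ndarray:
    """Planar (N, 3) grid of inner-corner coordinates, row-major, Z = 0."""
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny))
    pts = np.stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)], axis=1)
    return pts * square_mm


# ---------------------------------------------------------------------------
# Zhang-style calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    camera: CameraModel
    rms_px: float
    extrinsics: list  # list of (R, t) per view
    rms_initial_px: float
    n_views: int


def _vij(H: np.ndarray, i: int, j: int) -> np.ndarray:
    h = H
    return np.array([
        h[0, i] * h[0, j],
        h[0, i] * h[1, j] + h[1, i] * h[0, j],
        h[1, i] * h[1, j],
        h[2, i] * h[0, j] + h[0, i] * h[2, j],
        h[2, i] * h[1, j] + h[1, i] * h[2, j],
        h[2, i] * h[2, j],
    ])


def _intrinsics_from_homographies(Hs: Sequence[np.ndarray]) -> CameraModel:
    V = []
    for H in Hs:
        V.append(_vij(H, 0, 1))
        V.append(_vij(H, 0, 0) - _vij(H, 1, 1))
    V = np.asarray(V)
    _, s, vt = np.linalg.svd(V)
    if s[-2] / s[0] < 1e-12:
        raise SingularSystemError("calibration views are degenerate (rank-deficient conic system)")
    b = vt[-1]
    B11, B12, B22, B13, B23, B33 = b
    denom = B11 * B22 - B12 ** 2
    if abs(denom) < 1e-18 or abs(B11) < 1e-18:
        raise SingularSystemError("absolute-conic system is singular")
    v0 = (B12 * B13 - B11 * B23) / denom
    lam = B33 - (B13 ** 2 + v0 * (B12 * B13 - B11 * B23)) / B11
    if lam / B11 < 0:
        b = -b
        B11, B12, B22, B13, B23, B33 = b
        v0 = (B12 * B13 - B11 * B23) / denom
        lam = B33 - (B13 ** 2 + v0 * (B12 * B13 - B11 * B23)) / B11
    if lam / B11 <= 0 or lam * B11 / denom <= 0:
        raise SingularSystemError("conic solution does not define a real camera")
    alpha = np.sqrt(lam / B11)
    beta = np.sqrt(lam * B11 / denom)
    gamma = -B12 * alpha ** 2 * beta / lam
    u0 = gamma * v0 / beta - B13 * alpha ** 2 / lam
    return CameraModel(f=alpha, s=gamma, u=u0, v=v0, a=beta / alpha)


def _extrinsics_from_homography(H: np.ndarray, K: np.ndarray):
    M = np.linalg.solve(K, H)
    n1, n2 = np.linalg.norm(M[:, 0]), np.linalg.norm(M[:, 1])
    lam = np.sqrt(n1 * n2)
    if lam < 1e-15:
        raise SingularSystemError("homography collapses under K^-1")
    M = M / lam
    if M[2, 2] < 0:  # board must sit in front of the camera
        M = -M
    r1, r2, t = M[:, 0], M[:, 1], M[:, 2]
    R0 = np.stack([r1, r2, np.cross(r1, r2)], axis=1)
    U, _, Vt = np.linalg.svd(R0)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    return R, t


def _project_board(params, obj_pts_list):
    """Reprojection of every view given the packed parameter vector."""
    f, s, u, v, a = params[:5]
    coeffs = params[5:9]
    residual_pts = []
    for i, X in enumerate(obj_pts_list):
        rvec = params[9 + 6 * i: 12 + 6 * i]
        tvec = params[12 + 6 * i: 15 + 6 * i]
        R = Rotation.from_rotvec(rvec).as_matrix()
        Pc = X @ R.T + tvec
        n = Pc[:, :2] / Pc[:, 2:3]
        x, y = n[:, 0], n[:, 1]
        r2 = x * x + y * y
        radial = 1.0 + coeffs[0] * r2 + coeffs[1] * r2 * r2
        xd = x * radial + 2 * coeffs[2] * x * y + coeffs[3] * (r2 + 2 * x * x)
        yd = y * radial + coeffs[2] * (r2 + 2 * y * y) + 2 * coeffs[3] * x * y
        px = f * xd + s * yd + u
        py = a * f * yd + v
        residual_pts.append(np.stack([px, py], axis=1))
    return residual_pts


def calibrate_zhang(views: Sequence[CheckerboardObservation],
                    refine: bool = True,
                    fit_tangential: bool = True) -> CalibrationResult:
    """Estimate intrinsics + distortion from planar checkerboard views.

    Closed-form initialization (homographies -> absolute-conic constraints ->
    intrinsics -> extrinsics -> linear distortion fit) followed by a joint
    nonlinear refinement of all parameters minimizing RMS reprojection error.
    Requires >=3 views for the 5-parameter intrinsic solve.

    ``fit_tangential=False`` pins the tangential coefficients at zero: they
    are nearly degenerate with the principal point, so a radial-only model is
    preferred when the lens is known to be centred.
    """
    views = list(views)
    if len(views) < 3:
        raise InsufficientViewsError(
            f"plane-based calibration needs >=3 views, got {len(views)}")
    Hs = [dlt_homography(v.object_points[:, :2], v.image_points) for v in views]
    cam0 = _intrinsics_from_homographies(Hs)
    K0 = intrinsic_matrix(cam0)
    extr0 = [_extrinsics_from_homography(H, K0) for H in Hs]

    obj_pts = [v.object_points for v in views]
    img_pts = [v.image_points for v in views]

    # Linear least-squares distortion initialization in pixel space.
    rows, rhs = [], []
    Klin = np.array([[cam0.f, cam0.s], [0.0, cam0.a * cam0.f]])
    for (R, t), X, m in zip(extr0, obj_pts, img_pts):
        Pc = X @ R.T + t
        n = Pc[:, :2] / Pc[:, 2:3]
        x, y = n[:, 0], n[:, 1]
        r2 = x * x + y * y
        basis = np.stack([
            np.stack([x * r2, y * r2], axis=1),
            np.stack([x * r2 * r2, y * r2 * r2], axis=1),
            np.stack([2 * x * y, r2 + 2 * y * y], axis=1),
            np.stack([r2 + 2 * x * x, 2 * x * y], axis=1),
        ], axis=2)  # (N, 2, 4)
        ideal_px = n @ Klin.T + np.array([cam0.u, cam0.v])
        rows.append(np.einsum('ij,njk->nik', Klin, basis).reshape(-1, 4))
        rhs.append((m - ideal_px).reshape(-1))
    A = np.vstack(rows)
    bvec = np.concatenate(rhs)
    if not fit_tangential:
        A = A[:, :2]
    sol0, *_ = np.linalg.lstsq(A, bvec, rcond=None)
    coeffs0 = np.zeros(4)
    coeffs0[: len(sol0)] = sol0

    def pack(cam, coeffs, extr):
        p = [cam.f, cam.s, cam.u, cam.v, cam.a, *coeffs]
        for R, t in extr:
            p.extend(Rotation.from_matrix(R).as_rotvec())
            p.extend(t)
        return np.asarray(p, dtype=float)

    def rms_of(params):
        proj = _project_board(params, obj_pts)
        sq = [np.sum((p - m) ** 2) for p, m in zip(proj, img_pts)]
        n_pts = sum(len(m) for m in img_pts)
        return float(np.sqrt(sum(sq) / n_pts))

    p0 = pack(cam0, coeffs0, extr0)
    rms0 = rms_of(p0)
    p_best = p0
    # With a radial-only model the tangential entries (indices 7, 8) stay 0.
    free = np.ones(len(p0), dtype=bool)
    if not fit_tangential:
        free[7:9] = False
    if refine:
        def residuals(reduced):
            params = p0.copy()
            params[free] = reduced
            proj = _project_board(params, obj_pts)
            return np.concatenate([(p - m).ravel() for p, m in zip(proj, img_pts)])

        sol = scipy.optimize.least_squares(residuals, p0[free], method='lm',
                                           xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                           max_nfev=1000 * (len(p0) + 1))
        p_sol = p0.copy()
        p_sol[free] = sol.x
        if rms_of(p_sol) <= rms0:
            p_best = p_sol

    f, s, u, v, a = p_best[:5]
    coeffs = p_best[5:9]
    cam = CameraModel(f=f, s=s, u=u, v=v, a=a,
                      distortion=DistortionCoeffs(*coeffs))
    extr = []
    for i in range(len(views)):
        rvec = p_best[9 + 6 * i: 12 + 6 * i]
        tvec = p_best[12 + 6 * i: 15 + 6 * i]
        extr.append((Rotation.from_rotvec(rvec).as_matrix(), np.asarray(tvec)))
    return CalibrationResult(camera=cam, rms_px=rms_of(p_best),
                             extrinsics=extr, rms_initial_px=rms0,
                             n_views=len(views))


# ---------------------------------------------------------------------------
# Camera config serialization
# ---------------------------------------------------------------------------

_CONFIG_KEYS = ("f", "s", "u", "v", "a",
                "alpha1", "alpha2", "beta1", "beta2", "width", "height")


def save_camera(cam: CameraModel, path) -> None:
    """Write the camera to a plain `key = value` text config."""
    d = cam.distortion
    w, h = cam.image_size if cam.image_size else (0, 0)
    vals = dict(f=cam.f, s=cam.s, u=cam.u, v=cam.v, a=cam.a,
                alpha1=d.alpha1, alpha2=d.alpha2, beta1=d.beta1, beta2=d.beta2,
                width=w, height=h)
    lines = [f"{k} = {float(vals[k])!r}" for k in _CONFIG_KEYS]
    Path(path).write_text("\n".join(lines) + "\n")


def load_camera(path) -> CameraModel:
    vals = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, _, v = line.partition("=")
        vals[k.strip()] = float(v.strip())
    size = None
    if vals.get("width", 0) and vals.get("height", 0):
        size = (int(vals["width"]), int(vals["height"]))
    return CameraModel(
        f=vals["f"], s=vals.get("s", 0.0), u=vals["u"], v=vals["v"],
        a=vals.get("a", 1.0),
        distortion=DistortionCoeffs(vals.get("alpha1", 0.0), vals.get("alpha2", 0.0),
                                    vals.get("beta1", 0.0), vals.get("beta2", 0.0)),
        image_size=size)
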