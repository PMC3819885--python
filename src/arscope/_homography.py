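"""Low-level planar homography estimation (normalized DLT).

Shared by pose estimation, camera calibration and marker decoding; the
public typed wrapper lives in :mod:`arscope.pose`.
"""
from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError, UnderdeterminedError


def hartley_normalization(points: np.ndarray) -> np.ndarray:
    """Similarity transform taking points to centroid 0, mean distance sqrt(2).

    Standard conditioning step before any DLT solve.
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1).mean()
    if d < 1e-12:
        raise DegenerateGeometryError("all points coincide")
    s = np.sqrt(2.0) / d
    T = np.array([[s, 0.0, -s * centroid[0]],
                  [0.0, s, -s * centroid[1]],
                  [0.0, 0.0, 1.0]])
    return T


def _to_homogeneous(pts: np.ndarray) -> np.ndarray:
    return np.hstack([pts, np.ones((pts.shape[0], 1))])


def canonicalize(H: np.ndarray) -> np.ndarray:
    """Scale H to unit Frobenius norm with positive [2][2] entry (when nonzero)."""
    H = np.asarray(H, dtype=float)
    n = np.linalg.norm(H)
    if n == 0:
        raise DegenerateGeometryError("zero homography")
    H = H / n
    anchor = H[2, 2]
    if abs(anchor) < 1e-12:
        anchor = H.flat[np.argmax(np.abs(H))]
    if anchor < 0:
        H = -H
    return H


def dlt_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Total-least-squares homography mapping 2D ``src`` points to ``dst``.

    Hartley normalization is applied on both sides. Returns the canonical-scale
    3x3 matrix. Raises UnderdeterminedError for <4 points and
    DegenerateGeometryError for configurations that leave more than a
    one-dimensional null space (e.g. >=n-1 collinear points).
    """
    src = np.asarray(src, dtype=float).reshape(-1, 2)
    dst = np.asarray(dst, dtype=float).reshape(-1, 2)
    if src.shape[0] != dst.shape[0]:
        raise ValueError("source/destination point counts differ")
    n = src.shape[0]
    if n < 4:
        raise UnderdeterminedError(f"homography needs >=4 correspondences, got {n}")

    Ts = hartley_normalization(src)
    Td = hartley_normalization(dst)
    sh = (_to_homogeneous(src) @ Ts.T)
    dh = (_to_homogeneous(dst) @ Td.T)

    A = np.zeros((2 * n, 9))
    x, y = sh[:, 0], sh[:, 1]
    u, v = dh[:, 0], dh[:, 1]
    A[0::2, 0] = x
    A[0::2, 1] = y
    A[0::2, 2] = 1.0
    A[0::2, 6] = -u * x
    A[0::2, 7] = -u * y
    A[0::2, 8] = -u
    A[1::2, 3] = x
    A[1::2, 4] = y
    A[1::2, 5] = 1.0
    A[1::2, 6] = -v * x
    A[1::2, 7] = -v * y
    A[1::2, 8] = -v

    _, s, vt = np.linalg.svd(A)
    # A one-dimensional null space is expected; a second vanishing singular
    # value signals a degenerate configuration.
    if s[0] <= 0 or s[-2] / s[0] < 1e-10:
        raise DegenerateGeometryError("degenerate point configuration for DLT")
    Hn = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    if abs(np.linalg.det(H)) < 1e-12 * np.linalg.norm(H) ** 3:
        raise DegenerateGeometryError("estimated homography is rank deficient")
    return canonicalize(H)


def apply_homography(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Map 2D points through H with dehomogenization."""
    pts = np.asarray(pts, dtype=float)
    single = pts.ndim == 1
    ph = _to_homogeneous(pts.reshape(-1, 2)) @ np.asarray(H, dtype=float).T
    out = ph[:, :2] / ph[:, 2:3]
    return out[0] if single else out
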