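"""Virtual-model overlay: projection, alpha compositing, registration error.

The navel-centred surface model is pushed through the registered marker pose
and camera, its front-facing faces are rasterized into a silhouette, and the
silhouette is alpha-composited over the camera frame. Registration error is
quantified as the symmetric Hausdorff distance between silhouette boundaries
(pixels), converted to millimetres by the direct width correspondence of an
object of known physical size.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage import draw

from .anatomy import SurfaceModel
from .calibration import CameraModel
from .errors import GeometryError
from .pose import Pose, project


@dataclass
class OverlayResult:
    image: np.ndarray       # composited RGB uint8, same dimensions as input
    silhouette: np.ndarray  # bool raster of the projected model
    projected: np.ndarray   # (N, 2) per-vertex pixel coordinates (NaN if culled)
    opacity: float


def render_overlay(image: np.ndarray, model: SurfaceModel, pose: Pose,
                   cam: CameraModel, opacity: float = 0.5,
                   color: tuple = (0, 170, 255)) -> OverlayResult:
    """Project the model, rasterize front-facing faces, alpha-composite.

    Hidden surfaces are handled by back-face culling only (flat silhouette
    rendering, adequate for convex phantoms). ``opacity`` 0 returns the input
    bit-exactly; 1 paints the pure model color inside the silhouette.
    """
    if not (0.0 <= opacity <= 1.0):
        raise ValueError(f"opacity must be in [0, 1], got {opacity}")
    img = np.asarray(image)
    if img.ndim == 2:
        rgb = np.stack([img] * 3, axis=2)
    else:
        rgb = img.copy()
    Hpx, Wpx = rgb.shape[:2]

    verts_cam = model.vertices @ pose.R.T + pose.t
    depths = verts_cam[:, 2]
    if np.all(depths <= 0):
        raise GeometryError("all model vertices are behind the camera")

    visible = depths > 1e-9
    projected = np.full((len(model.vertices), 2), np.nan)
    if visible.any():
        # project() validates depth; only visible vertices pass through it
        sub = project(model.vertices[visible], pose, cam)
        projected[visible] = sub

    silhouette = np.zeros((Hpx, Wpx), dtype=bool)
    faces = model.faces
    face_ok = visible[faces].all(axis=1)
    tri_cam = verts_cam[faces[face_ok]]
    # Back-face culling: keep faces whose outward normal points at the camera.
    normals = np.cross(tri_cam[:, 1] - tri_cam[:, 0], tri_cam[:, 2] - tri_cam[:, 0])
    centroids = tri_cam.mean(axis=1)
    front = np.einsum('ij,ij->i', normals, centroids) < 0
    for tri in faces[face_ok][front]:
        pts = projected[tri]
        rr, cc = draw.polygon(pts[:, 1], pts[:, 0], shape=(Hpx, Wpx))
        silhouette[rr, cc] = True

    if opacity == 0.0:
        out = rgb.copy()
    else:
        out = rgb.astype(float)
        col = np.asarray(color, dtype=float)
        out[silhouette] = (1.0 - opacity) * out[silhouette] + opacity * col
        out = np.rint(out).clip(0, 255).astype(np.uint8)
    return OverlayResult(image=out, silhouette=silhouette,
                         projected=projected, opacity=float(opacity))


# ---------------------------------------------------------------------------
# Registration error metrics
# ---------------------------------------------------------------------------

def _boundary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    eroded = ndi.binary_erosion(mask, structure=ndi.generate_binary_structure(2, 1),
                                border_value=0)
    return mask & ~eroded


def silhouette_error_px(predicted: np.ndarray, reference: np.ndarray) -> float:
    """Symmetric Hausdorff distance between silhouette boundaries, in pixels."""
    pred = np.asarray(predicted, dtype=bool)
    ref = np.asarray(reference, dtype=bool)
    if pred.shape != ref.shape:
        raise ValueError("silhouette rasters must be congruent")
    if not pred.any() or not ref.any():
        raise ValueError("silhouette error undefined for an empty silhouette")
    bp, br = _boundary(pred), _boundary(ref)
    dt_ref = ndi.distance_transform_edt(~br)
    dt_pred = ndi.distance_transform_edt(~bp)
    return float(max(dt_ref[bp].max(), dt_pred[br].max()))


def silhouette_error_stats(predicted: np.ndarray, reference: np.ndarray) -> dict:
    """Hausdorff (max) and mean boundary displacement, both in pixels."""
    pred = np.asarray(predicted, dtype=bool)
    ref = np.asarray(reference, dtype=bool)
    bp, br = _boundary(pred), _boundary(ref)
    if not bp.any() or not br.any():
        raise ValueError("silhouette error undefined for an empty silhouette")
    dt_ref = ndi.distance_transform_edt(~br)
    dt_pred = ndi.distance_transform_edt(~bp)
    d_ab, d_ba = dt_ref[bp], dt_pred[br]
    return dict(hausdorff_px=float(max(d_ab.max(), d_ba.max())),
                mean_px=float((d_ab.sum() + d_ba.sum()) / (d_ab.size + d_ba.size)))


def px_to_mm(err_px: float, object_width_mm: float, object_width_px: float) -> float:
    """Direct width correspondence: err_mm = err_px * width_mm / width_px."""
    if object_width_px <= 0 or object_width_mm <= 0:
        raise ValueError("object widths must be positive")
    return err_px * object_width_mm / object_width_px


@dataclass(frozen=True)
class RegistrationErrorReport:
    """Overlay registration error in pixels and millimetres.

    ``err_mm`` is always ``err_px * scale_mm_per_px`` exactly.
    """

    err_px: float
    scale_mm_per_px: float
    note: str = ""

    def __post_init__(self):
        if self.err_px < 0:
            raise ValueError("pixel error must be non-negative")

    @property
    def err_mm(self) -> float:
        return self.err_px * self.scale_mm_per_px
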