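"""Square binary "hexadecimal" fiducial markers: generation, detection, decoding.

Layout
------
The marker is a square of ``grid + 2*border_cells`` cells per side: an
all-black border ring around a ``grid x grid`` interior code. Three interior
corner cells are reserved as fixed orientation bits — top-left black,
top-right black, bottom-left white — which disambiguate the four in-plane
rotations for any payload. The remaining ``grid**2 - 3`` cells carry the
payload row-major, most significant bit first, black = 1. The default
``grid = 5`` therefore holds any 16-bit (4 hex digit) id with 6 bits to
spare; ``grid = 4`` is supported with a 13-bit capacity. Orientation cells
can be disabled, in which case the full ``grid**2`` bits are payload and
rotation cannot be recovered (``rotation_index`` is 0 by convention).

Detection binarizes with the mean-luminance adaptive threshold over a region
of interest, extracts the single dark quad, and intersects total-least-squares
line fits of the four edges for subpixel corners.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import ConvexHull
from skimage import measure

from ._homography import apply_homography, dlt_homography
from .errors import AmbiguousMarkerError, MarkerCapacityError


@dataclass(frozen=True)
class MarkerSpec:
    """Physical and coding description of one fiducial marker.

    ``side_length_cm`` is the full physical edge of the printed marker
    including the black border (default 8.45 cm, the navel marker size).
    """

    side_length_cm: float = 8.45
    code_id: int = 0
    grid: int = 5
    border_cells: int = 1
    orientation_cells: bool = True

    def __post_init__(self):
        if not (self.side_length_cm > 0):
            raise ValueError("side length must be positive")
        if self.border_cells < 1:
            raise ValueError("at least one border cell is required")
        if self.grid < 2:
            raise ValueError("interior grid must be at least 2x2")
        if not (0 <= self.code_id < 2 ** (self.grid ** 2)):
            raise ValueError("code_id not representable in grid**2 bits")

    @property
    def side_mm(self) -> float:
        return self.side_length_cm * 10.0

    @property
    def total_cells(self) -> int:
        return self.grid + 2 * self.border_cells

    @property
    def payload_bits(self) -> int:
        return self.grid ** 2 - (3 if self.orientation_cells else 0)


# Orientation cell positions (row, col) in the interior grid and their
# required values (True = black).
def _orientation_cells(grid: int):
    return [((0, 0), True), ((0, grid - 1), True), ((grid - 1, 0), False)]


def _payload_positions(spec: MarkerSpec):
    reserved = {pos for pos, _ in _orientation_cells(spec.grid)} \
        if spec.orientation_cells else set()
    return [(r, c) for r in range(spec.grid) for c in range(spec.grid)
            if (r, c) not in reserved]


def cell_matrix(spec: MarkerSpec) -> np.ndarray:
    """Interior code cells as a boolean grid (True = black)."""
    if spec.code_id >= 2 ** spec.payload_bits:
        raise MarkerCapacityError(
            f"code_id {spec.code_id:#x} exceeds the {spec.payload_bits}-bit payload")
    cells = np.zeros((spec.grid, spec.grid), dtype=bool)
    positions = _payload_positions(spec)
    nbits = spec.payload_bits
    for k, pos in enumerate(positions):
        cells[pos] = bool((spec.code_id >> (nbits - 1 - k)) & 1)
    if spec.orientation_cells:
        for pos, val in _orientation_cells(spec.grid):
            cells[pos] = val
    return cells


def _code_from_cells(cells: np.ndarray, spec: MarkerSpec) -> int:
    positions = _payload_positions(spec)
    nbits = spec.payload_bits
    code = 0
    for k, pos in enumerate(positions):
        if cells[pos]:
            code |= 1 << (nbits - 1 - k)
    return code


def generate_marker(spec: MarkerSpec, pixels_per_cell: int = 16) -> np.ndarray:
    """Render the marker as a strictly binary uint8 raster (0 black, 255 white)."""
    if pixels_per_cell < 1:
        raise ValueError("pixels_per_cell must be >= 1")
    cells = cell_matrix(spec)
    total = spec.total_cells
    full = np.ones((total, total), dtype=bool)  # True = black (border default)
    b = spec.border_cells
    full[b:b + spec.grid, b:b + spec.grid] = cells
    img = np.where(full, 0, 255).astype(np.uint8)
    return np.kron(img, np.ones((pixels_per_cell, pixels_per_cell), dtype=np.uint8))


def marker_pattern_lookup(spec: MarkerSpec) -> np.ndarray:
    """Cell-level luminance lookup (total x total, float in [0, 1], 0 = black)."""
    cells = cell_matrix(spec)
    total = spec.total_cells
    full = np.ones((total, total), dtype=bool)
    b = spec.border_cells
    full[b:b + spec.grid, b:b + spec.grid] = cells
    return np.where(full, 0.0, 1.0)


def marker_plane_corners(spec: MarkerSpec) -> np.ndarray:
    """Canonical physical corners (mm, Z=0), order TL, TR, BR, BL.

    The marker frame has X to the right and Y downward across the printed
    face, origin at the marker center.
    """
    h = spec.side_mm / 2.0
    return np.array([[-h, -h, 0.0], [h, -h, 0.0], [h, h, 0.0], [-h, h, 0.0]])


# ---------------------------------------------------------------------------
# Adaptive thresholding (mean luminance over a region of interest)
# ---------------------------------------------------------------------------

def adaptive_threshold(image: np.ndarray, roi: tuple | None = None) -> np.ndarray:
    """Binarize by the mean luminance over ``roi`` (full frame by default).

    ``roi`` is (row0, col0, row1, col1), half-open. Pixels strictly greater
    than the mean are classified white (True); equality falls to black.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if roi is None:
        roi = (0, 0, img.shape[0], img.shape[1])
    r0, c0, r1, c1 = roi
    if not (0 <= r0 < r1 <= img.shape[0] and 0 <= c0 < c1 <= img.shape[1]):
        raise ValueError(f"empty or out-of-bounds ROI {roi}")
    threshold = img[r0:r1, c0:c1].mean()
    return img > threshold


# ---------------------------------------------------------------------------
# Quad detection with subpixel corners
# ---------------------------------------------------------------------------

def _reduce_hull_to_quad(pts: np.ndarray) -> np.ndarray:
    """Drop hull vertices whose removal changes the polygon area least."""
    pts = list(pts)
    while len(pts) > 4:
        n = len(pts)
        losses = []
        for i in range(n):
            a, b, c = pts[(i - 1) % n], pts[i], pts[(i + 1) % n]
            u, v = b - a, c - a
            losses.append(abs(u[0] * v[1] - u[1] * v[0]) / 2.0)
        pts.pop(int(np.argmin(losses)))
    return np.asarray(pts)


def _order_corners(corners: np.ndarray) -> np.ndarray:
    """Order with positive shoelace in (x, y), starting at the top-left corner."""
    x, y = corners[:, 0], corners[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 < 0:
        corners = corners[::-1]
    start = int(np.argmin(corners.sum(axis=1)))
    return np.roll(corners, -start, axis=0)


def _tls_line(pts: np.ndarray):
    """Total-least-squares line: (point on line, unit direction)."""
    mean = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - mean)
    return mean, vt[0]


def _intersect(l1, l2):
    p1, d1 = l1
    p2, d2 = l2
    A = np.stack([d1, -d2], axis=1)
    s = np.linalg.solve(A, p2 - p1)
    return p1 + s[0] * d1


def detect_marker_quad(binary: np.ndarray, min_area: int = 100):
    """Locate the single dark marker quad in a binarized frame.

    Returns the 4 subpixel corners (x, y), ordered counter-clockwise in the
    pixel convention (x right, y down) starting at the top-left, or None when
    no marker-like quad exists. Raises AmbiguousMarkerError for multiple
    candidates.
    """
    binary = np.asarray(binary, dtype=bool)
    dark = ~binary
    labels, n_lab = ndi.label(dark, structure=np.ones((3, 3), dtype=int))
    candidates = []
    for lab in range(1, n_lab + 1):
        comp = labels == lab
        area = int(comp.sum())
        if area < min_area:
            continue
        rows = np.any(comp, axis=1)
        cols = np.any(comp, axis=0)
        if rows[0] or rows[-1] or cols[0] or cols[-1]:
            continue  # marker is assumed fully inside the frame
        filled = ndi.binary_fill_holes(comp)
        contours = measure.find_contours(filled.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        pts = contour[:, ::-1]  # (x, y)
        if len(pts) < 8:
            continue
        try:
            hull = ConvexHull(pts)
        except Exception:
            continue
        quad0 = _reduce_hull_to_quad(pts[hull.vertices])
        quad0 = _order_corners(quad0)
        qx, qy = quad0[:, 0], quad0[:, 1]
        quad_area = abs(np.sum(qx * np.roll(qy, -1) - np.roll(qx, -1) * qy)) / 2.0
        filled_area = float(filled.sum())
        if quad_area <= 0 or not (0.75 <= filled_area / quad_area <= 1.3):
            continue
        candidates.append((quad0, pts, filled))
    # Dark interior code cells can themselves form quad-like blobs; they are
    # nested inside the marker's filled quad and are not separate candidates.
    keep = []
    for i, (qi, pi, fi) in enumerate(candidates):
        nested = any(fj[fi].all() for j, (_, _, fj) in enumerate(candidates)
                     if j != i and fj.sum() > fi.sum())
        if not nested:
            keep.append((qi, pi, fi))
    candidates = keep
    if not candidates:
        return None
    if len(candidates) > 1:
        raise AmbiguousMarkerError(f"{len(candidates)} marker-like quads found")

    quad0, pts, _ = candidates[0]

    # Assign contour points to each edge (excluding corner vicinity) and refit
    # by total least squares; iterate with a shrinking assignment band since
    # the initial hull-reduced corners can be a few pixels off.
    quad = quad0
    for band in (4.0, 1.5, 1.5):
        side_len = np.mean(np.linalg.norm(np.roll(quad, -1, axis=0) - quad, axis=1))
        corner_excl = max(2.0, 0.08 * side_len)
        lines = []
        for i in range(4):
            a, b = quad[i], quad[(i + 1) % 4]
            d = b - a
            L = np.linalg.norm(d)
            d = d / L
            rel = pts - a
            along = rel @ d
            perp = np.abs(rel @ np.array([-d[1], d[0]]))
            sel = (perp < band) & (along > corner_excl) & (along < L - corner_excl)
            edge_pts = pts[sel]
            if len(edge_pts) < 2:
                return None
            lines.append(_tls_line(edge_pts))
        quad = np.array([_intersect(lines[i - 1], lines[i]) for i in range(4)])
        quad = _order_corners(quad)
    return quad


def refine_corners_subpixel(image: np.ndarray, corners: np.ndarray,
                            search_px: float = 3.0) -> np.ndarray:
    """Refine quad corners against the grayscale edge profile.

    For each quad side, samples intensity profiles along the edge normal at
    many stations, locates the mid-intensity crossing of each profile by
    linear interpolation, refits the side by total least squares and
    intersects adjacent sides. Exploits the anti-aliased ramp of the true
    edge, which the binarized contour quantizes away.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    corners = np.asarray(corners, dtype=float).reshape(4, 2)
    offsets = np.arange(-search_px, search_px + 0.25, 0.5)
    lines = []
    for i in range(4):
        a, b = corners[i], corners[(i + 1) % 4]
        L = np.linalg.norm(b - a)
        d = (b - a) / L
        nrm = np.array([-d[1], d[0]])
        m = max(8, int(L * 0.8))
        ts = np.linspace(0.12, 0.88, m)
        base = a[None, :] + ts[:, None] * (b - a)[None, :]
        # (m, n_off, 2) sample positions
        sample_xy = base[:, None, :] + offsets[None, :, None] * nrm[None, None, :]
        vals = ndi.map_coordinates(
            img, [sample_xy[..., 1].ravel(), sample_xy[..., 0].ravel()],
            order=1, mode='nearest').reshape(m, len(offsets))
        refined = []
        for j in range(m):
            prof = vals[j]
            mid = 0.5 * (prof[0] + prof[-1])
            diff = prof - mid
            cross = np.flatnonzero((diff[:-1] * diff[1:] <= 0)
                                   & (prof[:-1] != prof[1:]))
            if cross.size == 0:
                continue
            k = cross[np.argmin(np.abs(offsets[cross] + 0.25))]
            frac = (mid - prof[k]) / (prof[k + 1] - prof[k])
            off = offsets[k] + frac * (offsets[k + 1] - offsets[k])
            refined.append(base[j] + off * nrm)
        if len(refined) < 2:
            return corners  # refinement not possible; keep binary estimate
        lines.append(_tls_line(np.asarray(refined)))
    out = np.array([_intersect(lines[i - 1], lines[i]) for i in range(4)])
    return out


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def _sample_bilinear(img: np.ndarray, xy: np.ndarray) -> np.ndarray:
    coords = np.stack([xy[:, 1], xy[:, 0]])  # (row, col)
    return ndi.map_coordinates(img, coords, order=1, mode='nearest')


def decode_marker(image: np.ndarray, corners: np.ndarray, spec: MarkerSpec):
    """Decode the marker payload given its 4 detected corners.

    Samples each interior cell center through the corner-induced homography,
    classifies black/white against the (known black) border reference, and
    tries the four rotations against the orientation cells. Returns
    ``(code_id, rotation_index)`` or None when no rotation matches (or, with
    orientation cells disabled, the code as sampled with rotation 0).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    corners = np.asarray(corners, dtype=float).reshape(4, 2)
    S = float(spec.total_cells)
    plane_corners = np.array([[0.0, 0.0], [S, 0.0], [S, S], [0.0, S]])
    H = dlt_homography(plane_corners, corners)

    b = spec.border_cells
    g = spec.grid
    rr, cc = np.meshgrid(np.arange(g), np.arange(g), indexing='ij')
    interior = np.stack([b + cc.ravel() + 0.5, b + rr.ravel() + 0.5], axis=1)
    border = [(r, c) for r in range(spec.total_cells) for c in range(spec.total_cells)
              if r < b or c < b or r >= S - b or c >= S - b]
    border = np.array([[c + 0.5, r + 0.5] for r, c in border])

    interior_vals = _sample_bilinear(img, apply_homography(H, interior))
    border_vals = _sample_bilinear(img, apply_homography(H, border))

    black_ref = float(border_vals.mean())
    white_ref = float(interior_vals.max())
    scale = max(abs(black_ref), abs(white_ref), 1e-9)
    if (white_ref - black_ref) / scale < 0.05:
        cells = np.ones((g, g), dtype=bool)  # no bright cell: all black
    else:
        threshold = 0.5 * (black_ref + white_ref)
        cells = (interior_vals < threshold).reshape(g, g)

    if not spec.orientation_cells:
        return _code_from_cells(cells, spec), 0

    matches = []
    for k in range(4):
        aligned = np.rot90(cells, k)
        if all(aligned[pos] == val for pos, val in _orientation_cells(g)):
            matches.append(k)
    if len(matches) != 1:
        return None
    k = matches[0]
    return _code_from_cells(np.rot90(cells, k), spec), k


def canonicalize_corners(corners: np.ndarray, rotation_index: int) -> np.ndarray:
    """Reorder detected corners so index 0 is the marker's physical top-left."""
    return np.roll(np.asarray(corners, dtype=float), -rotation_index, axis=0)


@dataclass
class MarkerDetection:
    """Detected marker: canonical corners, decoded code and plane->image map."""

    corners: np.ndarray
    code_id: int
    rotation_index: int
    homography: np.ndarray = field(default=None)


def detect_marker(image: np.ndarray, spec: MarkerSpec):
    """Convenience detect+decode on a grayscale frame. None when not found."""
    binary = adaptive_threshold(image)
    corners = detect_marker_quad(binary)
    if corners is None:
        return None
    decoded = decode_marker(image, corners, spec)
    if decoded is None:
        return None
    code_id, k = decoded
    canonical = canonicalize_corners(corners, k)
    H = dlt_homography(marker_plane_corners(spec)[:, :2], canonical)
    return MarkerDetection(corners=canonical, code_id=code_id,
                           rotation_index=k, homography=H)
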