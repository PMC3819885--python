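# Methods

## Camera model and calibration

The camera is a 5-parameter pinhole: focal length `f` (px), skew `s`,
principal point `(u, v)`, aspect ratio `a` (vertical focal length `a·f`),
with lens distortion acting on normalized coordinates `n = (x/z, y/z)`:

```
n_d = n · (1 + α₁ r² + α₂ r⁴) + tangential(β₁, β₂),   r² = ‖n‖²
```

radial applied first, tangential added (Brown's convention). The inverse is a
fixed-point iteration (max 50 sweeps, tolerance 1e-10 normalized units),
which contracts for webcam-scale coefficients.

Calibration is plane-based: a homography per checkerboard view (normalized
DLT — both point sets are Hartley-normalized to centroid 0 / mean distance
√2 before every linear solve in this package), absolute-conic constraints
stacked over views and solved by SVD for the closed-form intrinsics,
extrinsics per view from `K⁻¹H` with SVD re-orthonormalization, a linear
least-squares distortion fit, and a joint Levenberg–Marquardt refinement of
all parameters against pixel reprojection error. Three views is the rank
minimum for the 5-parameter conic solve and is enforced. The reported RMS is
recomputed from the refined parameters, and refinement is accepted only if it
does not increase the objective.

`fit_tangential=False` pins β₁ = β₂ = 0. The tangential pair is nearly
degenerate with the principal point (their Fisher information matrix is
ill-conditioned for planar targets), so a radial-only model is the right
choice when the lens is known to be centred; the noisy-recovery tests use it
for exactly that reason, together with views spread across the frame —
off-centre views are what constrain `(u, v)`.

The shipped `validation_camera()` fixture is the reading adopted for the
published calibration of the system's webcam: `f = 518.550`, `s = 0`,
`u = 349.727`, vertical focal length `1.33 × 517.48`, `v = 279.897` on a
640×480 sensor, distortion `(−0.323276, 0.112309, −0.000341309, −0.00175445)`.
The printed matrix mixes an aspect ratio of 1.33 with two distinct focal-like
values and does not reconcile them; the fixture documents this parsing rather
than resolving it, and nothing downstream depends on the choice beyond the
numeric entries themselves.

## Fiducial marker

The marker is a square of `grid + 2·border` cells: an all-black border ring
around a `grid × grid` interior code, physical side 8.45 cm. Three interior
corner cells are fixed orientation bits (top-left black, top-right black,
bottom-left white); one can show this triple identifies the in-plane rotation
uniquely for every payload. Payload bits fill the remaining cells row-major,
MSB first, black = 1. The default `grid = 5` gives 22 payload bits, so any
16-bit ("4 hexadecimal digits") id fits alongside the orientation cells; a
4×4 grid is supported with 13-bit capacity. The layout is a documented
invention — the original system specifies only "a binary hexadecimal code
marker" — and is isolated in `MarkerSpec` so alternatives are pluggable.

Detection binarizes with the mean-luminance threshold over a region of
interest (strictly-greater ⇒ white; equality falls to black). The first pass
uses the full frame; registration then re-thresholds over the detected quad's
axis-aligned bounding rectangle, which is the mean-over-marker-ROI rule that
makes the threshold robust to illumination gradients. The dark connected
component is reduced to a quad (convex hull, iterative vertex removal), its
contour points are assigned to the four sides and refit by total least
squares with a shrinking assignment band, and corners are line
intersections. For grayscale input the corners are refined once more against
the anti-aliased intensity ramp: profiles are sampled along each edge normal,
the mid-intensity crossing located by linear interpolation, and the sides
refit — this removes the ±0.5 px quantization of the binarized contour and
is what brings corner error to ~0.1–0.2 px RMS on noiseless renders.

Decoding samples cell centres through the corner homography, classifies
against the known-black border reference, and tries the four rotations
against the orientation cells; the decoded id is rotation-canonical and the
corner order is rolled so index 0 is the marker's physical top-left. There is
no error correction: corrupted payload cells decode to a different id.

## Pose estimation

With `Z = 0` world points, `H ~ K (R₁ R₂ t)`. Decomposition scales `K⁻¹H` by
the geometric mean of `‖R₁‖, ‖R₂‖`, fixes the sign by positive depth of the
plane origin (erroring when ambiguous), completes `R₃ = R₁ × R₂` and projects
onto SO(3) by SVD — the cross-product construction alone leaves `R₁, R₂`
non-orthogonal under noise. Refinement minimizes the summed squared pixel
reprojection error over a left-multiplied axis-angle increment and the
translation, with the analytic Jacobian through the full
projection-plus-distortion chain; damping starts at 1e-3, ×10 on rejection,
÷10 on acceptance; termination on relative objective change < 1e-10 or 100
iterations. Accepted steps never increase the objective, so the refined pose
is at least as good as its initialization. Corners are undistorted before the
DLT so the homography relates ideal pinhole coordinates.

Near fronto-parallel poses the tilt is weakly observable from four coplanar
points (the classic planar-pose ambiguity); the subpixel corner refinement
above is what keeps the angular error of the end-to-end registration below
0.5° across viewing angles of 30–90°.

## Anatomy model

Volumes are scalar grids with strictly positive mm spacing in a right-handed
RAS-like axis convention (real-scan orientation handling is out of scope);
NIfTI goes through nibabel, MetaImage through SimpleITK, and round trips are
bit-exact. Region growing is the maximal connected component of the
intensity window containing the seed, 26-connected by default (6-connected
optional), with the CT phantom window 150–2200 HU.

Surface extraction runs marching cubes at the 0.5 level of the padded,
Gaussian-smoothed (σ = 1 voxel; 0 disables) occupancy: interpolating raw
binary data produces staircase facets that overestimate the area of smooth
objects by ~9%, while the smoothed field recovers a 20-voxel sphere's area
to well under 1% and moves boundaries by under half a voxel. Zero-area faces
are dropped.

Re-basing to the navel landmark is the pure translation `x' = x − (α, β, γ)`
placing the landmark at the origin. (Taken literally, the published change of
coordinates reads `x' = α + x`, which moves the landmark *away* from the
origin; the stated intent — establish the origin at the navel — requires the
minus sign, which is what `recenter_to_navel` implements. The literal sign is
available via `toward_origin=False`.)

## Overlay and registration error

Vertices are projected through the registered pose; the silhouette is the
filled union of projected front-facing faces (back-face culling only — flat
silhouette rendering, adequate for convex phantoms, a documented limitation
for concave organs); compositing is the convex combination
`(1−α)·image + α·color` inside the silhouette.

"Error in pixels" is operationalized as the symmetric Hausdorff distance
between the silhouette boundaries (the farthest the virtual outline strays
from the real one), with the mean boundary distance reported as a secondary
metric. Conversion to mm uses the direct width correspondence
`err_mm = err_px × width_mm / width_px`.

## The jar experiment

The accuracy of the registration chain is measured on a synthetic
re-creation of the phantom experiment: a 500 mL jar of 101 mm outer diameter
imaged as 512×512 CT slices at 0.488×0.488×0.625 mm, segmented by region
growing in [150, 2200] HU, meshed, and re-based to the centre of the top
opening where the marker sits. The camera (the `validation_camera()`
intrinsics with distortion) views the marker fronto-parallel — the
90-degree placement — and the virtual jar is projected through the
*estimated* pose, while the "real jar" reference silhouette is computed
analytically through the true camera (a pixel belongs to the disk iff its
undistorted ray falls inside the circle of radius `r/z`).

Unstated parameters were fixed once: camera distance 500 mm, which makes the
jar ≈104 px wide (≈0.97 mm/px, representable against the published
pixel-to-mm correspondence of the original experiment), jar wall height
100 mm, wall 3 mm, solid 5 mm base. The noiseless pipeline yields ≈1 px
Hausdorff error (≈0.97 mm), the budget of which is roughly: pose estimation
from subpixel corners (~0.3 px), voxelization and smoothing of the mesh
boundary (~0.5 px), and rasterization of the two silhouettes (~0.5 px). The
published system figures — 3 px and 2.91 mm — act as upper bounds for this
noiseless re-creation; matching them exactly is not expected since the
original values include physical-camera effects the renderer does not model.

## Trial simulation

Each correction distance is decomposed into named displacement components
(pneumoperitoneum, patient anatomy, surgeon skill, and — in the AR arm —
registration, segmentation and residual terms). Only their sum is observable
in real data; the components are first-class only in the generator, drawn as
zero-mean isotropic Gaussian 3-vectors whose sum is the record's `d` exactly
(budget closure to machine precision), with `P* = P + d` by construction.

Per-axis SDs (cm) were calibrated once so the analytic pooled `E‖d‖` over
trocars {1, 3, 4} matches the published global scales — control
(0.50, 0.50, 0.42, 0.15) giving E ≈ 1.33 cm, AR arm
(0.50, 0.05, 0.05, 0.291/√3, 0.05, 0.10) giving E ≈ 0.87 cm, where the
registration component's scale tracks the measured 2.91 mm system error.
Trocar 2 (the umbilical port, incised right at the mark) is scaled to the
published ~0.13/0.12 cm means in both arms, which reproduces the qualitative
pooling pattern: trocar 2 separates from the rest, trocars 1/3/4 pool.

A zero-mean Gaussian model constrains `SD(‖d‖)/E‖d‖` to √(3π/8 − 1) ≈ 0.42,
so the per-trocar SDs of the original control arm (where SD exceeds the mean,
e.g. 1.88 ± 1.96 cm — a heavy-tailed distribution) are *not* reproduced; the
simulation is calibrated on means only, and tests that need the published
SDs feed them in as printed worked examples rather than regenerating them.

## Validation statistics

Sample SDs use the n−1 denominator; report tables render round-half-up to
2 decimals (cm) and improvements to integer percent, matching the printed
precision, while all internal values stay unrounded. The Mann–Whitney U test
is two-sided ("equal medians at the 5% level" read as two-sided,
p = 2·min(tail) capped at 1), with mid-ranks for ties. Exact mode computes
the full permutation null of the rank sum by dynamic programming over the
doubled mid-ranks (equivalent to enumerating every rank split, feasible to
n = 12 per group); approximate mode uses the normal approximation with tie
and continuity corrections. Pairs with p > 0.05 are flagged poolable; no
multiple-testing correction is applied across the six pairwise tests,
mirroring the original analysis. Improvement metrics are
`(mean_ctrl − mean_ar)/mean_ctrl` and `(sd_ctrl − sd_ar)/sd_ctrl` in percent,
returned unrounded with a 0-decimal rendering.

The published global figures are internally inconsistent at the printed
precision (the pooled "with system" mean cannot be reconstructed from the
per-trocar table, and the variability reduction is quoted both as 63% and
65%); this package reports unrounded metrics and treats the 63% figure —
the one consistent with the published global SDs (1.43 vs 0.53 cm, a 62.94%
reduction) — as the anchor in its checks.

## What the synthetic experiments do and do not show

Passing tests demonstrate the *algorithmic* correctness and numerical
accuracy of the chain on ideal data: exact parameter recovery, subpixel
corner behaviour under rendered anti-aliasing, noise and illumination
gradients, and a registration error bounded by the published system error.
They do not model motion blur, rolling shutter, specular glare, soft-tissue
deformation under pneumoperitoneum, marker placement error on skin, or MRI
segmentation ambiguity — the real-world terms that dominate the clinical
error budget. The clinical outcome tables derive from unpublished raw
measurements and are handled as printed-value worked examples, not
regenerated data.
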