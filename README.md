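# arscope

Marker-based augmented-reality guidance for laparoscopic trocar placement —
a tested re-implementation of the full pipeline of a surgical AR navigation
system: camera calibration, square-fiducial detection and pose registration,
patient-model segmentation and overlay, and the statistics used to validate
the system against a control arm.

## The problem

In laparoscopic surgery, instruments enter the abdomen through trocars placed
at sites the surgeon marks with a pen before insufflation. Pneumoperitoneum
deformation, patient anatomy and surgeon judgement displace the ideal incision
from the pen mark; the correction distance `‖d_i‖ = ‖P*_i − P_i‖` between mark
`P_i` and incision `P*_i` for trocar `i` is the outcome of interest. An AR
system that projects a preoperative 3D model of the patient's organs onto the
live camera view — registered through a single square fiducial placed on the
navel — can shrink that correction.

The library covers each stage:

- **`arscope.calibration`** — 5-parameter pinhole intrinsics
  `K = [[f, s, u], [0, a·f, v], [0, 0, 1]]` with a 2-radial/2-tangential
  distortion polynomial, estimated from planar checkerboard views by Zhang's
  method (closed-form absolute-conic initialization + joint LM refinement).
- **`arscope.markers`** — generation, adaptive-threshold detection (mean
  luminance over a region of interest), subpixel quad corners and
  rotation-invariant decoding of a binary "hexadecimal" code marker
  (8.45 cm side; 5×5 code grid with 3 orientation cells by default).
- **`arscope.pose`** — plane-to-image homography by normalized DLT,
  pose recovery from `K⁻¹H = (R₁ R₂ t)` with `R₃ = R₁ × R₂` and SVD
  orthonormalization, and Levenberg–Marquardt minimization of the summed
  squared reprojection error with an analytic Jacobian.
- **`arscope.anatomy`** — NIfTI/MetaImage volume IO, seeded region growing
  within an intensity window (150–2200 HU for the CT phantom), marching-cubes
  surface extraction, and re-basing of coordinates to the navel landmark.
- **`arscope.overlay`** — projection of the navel-centred model through the
  registered pose, alpha compositing, and registration error as the symmetric
  Hausdorff distance between silhouette boundaries (px), converted to mm by a
  known-width correspondence.
- **`arscope.stats`** — correction-distance records, per-trocar and pooled
  mean/SD summaries, exact and asymptotic two-sided Mann–Whitney U tests for
  the trocar-pooling rule, and between-arm improvement metrics.
- **`arscope.synthetic`** — the fixture generator: rendered marker and
  checkerboard scenes from known ground-truth cameras, a synthetic 512×512 CT
  of a 101 mm jar at 0.488×0.488×0.625 mm spacing, and simulated two-arm
  trials with per-component error budgets.

## Worked example

Register the marker pose from a rendered frame and measure the end-to-end
overlay error of the jar experiment:

```python
>>> from arscope.experiments import run_jar_experiment
>>> r = run_jar_experiment(seed=1)
>>> print(f"registration error: {r.err_px:.1f} px = {r.err_mm:.2f} mm "
...       f"(jar width {r.jar_width_px:.0f} px, "
...       f"scale {r.scale_mm_per_px:.3f} mm/px)")
registration error: 1.0 px = 0.97 mm (jar width 104 px, scale 0.971 mm/px)
>>> print(f"marker code {r.code_id:#06x}, estimated depth {r.pose.t[2]:.1f} mm "
...       f"(true {r.pose_true.t[2]:.0f} mm)")
marker code 0xa5c3, estimated depth 498.9 mm (true 500 mm)
```

The pipeline renders the 8.45 cm marker fronto-parallel at 50 cm through the
calibrated webcam model, detects and decodes it, estimates and refines the
pose, segments the jar from its synthetic CT, projects the virtual jar
through the *estimated* pose, and compares the projected silhouette with the
analytic silhouette of the real jar. The 1.0 px / 0.97 mm discrepancy is the
registration error the AR system itself introduces.

The same stages are scriptable from the shell:

```bash
arscope marker make --id 0xA5C3 --out marker.png
arscope calibrate --images views/ --board-nx 9 --board-ny 6 --square-mm 25 --out camera.cfg
arscope register --image frame.png --camera camera.cfg --marker marker.json --out pose.json
arscope segment --volume jar.nii.gz --seed 356,256,88 --low 150 --high 2200 --out mask.nii.gz
arscope surface --mask mask.nii.gz --out model.ply
arscope overlay --image frame.png --model model.ply --pose pose.json --camera camera.cfg --opacity 0.5 --out fused.png
arscope validate --records trial.csv --pool 1,3,4 --out report/
```

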