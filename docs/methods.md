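# Methods

## Problem and model

Safe screw placement in the temporal bone (surgical fiducials, bone
conduction and bone-anchored hearing implants) depends on two local
properties that CT can measure: available bone thickness and bone
density. `tbprobe` evaluates both on a regular grid of retroauricular
positions expressed in a landmark-based coordinate system a surgeon can
reproduce in situ with a ruler, and condenses them into two per-position
scores: the Screw Implantation Safety Index (SISI) and the Column
Density Index (CODI).

The processing chain is: bone labeling → island removal → marching-cubes
surface → anatomical frame → grid projection → normal-trajectory
sampling → thickness / cortical density / indices → cohort aggregation.

## Geometry conventions

All computation is in physical millimetres. Voxel indices are 0-based
and refer to voxel centers; `CTVolume.axes` columns are direction
cosines forming a right-handed orthonormal basis, and readers normalize
flipped axes (dominant component of every column positive) so downstream
arithmetic never sees mirrored data. DICOM series are read slice-wise
with consistency checks on orientation and spacing; NIfTI volumes are
reoriented to closest-canonical before decomposition of the affine.

## Anatomical frame

- Origin: the most superior point of Henle's spine.
- y-axis: the axial (transversal) image-plane normal, supplied by the
  caller (unit vector, pointing superiorly). This realizes "probe plane
  perpendicular to the axial plane" with the weakest assumption.
- x-axis: the difference of the two zygomatic-process landmarks,
  projected onto the axial plane and normalized, pointing posteriorly.
  Landmark order (anterior point first) or an explicit `posterior_hint`
  point fixes the sign. A zygomatic direction parallel to the axial
  normal is a hard error.
- z-axis: x × y, flipped on the right side so +z is always lateral.
  With +x posterior and +y superior on both ears, mirror symmetry makes
  it impossible for both sides to be right-handed; the frame is
  right-handed (det +1) on the left and mirrored (det −1) on the right.
  This is deliberate: it lets left and right ears pool into a single
  grid. Probing only assumes +z lateral.

Grid defaults: 8×8, 5 mm spacing, lower anterior corner (4, −10) mm,
row-major anterior→posterior then inferior→superior — 64 probes over
35 × 35 mm².

## Segmentation

- Threshold 620 HU, **inclusive** (`HU >= 620`): "above a threshold" is
  ambiguous at the boundary; inclusive makes the 620 HU case
  deterministic.
- Island removal: 26-connected foreground components with fewer than 300
  voxels are deleted (foreground only; background holes are kept, they
  are real pneumatization).
- Mesh: marching cubes at level 0.5 on the one-voxel zero-padded mask
  (padding guarantees a closed surface when bone touches the volume
  edge), vertices mapped to physical coordinates.
- Smoothing: Taubin (shrink-compensated low-pass, λ = 0.5, ν = −0.53).
  The "4 mm kernel" is interpreted as a Gaussian-equivalent scale: one
  pass diffuses with variance ≈ λh̄² (h̄ = mean edge length), so the
  iteration count is σ²/(λh̄²) with σ = 2 mm (half the kernel size),
  clamped to [1, 200]. The algorithm family is a free choice; only the
  spatial scale is fixed. `smoothing_mm = 0` returns raw marching-cubes
  output.
- Normal orientation is verified by sampling the mask one voxel outside
  face centroids; the mesh is inverted if normals point inward.
- Anatomical ROI cropping is the caller's responsibility (a bounding box
  in frame coordinates); no automatic landmark detection.

## Probing

Grid points are cast along −z (medially). The first triangle hit gives
the entry point; the trajectory direction is that triangle's inward unit
normal. Ray–mesh intersection is an exact vectorized Möller–Trumbore
test over all triangles (meshes at this resolution are small enough that
no broadphase structure is needed).

- Sampling: every Δd = 0.15 mm from the entry point, trilinear
  interpolation by default (`nearest` available as a config option),
  stopping at the thickness cap or the volume boundary.
- Thickness `d_TB`: distance from entry to the **farthest** mesh
  intersection along the trajectory, clamped to 18 mm. Using the
  farthest hit means internal air-cell surfaces crossed by the ray do
  not terminate the measurement — thickness is outer-to-inner cortex.
  A ray with no opposite intersection reports the cap with a logged
  warning instead of discarding the probe.
- Cortical density: mean raw HU over depths `[onset, onset + 1.5 mm]`,
  both ends inclusive (11 samples when aligned), where onset is the
  first sample ≥ 1000 HU; no such sample → `no_cortex`. Averaging is on
  HU; density conversion applies to the mean. The window length is a
  parameter (default 1.5 mm).

## Calibration

Ordinary least squares of `HU = slope · BMD + intercept` on the
six-insert phantom table (water 0 plus 100–800 mg HA/cm³). Conversion
clamps negative HU to 0 before the inverse map and floors the result at
0, so `hu_to_bmd` is total, non-negative and non-decreasing. Without a
phantom, a default slope of 1.32 HU per mg HA/cm³ (intercept 0) is used
with a logged warning.

## Indices

- `SISI(d_min) = 100 · N_S / N` when `d_TB > d_min` (strict), else 0.
  N counts **all** samples at depth ≤ d_min including air; N_S counts
  samples ≥ 1000 HU (inclusive). Defaults d_min ∈ {4, 5} mm, common
  screw lengths.
- `CODI = Σ ρ(i)/1000 · Δd` in mg HA/mm²: calibrated densities
  (mg HA/cm³) are divided by 1000 to mg HA/mm³ before multiplying by the
  step in mm — the unit bridge is ours, chosen so the result is a column
  mass per unit area. The sum runs over the full sampled thickness
  (d_TB, capped at 18 mm); a screw-length-bounded variant is available
  via `depth_limit`.

## Synthetic phantoms

The slab generator emulates the study conditions at the probe scale:
layered cortical/trabecular slabs in −1000 HU air at the clinical voxel
grid (0.156 × 0.156 × 0.2 mm³ by default), water at 0 HU, mastoid air
cells as −800 HU spheres carved into sub-1000-HU layers until a target
volume fraction, additive Gaussian HU noise, all seeded and bitwise
deterministic. Layer boundaries snap to voxel boundaries and the ground
truth records the realized geometry, so recovery tests compare against
what was actually built. The calibration generator produces the
six-insert cylinder phantom with a known linear HU response and returns
the measured insert means.

What the phantoms do **not** model: curved anatomy, partial-volume and
beam-hardening artifacts, spatially correlated noise, soft tissue.
Passing recovery tests therefore demonstrates the correctness of the
geometry and arithmetic, not clinical accuracy on real temporal bones.

## Numerical choices and degenerate cases

- Trilinear interpolation makes the air–bone boundary a one-voxel ramp;
  the entry sample (~midway between air and bone HU) usually falls below
  the 1000 HU onset, so cortical windows start at the first interior
  sample. Analytic phantom truths use the ideal piecewise-constant
  profile; measured SISI/CODI can differ by the one or two boundary
  samples, which the test tolerances reflect.
- Recovery tests probe slabs that are wide relative to the 4 mm
  smoothing scale; near edges the smoothed surface curves and the entry
  normal tilts, which is physical, not an artifact.
- Thickness tolerance for slab recovery is half the voxel diagonal —
  the marching-cubes surface sits half a voxel outside the outermost
  bone voxel centers on each face.
- Problem sizes in tests and the acceptance script (slabs ~20–30 mm
  across at 0.2–0.3 mm voxels) were chosen as the smallest volumes on
  which surface curvature, smoothing and sampling interact as they do at
  clinical resolution.
- Tie-breaks: thresholds are inclusive everywhere (620 HU bone, 1000 HU
  onset/dense); sample-count arithmetic uses floor with a 1e-9 guard.

## Scope and limitations

Cohort-level clinical findings (thickness gradients, cohort mean
densities, ear-side effects) require patient scans and are out of scope,
as is mixed-effects statistical modeling — the per-probe CSV is designed
to feed external statistics packages. The indices are radiographic
scores; biomechanical validation (pullout strength, osseointegration) is
future work. No automatic landmark detection, no multi-frame enhanced
DICOM, no beam-hardening or scanner cross-calibration corrections.
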