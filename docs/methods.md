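# Methods

## Model overview

The package simulates bony impingement of the hip as rigid contact
between two triangle meshes: an acetabular cup (part of the hemipelvis)
and a proximal femur, articulated as an ideal ball joint about the
femoral head center.  No soft tissue is modeled — no labrum, capsule or
ligaments — so every motion limit reported here is a *bony* limit, an
upper bound on what the corresponding anatomy could reach.  All lengths
are millimetres, all angles degrees; the canonical frame is a right hip
with +x lateral, +y anterior, +z superior, and the neutral-pose head
center at the origin.  Left-side input meshes are mirrored across x = 0
at import.

## Synthetic anatomy

Patient CT segmentations are emulated, not used.  The generator sweeps
structured ring meshes that are watertight by construction (Euler
characteristic 2, verified per mesh):

* **Femur** — a spherical head (radius 24), a coaxial cylindrical neck
  (radius 16.5, so the cam-free alpha angle is arcsin(16.5/24) ≈ 43°, in
  the normal anatomical range), a circular-arc bend to a vertical shaft
  (neck-shaft angle 130°, femoral anteversion 15°), and a shaft truncated
  90 mm below the head.  The epicondylar landmarks that define the
  mechanical axis are placed analytically at the anatomical knee
  distance (380 mm); landmarks need not lie on the mesh.
* **Cam lesion** — a smooth radial bump at the head-neck junction,
  Gaussian in both the polar direction (width growing with amplitude:
  σ_θ = 7° + 1.3°/mm · A toward the head, 8° toward the neck — a tall
  cam is also a broad cam, which keeps the measured alpha strictly
  increasing in amplitude) and the circumferential direction (σ_φ =
  15°), centered at φ = 32° from anterior toward superolateral — the
  zone engaged at 90° flexion plus internal rotation, and clear of the
  flexion-contact zone (φ ≈ −60°), so resecting it restores rotation
  without materially changing flexion, as the emulated study observed.
* **Pelvis** — a hemispherical cup shell (inner radius = head radius +
  0.5 mm clearance, rim thickness 5 mm) whose pole axis encodes lateral
  coverage (rim at the lateral-coverage angle from vertical) and
  anteversion (default 15°).  Only rim geometry participates in bony
  impingement, so no iliac block is attached; the anterior pelvic plane
  landmarks (both ASIS, pubic symphysis) are synthetic points at
  adult-scale offsets, coplanar with the vertical so the supine
  functional pelvic plane is exactly the anterior pelvic plane (a
  configurable sagittal tilt, default 0°, stands in for soft-tissue
  pelvic tilt).

Two 1-D root finds calibrate the generator against the package's own
radiographic measurements: cam amplitude against a target alpha (to
±3°) and lateral coverage against a target CE (to ±2°).  Cohorts draw
per-case alpha/CE targets from truncated normal distributions inside
each diagnostic window (cam groups: alpha ∈ [55°, 84°]; no-cam group:
alpha ∈ [46°, 54.9°], floored at the generator's cam-free baseline;
borderline-DDH CE ∈ [20°, 24.9°]; cam-FAI CE ∈ [25°, 40°]) — rejection
sampling mirrors the study's inclusion rules rather than the raw
population.  Neck-shaft angle (SD 3°), femoral anteversion (SD 4°) and
cup anteversion (SD 4°) vary normally around the defaults to give
within-group spread.  All sampling flows from one master seed through
`numpy.random.SeedSequence`, so a cohort is byte-reproducible.

## Radiographic measurements

Alpha: the neck axis is estimated from the mesh (centroid direction of a
neck-band shell, 1.35–1.85 head radii from the center); vertices within
1.6 head radii are binned into 36 circumferential sectors; each sector's
radial profile r(θ) is scanned from the apex down for its crossing of
the fitted-head radius + 0.5 mm (a sub-voxel departure threshold,
configurable), with linear interpolation at the crossing; alpha is the
sector maximum.  If no sector departs, the cam-free geometric minimum is
returned with a flag.  CE: on the orthographic A-P projection, the
largest angle from the superior axis to a head-center-to-vertex line
among vertices lateral to the center and within a ±6 mm coronal slab
(the slab keeps the anterior/posterior walls out of the sourcil
measurement).  Classification applies the diagnostic thresholds exactly
as quoted in the glossary of definitions, with pincer exclusion tested
before the cam rule and CE 24.x treated as borderline (20 ≤ CE < 25).

## Motion limits

Poses compose flexion about the pelvic medio-lateral axis, then internal
rotation about the flexed femoral mechanical axis (head center →
epicondylar midpoint) — the clinical maneuver.  Contact is femur-vertex
to pelvis-surface distance, signed by the local face normal so
interpenetration counts as contact; the broad phase is a cKDTree over
pelvis vertices with a conservative pad, the narrow phase exact
point-triangle distance over the k nearest triangle centroids.  Femur
query vertices are pre-filtered to the exact radial band the pelvis
surface occupies around the rotation center (valid under pure rotation).
The limit search advances by steps bounded by (clearance − tolerance) /
(max vertex radius) — a Lipschitz bound on how fast the distance field
can change per radian, so the search cannot tunnel through the 5 mm rim
shell — then bisects the bracket to 0.1° and validates contact one
resolution step past the limit, recording the witness midpoint in
neutral femoral coordinates as the impingement point.  A case is
excluded when impingement appears below 90° of flexion; caps (150°
flexion, 90° rotation) are reported explicitly via `reached_cap`.
The exhaustive ascending sweep (`sweep_limit`, 0.05° steps) exists as an
independent validation oracle for the bracket search.

One consequence of signed contact at a fixed tolerance: *raising* the
contact tolerance stops the search earlier, so limits are monotonically
non-increasing in the tolerance.

The proximal/distal impingement-region boundary is the plane
perpendicular to the neck axis through the circle where the fitted head
sphere blends into the neck (axial offset √(R² − r_neck²)); ties go
proximal.  The source protocol this split imitates is not fully
specified, so region distributions are treated qualitatively; in the
synthetic cohort the cam groups' terminal contact sits on the bump and
classifies proximal almost uniformly, which can make the cohort's own
2×2 region table degenerate (reported as undefined rather than forced).

## Virtual resection

The trough is carved as a height-field displacement: vertices whose
footprint coordinates fall inside the elliptical outline (width/2 along
the circumferential direction, length/2 along the projected long axis)
move along the inward normal to the half-ellipsoid depth profile,
tapered smoothly over the outer 30% of the footprint ("edges trimmed
smoothly").  Material standing above the tangent plane at the center is
lowered by the full ellipsoid column, so the removed solid is always
contained in the half-ellipsoid — its volume is bounded by
(2/3)π(w/2)(L/2)d — and, because topology never changes and vertices
only move inward, the post-operative mesh is watertight and motion
limits can only increase.  The trough orientation uses an area-weighted
average of face normals within 4 mm (a burr is oriented against the
smoothed surface, and the averaging keeps repeat placements stable).
The 10 × 1.5 mm slice description of the resection length is honored as
a total 15 mm, not as a stair-stepped cut, and width is a chord, not an
arc.  Repeatability experiments jitter the center tangentially
(Gaussian, σ = 1 mm by default) and re-project it onto the surface.

## Statistics

Group means use the sample SD (n − 1); single-case groups report an
absent SD.  One-way ANOVA is computed from the explicit sum-of-squares
decomposition (degenerate all-equal input returns F = 0, p = 1,
flagged).  The post-hoc procedure is Tukey's HSD by default
(Bonferroni-corrected and unadjusted t-tests are available); the
emulated study reports pairwise p-values without naming its correction,
so exact pairwise p replication is not asserted anywhere.  The
contingency comparison is the two-sided Fisher exact test; ICC is the
one-way random-effects ICC(1,1) from the ANOVA variance decomposition
with the standard F-based 95% CI.  With the design size used for
repeatability (20 subjects × 2 repeats) the ICC's own sampling CI is
roughly ±0.2, so single-seed point estimates scatter accordingly; the
sufficient-resection ICC is the stable summary at this size.

## Problem sizes and tolerances

Default mesh edge length 2 mm (ring spacing refined to ~0.8 mm near the
head-neck junction, where the alpha contour and the trough live);
femora ≈ 7,000 vertices, cups ≈ 3,500.  Contact tolerance 0.1 mm,
angular resolution 0.1°, caps 150°/90°.  A full 38-case study (frames,
radiographs, pre-op limits, two resections, post-op limits) runs in
about half a minute on one CPU; the repeatability experiment adds
comparable time.  These sizes are the package's defaults and are what
the test suite and the acceptance script use.

## What the synthetic cohort does and does not show

The generator reproduces the *design* of the emulated study — group
sizes 15/11/12, the reported alpha and CE distributions, the diagnostic
windows — not its patients.  Qualitative findings reproduce robustly
across seeds: pre-operative internal rotation orders no-cam DDH >
DDH-with-cam > cam-FAI; both cam-bearing groups gain several degrees
more from the sufficient resection than the no-cam group; flexion is
essentially unchanged by resection; cam-FAI flexion is the most
restricted.  Absolute magnitudes are compressed relative to the
clinical report (synthetic pre-op IR means run some 10–30° lower),
because idealized cups, a single shared base anatomy and the absence of
soft-tissue-constrained reference frames narrow the between-patient
spread.  Passing tests therefore demonstrate internal consistency and
mechanism — not calibration of absolute ranges of motion against any
patient population.

## Known limitations

Ball-joint kinematics (no translation or subluxation); bone-on-bone
contact only; a minimal cup stands in for the hemipelvis; one shared
parametric base anatomy; orthographic projections stand in for
radiographs (no beam divergence); the cross-table-lateral view is
simplified to the head-neck plane projection; the functional pelvic
plane is operationalized as the anterior pelvic plane with an optional
tilt offset.
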