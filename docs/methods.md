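# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind `elbowaxis`.  Units are millimetres and degrees throughout;
coordinates are right-handed.

## Axis constructions

**Epicondylar axis.** Each epicondyle is the arithmetic mean of its three
picked points (simulating the palpable surgical landmarks); the axis joins the
two means, oriented lateral → medial.  Averaging three picks reduces the
picking noise per coordinate by √3.

**Long (intramedullary) axis.** A provisional shaft direction is derived from
the mesh itself: vertices are ranked along the principal direction of the
vertex cloud, and the provisional axis joins the centroids of the most distal
and most proximal 10% of vertices, with its sign fixed to point away from the
articular mass (the groove-point centroid).  The landmark file bounds the
usable diaphysis/metaphysis as scalar coordinates along this provisional
direction, measured from the vertex centroid.  Five slicing planes sit at
fractions {0.1, 0.3, 0.5, 0.7, 0.9} of this window — placed away from the
window ends to avoid end effects — and the largest-perimeter contour of each
plane section is fitted with a planar ellipse.  The long axis is the
total-least-squares line (principal direction of the centered scatter) through
the five ellipse centers, oriented distal → proximal.  One re-slicing pass
normal to the fitted axis (default on) removes most of the dependence on the
provisional direction; the ellipse centers of a cylinder cut at a modest tilt
still lie on the true axis, so the null-phantom long axis is recovered to
~1e-6 degrees.

**Ellipse fit.** Geometric, not algebraic: the residual of a point is its
radial deviation `|p − C| − R(θ)` along the ray from the center, with `R(θ)`
the boundary radius at the point's polar angle.  A moment-based initialization
(centroid, √2·coordinate SDs, principal angle) feeds a Levenberg–Marquardt
refinement of (center, radii, orientation); an axis-aligned variant fixes the
orientation.  Exact samples are recovered to 1e-8.

**True F-E axis (circle fit).** The 3D circle minimizes the summed squared 3D
point-to-circle distances `d² = (q − r)² + w²`, with `q` the in-plane distance
to the center and `w` the out-of-plane offset.  The radius is profiled out in
closed form (`r = mean q`), and Gauss–Newton iterates on the residual stack
`[q − mean(q); w]` over center (3 dof) and plane normal (2 dof, updated in a
local tangent basis).  Profiling the radius matters: in the unprofiled
parametrization the radius column and the along-normal center column of the
Jacobian become nearly parallel whenever the points lie close to a plane
through the current center, and the normal equations reach condition numbers
above 1e14.  Initialization is the PCA plane plus a 2D algebraic (Kåsa) fit;
convergence is declared on a relative objective change below 1e-12 or a step
norm below 1e-10, guarded by a gradient test so that heavily damped
micro-steps far from a stationary point are not mistaken for convergence, and
a Levenberg damping term activates whenever a plain Gauss–Newton step fails to
decrease the objective.  Maximum 100 iterations; non-convergence flags the
result instead of raising.  On 100 seeded noisy instances the fit matches or
beats a brute-force grid-refinement oracle in ≤ 5 iterations.  Reported
radial residuals are signed (in-plane distance minus radius, positive =
outside); out-of-plane components are kept separately in the diagnostics.
The circle normal is canonically oriented toward the specimen's
lateral → medial reference so downstream signed angles are reproducible.

## Anatomical frame and sign conventions

The frame is built from the two fitted axes alone: coronal normal ∝
long × F-E (oriented anterior), axial normal along the long axis, sagittal
normal completing the orthonormal triad (oriented medial); the signed
directions (anterior, medial, distal) form a right-handed triad, with the
chirality flipped for left-side specimens (which the file-level pipeline
mirrors to a canonical right side before analysis).

Per-plane rotational differences are signed angles, right-hand rule, from the
projected epicondylar axis to the projected F-E axis, about oriented
measurement normals **anterior** (coronal → external/internal), **medial**
(sagittal → flexion/extension), and **proximal** (axial → varus/valgus).  Both
axes are canonically oriented lateral → medial first to avoid 180° ambiguity.
By angle additivity this equals the difference α − β of the projected angles
to the long axis wherever those are defined, and it remains well defined in
the planes where the long axis (axial) or nearly the F-E axis (sagittal)
degenerates under projection.  Offsets are resolved onto (anterior+, medial+,
distal+); the third component is labelled inferior–superior with distal
positive, matching the printed table convention.

**The sagittal measure is ill-conditioned by construction.**  The sagittal
plane is perpendicular to the F-E axis up to the small angle 90° − α, so both
axes project onto it as short vectors of length ≈ cos α ≈ 0.1–0.15.  The
flexion/extension difference is the angle between these small projections: it
is exactly defined, rigid-motion invariant, and recovered perfectly on
phantoms, but it amplifies anterior-tilt differences by roughly 1/cos α and
it responds strongly to axial-plane rotations.  Exactly perpendicular axes
(α = 90° with no anterior tilt) make the component degenerate; it is then
flagged NaN while the other components are still reported.

## Why the three rotational offsets are not independent dials

With the frame tied to the long and F-E axes, the six translational
components biject onto the six epicondyle coordinates once the exit points
are fixed, so the epicondylar direction is forced to
`w·d_FE + (V_lat − V_med)` with `w` the articular width between the exit
points.  A tilt of the F-E axis about the long axis is pure gauge (the frame
co-rotates), leaving exactly **two** free parameters — α and w — behind the
three per-plane rotational offsets.  The generator therefore solves (α, w) so
that the varus/valgus and external/internal targets are met exactly (to
1e-10, verified at generation time by re-measuring the ground truth with the
package's own code), while the flexion/extension offset is a *dependent*
quantity echoed back as achieved.  At the default construction values the
achieved flexion offset is ≈ −13.3°, driven by the −2.7 mm anterior offset
difference between the lateral and medial sides divided by the short sagittal
projections.  Real specimens obey the same constraint individually; cohort
*means* of the three rotational offsets need not be jointly realizable by any
single specimen, which is why a phantom cannot carry all nine cohort-mean
values at once.

## The synthetic phantom

The phantom emulates exactly the features the pipeline measures:

* an **elliptical shaft** (default radii 11 × 9 mm, length 90 mm, optional
  anterior bow in degrees) along a known centerline; the ground-truth long
  axis is the TLS line through the centerline points at the five slice
  fractions, so a bowed shaft remains self-consistent;
* an **articular spool**, a surface of revolution about the F-E axis whose
  radius profile dips to exactly the groove radius (default 9 mm) at the
  ground-truth circle and carries trochlear flanges and a capitellar bulge;
  the profile tapers to flat 1.2 mm end disks at the exact intended exit
  points, so the F-E line exits through the disk planes at the ground-truth
  trochlear and capitellum points irrespective of mesh resolution (ring
  vertex counts are kept odd so no cap triangle vertex sits on the axis);
* **epicondylar protrusions**, ellipsoids whose outer pole vertex is exactly
  the requested epicondyle apex (skipped when the apex lies on the articular
  mass, as in the null phantom), and a **posterior metaphyseal bridge**
  connecting shaft and epicondylar columns;
* **landmarks**: three picks per epicondyle jittered on the protrusion
  surface, and 20 groove points on the ground-truth circle over a 250° arc
  centered inferiorly (away from where the trochlea merges into the shaft),
  jittered tangentially and axially with SD σ and radially with σ/3,
  emulating imperfect picking of the "deepest part".  All draws come from a
  single seeded generator; the same spec and seed reproduce the mesh and
  landmarks byte-identically.

The mesh is the concatenation of these closed part surfaces.  Each part is
watertight and outward-oriented; the union is edge-manifold but
self-intersecting where parts overlap (no boolean-union step).  This is
irrelevant to every pipeline operation — plane sections are taken in a shaft
window kept clear of the articular mass and bridge, and exit points are the
*extreme* line-surface intersections — and generation aborts with an error if
the audit finds the F-E line exiting anywhere but the intended cap centers.
Default resolution (97 ring vertices × 96 profile stations, ≈ 30k triangles)
keeps a full pipeline run under a second; tests use a reduced 49 × 48 phantom
where many runs are needed.

What the phantom does **not** emulate: cortical/trabecular texture,
segmentation artifacts, osteophytes, anatomical asymmetry of the groove, or
any imaging physics.  Passing recovery tests therefore demonstrates the
correctness of the geometry pipeline, not robustness to real CT segmentation
noise.

Cohorts draw the six translational components (SDs 4.0/3.4/5.3 and
4.1/1.6/5.2 mm, the reported cohort spreads), α (83.7 ± 3.8°) and the
articular width (42 ± 4 mm, a plausible articular span) from ±3 SD truncated
normals; per-specimen rotational offsets emerge from the drawn geometry (see
above), giving an emergent varus spread of ≈ 2.7 ± 5.7° across cohorts.
Unrealizable draws are redrawn a bounded number of times and logged.

## Statistics

Column summaries use the sample SD (n − 1).  Shapiro–Wilk and Student's
t-tests delegate to scipy.stats; the medial-vs-lateral offset comparison is
paired by default (both offsets come from the same specimens) with a
two-sample variant behind a flag, and no multiple-testing correction is
applied (α = 0.05 per comparison).  A paired test with zero-variance
differences returns a flagged degenerate result rather than raising.
ICC(2,1) (two-way random, absolute agreement) and ICC(3,1) (two-way mixed,
consistency) are computed from the two-way ANOVA mean squares in the
McGraw–Wong formulation, with significance from F = MSR/MSE on
(n − 1, (n − 1)(k − 1)) degrees of freedom; the implementation is
cross-checked against pingouin to 1e-10 in the tests.  Statistical
calibration runs (power and null rejection of the paired M-L test, 2000
replicates of n = 15) use the generator's parameter sampler directly — on
noise-free landmarks the measured offsets equal the drawn parameters exactly,
so cohort-level statistics do not require building 30 000 meshes.

## Problem sizes and tolerances used in validation

Null phantom and cohort-mean phantom at default resolution, zero jitter:
rotational differences < 0.05° and translational components < 0.1 mm (null),
recovery of construction values within 0.2°/0.2 mm (cohort-mean; the flexion
component is checked against the requested value and documents the dependence
above).  Oracle equivalence on 100 seeded instances each for the circle and
ellipse fits (20 and 36 points, noise SD up to 1 mm) at ≤ 1e-6 relative
excess over a grid oracle refined three times.  Rigid-motion invariance over
50 seeded rotations+translations of a reduced-resolution phantom at < 1e-6
(degrees and mm).  All invariant checks (Pythagorean consistency of offset
records, frame orthonormality to 1e-9, projection idempotence to 1e-12) also
run as assertions inside every pipeline execution.

## Known limitations

* The flexion/extension offset cannot be dialed independently of the
  translational components (geometric identity, documented above); its
  acceptance check against the requested cohort-mean value fails by design
  and is kept failing rather than weakened.
* Exit points are taken on the raw mesh surface; no articular-surface
  smoothing is applied.
* The epicondyle apex-finding procedure on the bone surface is not
  implemented; epicondyles come from the picked landmarks only.
* Groove start/end selection "according to curvature" is an acquisition
  detail outside the package; groove points arrive in the landmark file.
* Left-side handling mirrors the specimen to a canonical right side; the
  mirroring plane is the global yz-plane, so left-side meshes must use the
  same x = medial-lateral convention as right-side ones.
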