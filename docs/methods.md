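# Methods

`raoplan` simulates the complete accuracy-evaluation loop for navigated
rotational acetabular osteotomy (RAO): phantom generation → virtual
osteotomy and reorientation planning → simulated intraoperative
confirmation → synthetic postoperative model → rigid registration →
clock-face sector-angle measurement → per-position group statistics. This
note records the model, the defaults and the design decisions; everything
quantitative stated here is computed by the test suite or the acceptance
script, not transcribed from elsewhere.

Units are millimetres and degrees throughout. The internal convention is a
right hip with x mediolateral (toward the contralateral side — the
reference direction for sector angles), y anterior, z cephalad; left-hip
models are mirrored across the mid-sagittal plane on entry and their side
recorded, so a single clock convention serves all measurements.

## The hip phantom

The phantom idealises the hemipelvis around a femoral head of radius 24 mm
(best-fit-sphere territory for an adult hip):

- an **articular cup**: a spherical shell concentric with the head at
  radius 26 mm (head + 2 mm joint gap), opening medially into a
  non-articular **fossa** of 30° polar radius;
- a 4 mm **backing shell** (the outer cortex a pointer can touch);
- a peri-acetabular **collar** out to 52 mm radius so a spherical osteotomy
  passes through bone at every azimuth, and a slab-like **iliac wing** over
  the posterosuperior azimuths (raised-cosine lobe, 38 mm long, centred
  35° posterior of 12:00) that twists out of the radial direction by up to
  ±30°, plus tubercle-like ridges at four asymmetric azimuths.

Per-clock coverage is prescribed directly: the rim point at azimuth φ sits
at polar angle ASA(φ) from the +x axis, with ASA(φ) interpolated
periodically from the coverage map. The default map is a superolateral-
deficiency pattern: ASA 100° at 12:00 (lateral centre-edge analogue
CE = ASA − 90 = 10°), rising to 115–127° anteriorly/posteriorly and ~145°
inferiorly. With the 30° fossa this fixes the mid-frontal roof chord, so
the preoperative phantom measures lateral CE 10°, anterior CE 37°, roof
obliquity (ARO) 25°, acetabular head index 59% and head-centre-to-Köhler
distance 45 mm — the morphology of a typical preoperative RAO cohort. A
`dysplasia_severity` scalar adds or removes superolateral coverage (15° per
unit, tapering as cos φ).

Because rim, fossa edge and head centre are analytic, the phantom is its
own oracle: requested coverage must be re-measured to within ±1° (mesh
interpolation) at every clock position, and that round-trip is tested.

Three features exist purely because *surfaces of revolution cannot be
registered*: the mesh parameterisation is jittered (seeded, deterministic;
every vertex stays exactly on the analytic surface), the wing twists out of
the radial cone, and the cup/backing shells carry a smooth sub-millimetre
radial waviness (feathered to zero at the rim and fossa edge). Without
them, any rotation about the mediolateral axis slides the phantom over
itself and the registration problem is ill-posed — which no real pelvis is.

What the phantom does **not** emulate: CT voxelisation and partial-volume
effects, segmentation bias, cartilage vs bone distinction, cortical
thickness variation, the anatomical osteotomy path (innominate groove /
sciatic notch — the cut here is the pure sphere), and inter-patient shape
variability (one parametric shape, not a statistical shape model). Passing
tests therefore demonstrate correctness of the geometry/measurement
pipeline under known ground truth, not clinical performance on real CT.

## Virtual osteotomy and reorientation

The osteotomy sphere is centred on the fitted head centre (offset
configurable, must stay within 10 mm) with default diameter 85 mm, the
midpoint of the usual 80–90 mm range; diameters outside 60–120 mm are
rejected. Mesh triangles crossing the sphere are split along the exact
intersection; the fragment is the vertex-connected component inside the
sphere that carries the rim (vertex connectivity, not edge-manifold
connectivity, because the parametric multi-sheet surface has non-manifold
seams).

The reorientation transform is decomposed, all about the osteotomy-sphere
centre, into a lateral rotation β about the anteroposterior axis, an
anterior rotation γ about the mediolateral axis, and a medialising
translation along x. Targets: mid-frontal ARO = 0°, anterior CE at the
midpoint of 45–50°, Köhler distance at the midpoint of 35–40 mm. β and γ
are coupled on a spherical fragment (both move the mid-frontal roof chord
and the anterior rim), and sequential relaxation stalls between them, so
the solver nests the two 1-D bisections: for each trial γ the inner
bisection finds β with ARO on target, and the outer bisection moves γ until
the anterior CE lands on its midpoint along that manifold. Each 1-D solve
scans a grid for sign changes first (the measured responses have
discrete-geometry branch jumps; brackets that collapse onto a jump are
discarded and the next-nearest tried) and then bisects to 0.1° / 0.1 mm.
Solutions needing more than a 60° composite rotation raise an infeasible-
plan error carrying achieved vs target values. On the default phantom the
solve lands at β ≈ −31°, γ ≈ −45° (composite 54°), medialisation 7.5 mm.

The planned head centre is the preoperative fitted centre carried through
the reorientation transform — the femoral head follows the reoriented
acetabulum. This is what makes the medialisation target meaningful (a
fixed measurement centre would never change its Köhler distance) and what
makes ΔASA vanish identically in the zero-error case.

Four fiducials are placed evenly over a 60° superolateral rim arc
(consecutive spacing 20°), offset 5 mm peripheral to the rim and snapped to
the fragment surface; the arc must separate them by more than the 2 mm
notch diameter. Relocation applies the plan transform exactly, pairing
#1→#5 … #4→#8.

## Postoperative simulation and the error models

A placement attempt is a rotation about the planned head centre (per-axis
normal SDs) plus a per-axis normal translation, applied *after* the planned
transform — i.e. a patient-space perturbation of the planned pose, so a
forced δ rotation about the anteroposterior axis shows up as
ΔASA(12:00) = δ exactly. The two confirmation checks are rejection
samplers (attempt budget 1000):

- **surface touch**: five digitized points on the outer lateral surface
  must each lie within the acceptance tolerance of the *planned* surface;
- **fiducial**: each digitized notch must lie within tolerance of its own
  relocated counterpart — all four, no best-of.

Defaults (simulation parameters, not clinical measurements): rotation SD
3°/axis for the surface-touch arm and 1°/axis for the fiducial arm,
translation SD 1 mm, pointer noise 0.3 mm, acceptance tolerance 2 mm. The
asymmetry in rotation SD encodes that the fiducial display lets the surgeon
iterate toward a tighter pose; the different *checks* then shape what each
arm accepts. Per-axis SDs are accepted so that single-axis contrasts (e.g.
both arms identical except rotational control about the anteroposterior
axis) can be constructed; in that scenario the significant band
concentrates around 12:00, since such rotations barely move the rim inside
the 9:00/3:00 radial planes.

The postoperative model places fragment + head at the accepted pose,
jitters the pelvis vertices (default surface noise 0.2 mm, segmentation-
scale), and moves everything by a random scanner pose (≤ 20° / 30 mm).

## Registration

`icp()` is deliberately the textbook primitive: nearest-vertex
correspondence via a KD-tree (ties to the lowest index), full Kabsch
re-solve per iteration, termination at mean-squared error ≤ 1e-5 mm²,
improvement < 1e-12, or the iteration cap; vertex sets above 50k are
seeded-subsampled. One of its iterations is tested against brute-force
exhaustive nearest neighbours plus Kabsch.

Vertex-to-vertex ICP between identically triangulated copies has a failure
mode worth documenting: the mesh lattice admits *permutation-locked
fixpoints* in which every vertex pairs with a neighbouring grid column
(residual rotation ≈ one azimuth step, ~4.5° here) and the Kabsch update
reproduces the current pose exactly. Shape asymmetry does not remove these
fixpoints. `robust_icp()` therefore adds an escape stage when the vertex
stage stalls above tolerance: correspondences are re-projected onto the
destination *surface* (exact point–triangle projection over KD-tree
candidate faces, seeded source subsample of 2000), which has no lattice
fixpoints, followed by a final vertex pass that reports the standard MSE.
Registration inside the case pipeline is instead initialised from paired
remainder-fixed landmarks (ASIS, pubis, Köhler points, contralateral head
centre) — the coarse alignment any navigation workflow performs — and
refined with plain vertex ICP; the default region is the iliac remainder
only, so fragment misplacement cannot bias the pelvis alignment
(whole-model registration is retained as an option and is measurably worse
under misplacement).

## Measurement

The clock face is built on the anterior pelvic plane (APP: both ASIS and
the pubic midpoint; anterior chosen as the side away from the head
centres): 12:00 cephalad in the APP, 3:00 anterior, one radial plane per 30
clock minutes (15°) about the x-axis through the head centre; the default
face spans 9:00→3:00 through 12:00, 13 planes. The ASA at a position is
the in-plane angle at the head centre between +x and the rim crossing of
that half-plane (linear interpolation along the rim polyline; if the rim
crosses more than once the crossing farthest from the centre — the
radiographically visible edge — is used and the event logged; no crossing
yields NaN, logged, never zero). Profiles use the fitted head centre of
the model's head mesh, except planning profiles, which use the planned
head centre.

Frontal-projection analogues: lateral CE = ASA(12:00) − 90; anterior
CE = ASA(3:00) − 90; AHI = percentage of the mediolateral head width medial
of the lateral rim (clamped to [0, 100]); Köhler distance = point-to-line
distance from the head centre to the landmark proxy line. ARO sections the
pelvis with the mid-frontal plane, keeps superior points within 5% of the
12:00 rim radius, takes the contiguous angular run containing the lateral
rim, and measures the chord from the run's medial end (an exact fossa-edge
crossing, since section polylines terminate on mesh boundaries) to the
exact 12:00 rim crossing; values beyond ±60° or runs shorter than 10° are
treated as unmeasurable (NaN) rather than reported.

## Statistics

Per clock position, cohorts are compared on |ΔASA| (signed mode available)
with Student's unpaired pooled-variance t test implemented from the
formula and cross-checked against an independent reference implementation
to 1e-9; p < 0.05 is flagged. Thirteen positions are tested, so a
Holm-adjusted column is emitted alongside the unadjusted one; the
unadjusted column is the primary read-out, mirroring per-position practice
in radiographic accuracy studies. Zero variance in both groups yields
t = 0, p = 1 for equal means and an undefined-p marker otherwise. Power for
the two-sample design uses the noncentral t distribution
(nc = d·√(n/2), df = 2n − 2; one- or two-sided), verified against a
Monte-Carlo rejection-rate oracle.

## Problem sizes and determinism

Default meshes use a 2 mm target edge (pelvis ≈ 7k vertices), cohorts use
20 joints per arm sharing one phantom and plan (only errors, noise and
scanner poses differ), and the replicate experiment for the method
contrast runs 50 cohort pairs; at these sizes a full cohort pair takes
about a second and the replicate experiment about a minute on one core.
Every stochastic stage consumes an explicit seed (phantom parameterisation
jitter, placement draws, digitization, surface noise, scanner pose, ICP
subsampling), and identical seeds reproduce bit-identical results; the
cohort report writes a manifest from which the identical CSVs can be
regenerated.

## Known limitations

- One parametric phantom, not a shape population: cohort variability comes
  entirely from the error models.
- The error-model SDs and tolerances are plausible simulation choices, not
  measured intraoperative distributions; conclusions are about the
  *relative* behaviour of the two confirmation checks under matched
  conditions.
- The postoperative lateral CE of the planned phantom (~46°) is higher
  than typical clinical outcomes, a consequence of prescribing ARO 0° with
  an idealised 30° fossa; the coverage map can be adjusted per study.
- Rim extraction from real segmentations is out of scope: models must
  carry a rim polyline (the phantom emits one; for real data it would come
  from upstream tooling).
- Standing-pelvis tilt correction and 2D radiograph simulation are not
  implemented.
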