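# Methods

This note records the models implemented in `femstrength`, the defaults and
their units, the numerical choices, and what the synthetic validation does
and does not demonstrate.

## Quantitative CT calibration

The calibration phantom is described by nominal rod densities (mg/cm³ of
hydroxyapatite equivalent) and explicit rod regions — world-space cylinders
or voxel masks. Rods are never auto-detected: localization is an input, so
the calibration is deterministic and testable. A voxel belongs to a region
iff its center lies inside it; the fit is ordinary least squares of density
on mean rod HU, reported with its R². `hu_to_density` returns ρ in g/cm³
and may return negative values for air-like HU; the property laws clamp
them. No water/air reference correction is applied beyond the rod line.

The calibration output is treated as *the* ρ of the property laws. The
literature distinguishes ash, apparent and HA-equivalent density, and
published power laws are not always explicit about which they expect; here
the HA-equivalent value from the phantom line is used throughout and the
choice is a visible constant of the pipeline, not something hidden in a
law's coefficients.

## Specimen geometry

Segmentation takes an HU threshold, keeps the largest connected component
and extracts the marching-cubes iso-surface at that threshold in world mm.
The specimen cut is a plane `cut_distance` (default 120 mm) from the
greater-trochanter-tip landmark along the distally pointing shaft axis,
tilted `coronal_slope_deg` (default 20°) about the anterior axis; landmark
and axes are explicit inputs (the synthetic generator provides them;
anatomical landmark detection is out of scope). After cutting, the model is
rotated into a canonical stance frame: load axis = global −z, shaft at the
slope angle to vertical in the x–z (coronal) plane, landmark at the origin.
The rotation is recorded as a 4×4 transform so material mapping can query
the CT volume in its own frame. The tilt is applied by rotating the model
rather than the load; the two are mechanically equivalent and a rotated
model keeps the solver's constraint handling axis-aligned.

The cut face is closed by ear-clipping the boundary loops of the uncapped
plane slice (duplicate vertices introduced along the cut line are welded
first). Ear clipping handles the simple, star-shaped cross-sections that
femoral shafts produce; pathological multi-genus cut faces are not a target.

### Tetrahedralization

The mesher is Delaunay-based: surface samples at roughly the target edge
length (a coarse analytic surface is subdivided so samples lie exactly on
it, a dense scanned iso-surface is grid-clustered and snapped back) plus an
interior body-centred-cubic lattice at 1.05× the target edge, triangulated
with Qhull and filtered to tetrahedra whose centroids lie inside the
surface. Interior points closer than half the target edge to the surface
are dropped to avoid slivers; remaining tetrahedra with volume below
10⁻⁷·edge³ are discarded. All tets are reordered to positive signed volume.
Point-in-surface queries use a bucketed z-ray-casting kernel with a
sub-micron irrational jitter against edge-degenerate rays (numba-jitted
when numba is importable).

Contracts verified by the suite: a 20 mm cube meshes to its analytic volume
within 0.5% (exactly, in practice), a 10 mm sphere within 2% with the error
non-increasing from 3.0 to 1.5 to 1.0 mm edges, and the median edge length
stays within 25% of the target.

Shell elements are attached to every boundary triangle except those on the
cut face or fully inside the resin-fixed node set, with a uniform thickness
(default 0.2 mm). `fixed_distal` collects all nodes within the distal depth
(default 30 mm) of the cut plane; `cap_contact` collects boundary nodes
within the cap angle of the upward load axis as seen from the femoral-head
centre (given, or fitted by least squares to the proximal boundary nodes).

## Material model

Per-element HU is the mean over voxel centers inside the tetrahedron; a
tetrahedron containing no voxel center (possible for boundary slivers when
elements approach the voxel size) falls back to trilinear interpolation at
its centroid. The normative density–property law is Keller's vertebral
relations, E = 1890 ρ^1.92 MPa and σ_c = 284 ρ^2.27 MPa; the published
piecewise conditions are implemented as: E = 0.001 MPa for ρ ≤ 0 (reading
the stray "ρ < 0" condition on the power branch as a sign typo — a power
law is undefined there and the companion line already covers ρ = 0) and
σ_c = 10²⁰ MPa for ρ ≤ 0.2, a sentinel that leaves low-density elements
effectively elastic. During assignment the modulus is clamped to
[0.01 MPa, 20 GPa] — so the final E at ρ = 0 is the 0.01 MPa floor while
the raw law still returns 0.001 — ν is fixed at 0.3 and σ_t = 0.8 σ_c.
Shells are assigned as if their CT value were 1000 HU. Alternative power
laws (Keyak, Carter, ...) can be registered with caller-supplied
coefficients and citations; only the vertebral law ships with coefficients.

Drucker–Prager constants follow from the two uniaxial strengths in closed
form: α = (1−r)/(√3(1+r)), k = r σ_c (α + 1/√3) with r = σ_t/σ_c; r = 1
recovers von Mises. The sentinel yield produces k ≈ 10²⁰ without overflow
because the yield check compares f = α I₁ + √J₂ − k directly.

## Finite element solver

Linear (constant-strain) tetrahedra with one integration point — exact for
this element — and constant-strain triangular membranes for the shells
(in-plane stiffness only; at 0.2 mm thickness on millimetre-scale triangles
the neglected bending energy is third order in thickness). Voigt order is
(xx, yy, zz, xy, yz, zx) with engineering shears; units mm/MPa/N.

Post-yield behaviour is elastic–perfectly-plastic with associated flow —
the principal modelling assumption, since only the yield criterion is
prescribed by the validation protocol being reproduced. The return map is
closed-form: radial scaling of the deviator with a volumetric shift,
Δλ = f_trial/(G + 9Kα²), and projection to the cone apex for trial states
beyond it. Shells remain elastic in the nonlinear solve; the phantom
validation path never stresses the shell past its yield and implementing
membrane plasticity was not warranted (a recorded limitation).

Loading is displacement-controlled and rate-independent: the resin-box set
is fully fixed, the cap set shares a prescribed displacement along the load
axis (lateral components free) advanced in equal increments (default
0.1 mm × 20 steps). The load axis must be a signed coordinate axis — the
orientation step guarantees −z — which keeps constraints scalar; oblique
axes would need multipoint constraints and are not supported. Each step
starts with a tangent predictor (the constraint increment solved against
the tangent of the previously committed state), then full Newton iterations
with the consistent tangent of the return map, a backtracking line search
on the residual norm, and the elastic matrix as a late fallback;
convergence is relative residual ≤ 10⁻⁶ (of the reaction norm) within 25
iterations by default. The consistent tangent carries a 10⁻³ residual
stiffness in the plastic rank-one update (10⁻⁴·D at the apex) purely for
conditioning of the fully plastic system; the residual, and therefore the
converged solution, is exact EPP. A step that fails to converge terminates
the analysis with the partial curve flagged; failure at step 1 raises.

Verified oracles: the affine patch test to 10⁻⁸ for ν ∈ {0, 0.3, 0.45}; an
axis-aligned 10×10×100 mm bar with free lateral faces reproduces
EA/L = 1000 N/mm within 0.5%; the same bar with σ_c = 10 MPa and r = 1
plateaus at σ_y·A = 1000 N within 1%; the nonlinear solver with sentinel
yields matches the linear solve to 10⁻⁸; fixed- and driven-set reactions
balance; external work bounds stored energy once yield begins.

## Fracture metrics

The structural stiffness is the least-squares slope of force on
displacement restricted to samples with force between 20% and 80% of the
fracture load (the detected fracture load; for monotone curves it coincides
with the force maximum). Fracture is detected from tangent-stiffness loss:
a reference stiffness is fitted over the initial linear segment — grown
from three samples while the next forward tangent stays within 5% of the
running fit, with the tolerance widened to 3.5× a robust (MAD-based)
tangent-scatter estimate, capped at half the slope, so noisy but straight
recordings keep growing — and the fracture load is the force at the first
sample whose forward tangent falls below (1 − 0.2)× that reference. The
FE-curve detector uses the raw tangents (exact to one increment on clean
curves). The mechanical detector first applies a centred 5-sample moving
average (odd-reflection padding, which maps linear segments onto
themselves) and requires the decline to persist for a full window of
tangents — the quantitative reading of a slope that "rapidly decreases",
chosen identical in threshold to the FE rule so the two metric sets are
commensurable. With 1% force noise the detected load's median deviation is
under 2% with occasional few-increment outliers near the knee.

Statistics: regressions via `scipy.stats.linregress` (slope t-test, R²);
Mann–Whitney U with an exact tie-aware enumeration when both groups have
≤ 8 observations and the tie-corrected normal approximation otherwise;
Student's t and an OLS multiple regression of fracture load on age, sex and
side are also provided. The cohort report emits the five validation
analyses: load and stiffness mech-vs-FE regressions, load-vs-stiffness per
source, right-vs-left Mann–Whitney comparisons, and load-vs-age per source.

## Synthetic specimens

`make_phantom` voxelizes an analytic signed-distance geometry — bar,
cylinder, or femur-like (shaft cylinder + 20°-tilted neck cylinder +
spherical head; a parametric stand-in that exercises the cut, cap tagging
and stance loading, not an anatomical shape model) — at the CT defaults of
0.3 × 0.3 mm pixels and 0.5 mm slices. Partial volume is emulated by
averaging 8³ sub-samples per voxel (configurable; tests use 2–4 on coarser
grids, and 1 when exact interior HU is the point of the test); imaging
noise is additive Gaussian HU. Three rods sit in a slab beside the
specimen; the ground truth reports measurement ROIs inset 1.5 voxels from
the physical rods so rim partial-volume never dilutes the calibration.
Density is constant, or radial (linear in boundary distance over half the
smallest dimension), with an optional cortical rim of fixed thickness and
density. Everything is bit-reproducible under a fixed seed.

`make_curve` produces a bilinear force–displacement record: slope k to the
knee at the programmed fracture load, a configurable fraction of k beyond
it, plus seeded Gaussian force noise.

`make_cohort` draws paired left/right femora from cadavers with uniform
ages on [74, 101] years. Mechanical fracture load is
15856 − 142.6·age + L + ε_m and the FE prediction 17915 − 153.8·age + L +
ε_f, where L ~ N(0, 1141²) N is a latent specimen strength shared by the
two methods and ε are independent N(0, 844²) N; stiffness is load/2.684
(mech) or load/2.886 (FE) plus N(0, 517²) / N(0, 130²) N/mm noise. The
slopes, intercepts and divisors are published cohort lines and mean ratios;
the latent/noise split was solved once from the reported load SDs
(1802/1879 N) and the mech-vs-FE R² (0.62) under the uniform-age
approximation, so synthetic validation reports land in a realistic numeric
range. These are generator configuration, not biological truth. Loads are
not clipped at zero (clipping would bias age-slope recovery); when curves
are requested the programmed knee is floored at 100 N.

## What the synthetic validation shows — and does not

Passing tests demonstrate that the pipeline's mechanics are correct:
calibration recovers a generator's line exactly, meshes converge to
analytic volumes, the FE solution matches closed-form oracles, detectors
recover programmed knees, and the cohort statistics recover generator
parameters with correct confidence-interval coverage. They do not
demonstrate predictive accuracy on real femora: the phantoms have simple
geometry and noise structure, no anatomical shape variation, no
scanner-physics artifacts, and the cohort generator assumes the very linear
model the report then fits. Reproducing a cadaveric validation (its R²
values, mean loads, laterality table) requires the original CT scans and
test curves, which are not distributed.

## Problem sizes

The test suite and acceptance script run deliberately scaled-down
configurations chosen as the smallest that still exercise every code path:
bars of 4–7 k tets at 3 mm edges for the solver oracles, a 16–20 mm bar
phantom at 0.3–0.5 mm voxels for end-to-end recovery, a femur-like phantom
at 1.5 mm voxels and 5 mm elements for the stance integration test, and
20-specimen cohorts with 50–100 seeded replicates for the statistical
calibration checks.
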