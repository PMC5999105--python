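# Methods

## Problem setting

Intraoperative registration aligns a dense preoperative bone surface
(the pre-operative model, POM — here a triangulated mesh in mm) with a
sparse set of surface sample points (SSP) measured on the patient. Two
factors dominate the achievable accuracy: the number of sample points
(each costs acquisition time) and the per-point localization error
(UPLE). This package implements the ICP-PS registration procedure and a
Monte-Carlo framework that maps accuracy as a function of both factors.

## Registration procedure

**Pre-registration.** The first six SSP carry area labels, two per
pre-registration area (greater trochanter, medial epicondyle, lateral
epicondyle). Each labeled point is paired with the centroid of its
area's vertices and the closed-form rigid least-squares fit (SVD of the
3×3 cross-covariance, Kabsch) aligns them. The reported objective keeps
the 1/n scaling; the minimizer is unaffected by it. If the optimal
orthogonal matrix is a reflection, the singular vector of the smallest
singular value is sign-flipped, so the result is always a proper
rotation. Degenerate inputs (n < 3, collinear sources, length
mismatches) raise typed errors rather than returning garbage.

**ICP.** Per iteration, closest model points of the current pose define
correspondences and the closed-form fit updates the pose; the loop stops
at 30 iterations or when the PSD improves by less than 1e−6 mm² (the
inner tolerance is a package choice; it terminates the alternation well
after changes become irrelevant at the 1e−5 mm² feedback tolerance).
Because each half-step minimizes the same objective, the recorded PSD
sequence is non-increasing.

Closest-point queries default to **vertex mode** (nearest mesh vertex by
k-d tree), the appropriate choice for a dense model where the vertex
spacing (~1 mm) is below the error scale of interest. An exact
**triangle mode** (point-to-triangle projection, accelerated by a k-d
tree over face centroids with a reach bound that keeps it exact) is
provided for coarse meshes, where vertex-mode distances are biased
upward. Both modes are available everywhere a PSD is computed; a run
uses one mode consistently.

**Perturbation search.** The escape move for the axial local minima of
a cylinder-like bone: candidates are rotations about and translations
along the distal–proximal axis, enumerated inclusively over
−5°…5° × 1° and −3…3 mm × 0.5 mm (143 candidates), rotation-major. The
axis is the first principal component of the vertex cloud with a fixed
sign convention (non-negative z, ties toward +x then +y), and the
rotation center is the vertex centroid — a reproducible, geometrically
natural choice. Every candidate is applied to the current registered
pose and scored by PSD; ties break toward the smallest perturbation
magnitude (so the identity wins when nothing improves), then enumeration
order. The PSD is the mean *squared* distance; the argmin is the same
under root-mean-square, and traces log the RMS in mm for readability.

**Feedback.** If the best perturbation strictly lowers the PSD, ICP
restarts from the perturbed pose; the loop repeats (full grid each
round) until the round-to-round PSD improvement is below 1e−5 mm², with
at most 5 rounds. The convergence test is on the *improvement*
(PSD_n − PSD_{n+1}), which is non-negative by construction. The final
PSD therefore never exceeds the PSD after the first ICP pass, and
running with the perturbation disabled reproduces the plain-ICP
baseline exactly.

## Accuracy metric

The bone-to-bone RMSE composes the estimated registration with the true
displacement and takes the root-mean-square displacement this residual
induces over all model vertices. It is zero iff the residual is the
identity (non-degenerate mesh), equals a pure translation's norm
exactly, and weighs rotational error by the bone's actual mass
distribution — unlike a fiducial-only error it cannot hide a pivot
about the sample points.

## Synthetic anatomy

No CT-derived model ships with the package, so all experiments run on a
procedural femur-like mesh. The surface is a radial function r(θ, z)
about the long axis — a shaft cylinder unioned with bump spheres for
the offset head, greater trochanter and two condyles, each star-shaped
about the axis — sampled on a (z, θ) grid and closed with end caps,
which guarantees a watertight, consistently wound mesh. Defaults:
shaft 400 mm × radius 15 mm, head radius 24 mm offset 25 mm medially,
~1 vertex/mm² (≈38k vertices, the density of a typical segmented CT
model), seeded and bitwise reproducible.

Two deliberate departures from an ideal cylinder matter:

* a smooth low-order radial roughness field (RMS 0.3 mm) breaks exact
  rotational symmetry, as a real bone does;
* per-vertex jitter of the (θ, z) sampling (35% of the grid spacing)
  makes the vertex distribution irregular. A perfectly regular grid
  creates artificial "lattice" local minima in *every* direction, which
  no segmented CT mesh exhibits; with jitter the surviving local-minimum
  family is the axial one caused by the bone's true near-symmetry — the
  regime the perturbation search is designed for, and the regime the
  tests verify (midshaft-only points offset +3 mm axially leave plain
  ICP ≥ 1 mm off in most trials).

Labels emulate an ultrasound accessibility map: the posterior shaft
sector (±50° about −y over the mid 76% of the shaft) and the articular
surfaces (head sphere, distal 8 mm) are inaccessible; pre-registration
disks (30 mm diameter at the trochanter, 20 mm at each epicondyle,
Euclidean chord radius) are carved from the accessible set around
anchor vertices chosen at the anatomical extremes; four 20 mm midshaft
disks are labeled for optional sampling protocols. The
accessible/inaccessible boundary of a real protocol is approximate and
pictorial; here it is an explicit parameterized surrogate.

What the synthetic model does **not** emulate: real cortical shape
detail, segmentation artifacts, anisotropic ultrasound error, and the
specific geometry of any individual femur. Absolute RMSE values obtained
here therefore characterize the method under controlled conditions, not
any particular clinical dataset; trends (accuracy vs. point count,
vs. noise, ICP-PS vs. ICP) are the transferable results.

## Simulation design

Each trial: draw GT-SSP (two random vertices per pre-registration area,
the rest uniform over accessible vertices — vertices, not arbitrary
surface points, matching vertex-mode scoring on a dense mesh), displace
by a random rigid transform, add noise, register, and re-score the
intermediate transforms from the trace to get the RMSE after steps 2, 3
and 4 without re-running.

* **Displacement**: rotation axis and translation direction uniform on
  the sphere; angle ≤ 10°, translation ≤ 20 mm (uniform magnitudes).
  The magnitude of the "arbitrary new location" is inherently a
  protocol choice: it must lie within the capture range of the six-point
  pre-registration while leaving it a non-trivial task. Both bounds are
  configurable.
* **UPLE noise**: direction uniform on the unit sphere (normalized
  Gaussian), magnitude uniform on [a, b]; intervals 0, [0–1] and
  [1–2] mm by default; the drawn magnitude is stored per point.
* **Design**: point counts 6…25 × three intervals × repeats; at 100
  repeats this enumerates 6000 trials. All points are re-drawn each
  repeat. Trial seeds come from `SeedSequence(master_seed, spawn_key=
  (method, n_points, interval, repeat))`, so extending any factor list
  never changes existing trials and every number in the table is
  replayable from the master seed.
* **Incremental evaluation**: a repeated-measurements protocol on
  simulated data — 25 sites (6 pre-registration + 19 accessible), 10
  noisy measurements each, keep the per-site minimum ("closest") or
  maximum ("farthest") error measurement, sort the non-pre-registration
  sites by descending error and register cumulatively from 6 to 25
  points with both methods. The stored noise magnitude stands in for a
  measured point-to-bone distance, which would require a physical
  ground-truth apparatus.

Tests and the acceptance checks run scaled-down designs (typically 20
repeats, or 100 single trials for monotonicity properties) — sizes
chosen to make the Monte-Carlo trends stable while keeping the suite
quick to run; the full 6000-trial design runs through
`icpps simulate` or `run_experiment` unchanged.

## Numerical choices and edge cases

* Angles are degrees at every API surface, radians internally; all
  lengths mm.
* Orthonormality/determinant of rotations validated at 1e−6 on
  construction; composition/inversion closure holds to 1e−9.
* STL I/O supports binary and ASCII; binary files are structurally
  validated first so truncation yields a parse error with a byte
  offset. The facet soup is merged by exact coordinate match; because a
  reader necessarily rebuilds the vertex list in its own order, region
  labels written next to an STL are remapped to the written file's
  reconstructed ordering (verified by re-reading), keeping the sidecar
  self-consistent at STL (float32) precision.
* Grid enumeration includes both endpoints; non-exact-multiple ranges
  append the upper endpoint.
* Empty point sets, missing labels/regions, invalid intervals and
  degenerate meshes raise typed errors from a single hierarchy; the CLI
  maps them to categorized messages with exit code 1 (usage errors: 2).

## Known limitations

* Vertex-mode PSD is lower-bounded by the mesh sampling; on meshes much
  coarser than ~1 vertex/mm² use triangle mode.
* The perturbation grid only searches one axis; shapes with additional
  near-symmetries (or poorly covered directions) would need a different
  candidate set.
* RMSE is not monotone across stages — only the PSD is; a perturbation
  accepted on PSD can occasionally move the pose slightly away from the
  hidden truth, although on average it improves it markedly.
* The isotropic noise model collapses calibration, speed-of-sound and
  tracking errors into one magnitude; anisotropic or spatially
  correlated error is out of scope.
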