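# Methods

This note documents the models implemented in `molscene`, the numerical
choices behind them, and what the synthetic test fixtures do and do not
show about real molecular data.

## Rigid transforms and screw motions

A pose is a proper rigid motion `p' = R p + t` with `R ∈ SO(3)` stored as a
matrix and `t` in Ångströms (PDB-native units).  Composition applies the
right factor first (`(T1·T2) p = T1 (T2 p)`), so placing a copy "in A's
local frame" reads left-to-right: `T_B = T_A · T_AB`.  Constructors
validate orthonormality and `det = +1`; drift between 1e-9 and 1e-7
(accumulated round-off from long composition chains) is re-projected onto
SO(3) by SVD, and anything worse is rejected as invalid.  `transform_power`
uses square-and-multiply so 50-copy chains keep errors near machine
precision.

Every rigid motion is a screw: rotation by `angle` about an axis through
`axis_point` along unit `axis_direction`, plus a signed `rise` along the
axis.  Decomposition takes the rotation's axis-angle, projects the
translation onto the axis for the rise, and solves `(I − R) p = t⊥` by
least squares for the axis point (constrained to `p ⟂ u`, making it the
point on the axis nearest the origin).  Conventions: the angle is reported
in `[0, π]` with the axis direction absorbing the sign; a pure translation
reports angle 0 with the axis along the translation through the origin; for
a half-turn (where the axis sign is otherwise ambiguous) the first non-zero
axis component is made positive.  Round-trip reconstruction is tested to
1e-7.

Shadow projection models a light infinitely far away along the "up"
direction: points are projected along `up` onto the plane
`p·up = ground_height`.  The along-up component is *replaced* rather than
corrected, which makes the operation exactly idempotent whenever `up` is
exactly representable (e.g. axis-aligned).

## Meshes, surfaces, and bounding boxes

Meshes are indexed triangle lists with validated faces (no out-of-range or
repeated indices); all fixtures are wound counter-clockwise so face normals
point outward — the collision response relies on this.

The molecular surface generator is a **Gaussian-density isosurface**, a
deliberately simplified stand-in for the solvent-excluded (Connolly)
surface: density `Σ_i exp(−(‖p − c_i‖² − R_i²)/σ²)` with
`R_i = vdW_i + probe` is sampled on a regular grid and triangulated by
marching cubes at level 1.  For a single atom the level-1 surface sits
exactly at radius `R_i`; clusters blend smoothly.  Defaults: probe 1.4 Å
(water), grid 0.5 Å, blend width σ = 1.2 Å.  It reproduces the topology and
approximate geometry of a probe-rolled surface (merging of nearby atoms,
separation of distant ones, watertightness) but not its exact re-entrant
geometry; tests that need a true SES do not exist in this package by
design.

Oriented bounding boxes come from vertex-covariance PCA (eigenvectors in
descending-eigenvalue order, ties broken by axis index, deterministic axis
signs, handedness fixed on the last axis), with extents from the projection
range.  This is the common fast construction, not the minimum-volume box;
the invariant `OBB volume ≥ convex hull volume` is what downstream code
relies on.

OBJ I/O implements the minimal dialect the package writes: `v x y z` and
`f i j k` (1-based), nine significant digits, other tags ignored on read,
parse errors naming the offending line.  PDB input goes through biotite
with the dialect rules applied on top: first model only, alternate
locations other than `' '`/`'A'` dropped, chain termini = first/last
alpha-carbon per chain in record order.

Fixture meshes are icosphere-based (via trimesh): spheres, scaled
ellipsoids, and "blobs" — ellipsoids perturbed by a few seeded
low-frequency plane waves (amplitude 0.15 of radius), keeping them smooth,
star-shaped, and within 30 % of the generating ellipsoid's volume.  They
stand in for globular protein surfaces: convex-ish, closed, moderately
anisotropic.  They do **not** emulate deep clefts, tunnels, or the
thousands-of-triangle meshes of real surfaces, so passing collision tests
demonstrate algorithmic correctness, not large-mesh performance.

## Collision detection

The triangle–triangle predicate is a full separating-axis test over 17
candidate axes (both normals, the 9 edge×edge cross products, and the 6
in-plane edge normals, which close the coplanar case).  Separation must
exceed 1e-9 to count, so touching contact is classified as colliding — ties
resolve toward "colliding" throughout.  The test is vectorized over
candidate pairs.

Each mesh gets an axis-aligned box tree built once in its local frame
(median split on the longest axis, leaves ≤ 4 triangles) and cached on the
mesh.  At query time node boxes are re-bounded under the pose (transform
the 8 corners, take min/max — conservative).  Pair traversal descends the
larger node; leaf–leaf candidates are tested in one vectorized batch.  An
exhaustive all-pairs reference (`brute_force_pair`) exists alongside for
oracle comparisons.

`tests_performed` counts object-pair BVH queries, not triangle tests.  For
scene queries with moving set `M`, only pairs meeting `M` are tested
(≤ m·n).  For chain-internal queries, copy 1 is tested against copies
2…n (exactly n−1 queries); a hit at offset k implies hits `(i, i+k)` for
all i, reported with the representative pair's contact list re-used — the
relative pose being identical, the contact topology is too.  Chain-internal
reports can therefore list more colliding pairs than tests performed; that
surplus is precisely the saved work, and the pairwise invariant
`tests ≥ pairs` is enforced only for scene queries.

## Pose-mode physics

The integrator is a pose controller, not a dynamics simulation: unit mass
and inertia for every object, semi-implicit Euler with per-step velocity
retention (`v ← γ v + dt·F`, `x ← x + dt·v`, likewise for the angular
channel with an exponential-map rotation update re-projected onto SO(3)).

Wrenches on a manipulated object: tracker pull
`F = k_t (x_target − x)`, `τ = k_r · axisangle(R_target R⁻¹)`, plus a
penalty `response_gain` along the unit normal of the *other* body's contact
triangle for every contact, applied at the contact-pair midpoint (torque =
offset × force).  Non-manipulated objects are never written to — their
poses are bitwise unchanged across any step sequence, which is the defining
contract.  Collision queries route through the filtered scene query with
the manipulated set as movers.

Defaults (all overridable): `k_translate = 1 /Å`, `k_rotate = 1 /rad`,
`damping γ = 0.5`, `response_gain = 10` per contact, `dt = 0.05`,
`penetration_tolerance = 0.1 Å`, `max_iterations = 2000`, convergence when
the combined wrench norm drops below 1e-4.  These were chosen for stability
margin: with γ = 0.5 the free-placement error contracts by ≈ dt²k/(1−γ)
per step, reaching ~2×10⁻⁴ Å within the iteration cap, and the
per-step travel near contact stays an order of magnitude below the
penetration tolerance.  Penalty contact produces a small bounded
oscillation (contact on/off) rather than a fixed point; the guarantee kept
is that penetration never exceeds the tolerance, not that the contact state
is static.

Penetration is measured per contact as the deeper triangle's worst vertex
behind the other triangle's plane (the minimum of the two one-sided
depths); it is a diagnostic approximation, not a minimum translation
distance.

The rejected first design is retained as `settle_reject_mode`: integrate
the tracker wrench alone and apply the candidate pose only if collision
free.  A rejected candidate also zeroes the accumulated velocity —
otherwise velocity would build up until a candidate jumped clear through
the obstacle, which would mask the sticking behaviour this mode exists to
demonstrate.  Whether the original interactive system applied contact
torque as well as force is not specified anywhere authoritative; this
implementation applies both (torque from contact offset × force) as its own
choice.

## Spring connectors and layout

Springs are linear (Hookean) with rest length `L0 ≥ 0`; stiffness defaults
to 1 and "fixed-length" behaviour is approximated by stiffening (×100)
rather than by a rigid constraint, keeping a single solver.  Exactly
coincident endpoints with `L0 > 0` have no defined force direction; a fixed
+x nudge is applied for one step to break the tie deterministically.
Attachment points are object-local, so terminus snapping simply copies the
chain's terminal CA coordinate into the connector end.

`relax_layout` marks every object touched by a force-mode spring as
manipulated (others stay fixed unless explicitly freed), applies the summed
spring wrenches with no tracker targets, and settles with collision
response active.  Internal forces sum to zero exactly (Newton's third law
by construction), spring energy is non-increasing once contact-free, and
infeasible networks converge to a force-balance local optimum whose
per-connector residuals are reported rather than raising an error — e.g.
two equal-stiffness springs of rest lengths 2 and 8 between the same pair
settle at separation 5.

## Animation

Positions interpolate with a centripetal Catmull-Rom spline (Barry-Goldman
evaluation, endpoint duplication at the boundaries, exact linear
degeneration for two keyframes); orientation uses piecewise slerp with
shortest-arc sign handling; colors lerp in linear RGB, while symbolic
data-coloring labels (e.g. "charge") switch at keyframes without
interpolation, as do group membership and visibility.  Sampling at a
keyframe time returns that keyframe's state exactly (compared by identity,
not via the spline).  Smoother-than-C1 orientation interpolation across
three or more keyframes (squad) is a noted possible upgrade, not
implemented.  Frame export samples `t0 + k/fps` for
`k = 0 … floor((t1−t0)·fps)` (an epsilon of 1e-9 guards the floor against
representation error) into renderer-neutral JSON records with row-major
4×4 matrices.

## Scene documents

The JSON scene format is versioned and strict: unknown keys are rejected by
name, all id references are resolved and dangling ones collected into a
single validation error, meshes are stored as reproducible fixture specs or
OBJ paths relative to the document, and poses are row-major 4×4 matrices.
Duplication and group import always mint fresh ids (never overwrite), and a
group fragment is itself a complete valid document.

## Problem sizes and determinism

Randomized suites use fixed seeds recorded in the tests.  Collision oracle
comparisons run on scenes of up to 10 objects with meshes of 80–320
triangles — sizes at which the exhaustive all-triangle-pairs oracle is
itself fast and exact, chosen as the package's verification scale;
correctness of the BVH path is representation-independent and does not
change with mesh size.  Physics and spring fixtures use the default
parameter set above; every example and the acceptance script are
deterministic given `--seed`.

## Known limitations

* The Gaussian isosurface is not a true solvent-excluded surface; re-entrant
  geometry is smoothed.
* Pose-mode physics has no momentum transfer between objects and no
  molecular dynamics; it is a placement tool.
* Penetration depth is an approximate diagnostic.
* Contact oscillation means wall-contact runs end by iteration cap, not by
  wrench convergence; the penetration bound is what is guaranteed.
* Degenerate (zero-area) triangles are not handled by the separating-axis
  predicate; mesh validation upstream excludes them.
* mmCIF, surface coloring data, and renderer project export are out of
  scope.
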