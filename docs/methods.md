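# Methods

`kneefem` rebuilds a subject-specific mouse-knee contact workflow as a
tested pipeline: micro-CT-like volumes are segmented into bone, cartilage
and meniscus masks, the masks are meshed into a conforming multi-region
tetrahedral model, and a displacement-controlled linear-elastic solve with
frictionless penalty contact yields per-condyle cartilage contact-pressure
statistics for four model variants of decreasing geometric fidelity.  This
note records the model, its assumptions, the numerical choices, and what
the synthetic data can and cannot tell you about real scans.

## The imaging workflow being emulated

The real workflow images a dissected mouse knee twice: once intact in the
rest position (bone and the calcified menisci are bright, cartilage is
invisible), and once with femur and tibia separated and stained so the
cartilage shells become visible at intermediate intensity.  Each stained
bone is mapped back into the rest frame by landmark rigid registration, the
cartilage is segmented and the bone is subtracted, and the soft meniscus —
invisible in both scans — is reconstructed by filling the gap between the
calcified menisci and the cartilage surfaces.

The package substitutes two steps that are manual in the original
workflow:

* cartilage contouring is replaced by threshold segmentation followed by
  Boolean subtraction of the (one-voxel-dilated) bone masks — valid on the
  phantom, where the stained-cartilage contrast is controlled;
* hand-editing of the meniscus wrap is replaced by two rules: wrap
  components not connected to the calcified meniscus are discarded, and
  the wrap is trimmed a configurable clearance (default two voxels) below
  the femoral cartilage so the joint space is not welded shut, then
  regularised by mask smoothing (its raw surface is rough at the voxel
  scale).

## The synthetic knee phantom

The phantom (`kneefem.synthetic.PhantomSpec`) is an analytic mouse-scale
geometry evaluated on a voxel grid, with every tissue mask, landmark pair
and separation transform known exactly.  Superior is +z, lateral is +x.

* **Femur**: two spherical condyles (lateral radius 0.55 mm, medial
  0.50 mm, centres 1.25 mm apart), truncated superiorly and capped by a
  rectangular shaft plate with a flat top (the coupled loading surface).
  Femoral cartilage is a uniform 0.10 mm shell over the inferior cap of
  each condyle.
* **Tibia**: a plateau slab (2.5 x 1.2 x 0.32 mm) with a shallow spherical
  pocket (radius 0.9 mm) under each condyle.  The ground-truth tibial
  cartilage fills each pocket up to a spherical surface *concentric with
  its condyle*, leaving a small rest clearance between the cartilage
  surfaces (lateral 18 um, medial 20 um): the individual joint surfaces
  are nearly conforming, as articular surfaces are.
* **Subchondral prominence**: the pocket centres are shifted 0.138 mm in
  +y off the condylar axes.  At the prominence the bone-to-bone gap
  narrows to ~0.15 mm laterally — *less* than the 0.2 mm cartilage stack.
  This is the geometric feature that separates the model variants:
  homogeneous cartilage layers sized from the minimal bone gap come out
  thin (75 um) and touch only at the prominence, while the individual
  cartilage fills the true conforming geometry.  The medial pocket is
  60 um deeper (thicker medial cartilage), so a single-thickness layer
  sized on the lateral gap cannot restore medial contact.
* **Menisci**: calcified meniscus arcs (torus segments, tube radius
  40 um, spanning 200 degrees) float in the peripheral joint space above a
  thin flat cartilage annulus; the wrap reconstructs the soft meniscus
  around them.  The calcifications are part of the meniscus structure and
  take the meniscus material property.
* **Scans**: rest scan (bone + calcified menisci bright) and two stained
  scans (each bone + its cartilage, rigidly displaced by stored
  transforms, cartilage at intermediate intensity), all with seeded
  additive Gaussian noise (default SD 5 on a 20/90/180 intensity scale).
  Beam-hardening and ring artifacts of real reconstructions are *not*
  simulated; the reconstruction corrections that would remove them are out
  of scope.
* **Spacing**: default 17.4 um = 4 x the 4.35 um acquisition voxel of the
  workflow being emulated, chosen so the 87 um femur lift is an exact
  5-voxel shift; the spec carries spacing explicitly and finer grids are
  available at proportional cost.

What passing tests on the phantom do **not** show: robustness to
uncontrolled stain contrast (real cartilage segmentation was manual for a
reason), to reconstruction artifacts, to landmark identification error
(phantom landmarks are exact by construction; the noise study quantifies
sensitivity separately), or to anatomy outside the two-condyle idealisation
(no trochlea, cruciate region, or growth plate).

## Geometry operators

Gaussian smoothing (sigma = 1 voxel) and single-level thresholding follow
the emulated bone workflow; the automatic level is Otsu's criterion with a
bimodality check.  Mask smoothing is indicator-blur-rethreshold (Gaussian
sigma = radius/2, threshold 0.5) with the 2-voxel default radius.  The
meniscus wrap is a morphological closing of calcified-meniscus + cartilage
with a ball of radius `max_gap/2` (default `max_gap` 150 um), minus the
inputs, with the connectivity and clearance rules above.  Homogeneous
cartilage is a constant-distance offset shell of each bone's articular
region computed from Euclidean distance transforms; the per-layer thickness
is half the minimal bone-to-bone gap of the governing condyle, so the two
layers just touch there.  The femur lift before meshing is the 87 um gap
translation rounded to whole voxels (exactly 5 at the default spacing); the
contact-initialisation displacement closes exactly the lifted amount.

## Registration

Rigid fits are closed-form orthogonal Procrustes (Kabsch) with a
sign-corrected SVD so reflections are impossible; correspondences come from
landmark ids, so no iterative matching is needed.  The two-step procedure
fits 3 coarse markers, maps the full landmark set through the coarse
transform, and refines with all (>= 15) landmarks.  Resampling is trilinear
with the background intensity mode as fill.  The reported RMS residual is
per coordinate (`sqrt(SSE / 3n)`), which for isotropic landmark noise of
standard deviation sigma estimates sigma itself.

## Meshing

Voxels become tetrahedra by the six-tet Kuhn subdivision (all six tets
share the cube's main diagonal); with one diagonal orientation everywhere,
neighbouring cubes tile face-to-face, so multi-material interfaces conform
by construction and per-tissue volume equals the mask volume to floating
point.  Coarsening toward a target edge length is block-majority
downsampling of the label grid; all tissues share one grid (the finest,
soft-tissue target) because conforming interfaces between differently
coarsened tissues would need transition meshing.  Desk-scale default:
52.2 um cells (3 voxels), ~10^5 tets per variant.

Voxel surfaces are staircased; four Taubin smoothing passes
(lambda = 0.5, mu = -0.53) over the exterior boundary nodes turn the
staircase into a continuous piecewise-linear surface with little volume
change.  The flat support bands (distal tibia, femur top) are pinned, and
node moves that would invert a tet are bisected back.  Smoothing matters
for contact: the vertical-ray gap on a raw staircase is discontinuous at
every tread edge.

Named sets follow geometric rules: `tibia_distal_fixed` is the tibia-bone
nodes within 2 mesh cells of the minimal tibia z (the unspecified "most
distal portion" is this configurable band), `femur_top_coupled` the femur
nodes within 1 cell of the maximal z, and the articular facet sets are the
exterior faces of each cartilage (and the superior meniscus faces) filtered
by outward-normal direction.

## The contact solver

Small-strain linear elasticity on constant-strain tetrahedra (exact for
affine fields — the patch test holds to machine precision), mm/N/MPa
units.  Tissue properties: cartilage E = 6 MPa, nu = 0.49; meniscus
E = 59 MPa, nu = 0.49 (the whole structure - the calcified portions are
anatomical features of the meniscus body and take its property); bone
E = 18000 MPa, nu = 0.3.  Near-incompressible linear tets lock volumetrically; that
stiffening is shared with the workflow being reproduced and is accepted.

Constraints are handled by master-slave elimination (`u = T q + g`):
Dirichlet supports, tied interfaces (slave node = barycentric blend of its
master facet, a multipoint constraint), and kinematic translation coupling
of the femur top to a reference point.  The reference point's transverse
translations are fixed at zero and its axial translation is prescribed;
rotational coupling is not modelled.  With the bodies positioned by a
displacement protocol this makes every step well-posed even before contact
closes.  The axial reaction is the sum of constraint residuals over the
coupled nodes, taken along the loading direction.

Contact is frictionless node-to-surface penalty:

* **Gap**: each slave node pairs with the master facet pierced by its ray
  along the loading axis ("ray" mode, the default).  On piecewise-linear
  surfaces this gives a unique, stable pairing and a gap that is continuous
  in the displacement, where closest-point projection flickers between
  facets.  Facets nearly parallel to the ray are excluded using *reference*
  normals so the admissible set never changes with deformation.  A
  closest-point mode remains available.
* **Normal**: Phong (barycentric vertex-averaged) normals make the force
  direction continuous across facet edges.
* **Penalty**: pressure = k_p x penetration with
  `k_p = 50 E_soft / h` per unit tributary area, where `E_soft` is the
  softer of the two contacting tissues and `h` the mean slave facet edge.
  Scaling by the softer side keeps pairs like stiff-meniscus-on-soft-
  cartilage well conditioned.  A x10 penalty robustness check is part of
  the test suite.
* **Solution scheme**: at each load step, an outer loop re-evaluates the
  pairing at the current displacement (finite sliding) and freezes it; the
  frozen problem — quadratic elastic energy plus one-sided quadratic
  penalty — is convex and is solved *exactly* by a semismooth-Newton inner
  loop with a backtracking energy line search.  Convergence is declared on
  the true force residual of the free DOFs (2-norm, relative 1e-3).  A few
  slave nodes can sit on folds of the surfaces where re-pairing is
  genuinely discontinuous; after 5 outer updates the pairing is frozen for
  the rest of the step (the step then closes on one well-posed convex
  problem), and a small re-pairing noise floor (3%) is also accepted if
  the residual has clearly stagnated there.  The achieved relative
  residual is stored on every step.
* **Linear algebra**: the reduced elastic matrix is factored once per
  model (SuperLU); each penalty system is solved through the Woodbury
  identity, with the `K^-1 w` back-solves cached per contact constraint
  and refreshed only when the constraint vector drifts; iterative
  refinement against the exact model residual absorbs the cache
  approximation, with a direct factorisation as last resort.

The loading protocol is the emulated one: the femur is lifted 87 um at
geometry build, driven back 87 um to initialise contact, then loaded 30 um
in four equal steps; analysis selects the loading step whose axial
reaction is closest to 0.3 N (ties to the earlier step).

## Pressure statistics

Contact pressure lives on the slave nodes (penalty force / tributary
area).  Nodes are split medial/lateral by the sagittal plane through the
centroid of the femoral articular surface, normal along the medio-lateral
axis (configurable).  Per condyle, the mean and peak pressures are taken
over the cartilage-on-cartilage interface (the pressure *between the
femoral and tibial cartilage layers*), while the contact area and the
frequency histogram cover every loaded interface including the meniscus
(the femoral-surface map view); a per-master-surface aggregate is also
stored on each solution step.  The peak excludes isolated points: a node
qualifies only if at least 3 other contacting nodes lie within 3x the
median inter-node spacing (the concrete form of an exclusion rule the
emulated workflow leaves unspecified; both knobs are configuration), with
a fallback to the raw maximum when no node qualifies.  Histograms use
0.2 MPa bins from 0.2 MPa, with below-range contacting nodes collected in
a leading bin so counts always sum to the number of contacting nodes;
contact area is the summed tributary area of contacting nodes.  Percent
differences are quoted against the single-thickness model laterally and
the two-thickness model medially (the single-thickness model has no medial
contact to reference).

## Problem sizes and determinism

Desk-scale defaults: phantom grid ~1.2M voxels at 17.4 um, meshes of
~100-150k tets (~60-75k free DOFs), four variants solved in roughly 7-8
minutes on one CPU.  The emulated workflow's own 5 um soft-tissue meshing
target implies multi-million-element models and many-hour solves; those
targets remain reachable through the configuration but are not the
defaults.  All randomness flows from one seed (phantom noise); identical
seeds give bit-identical volumes and byte-identical summary tables.

## Known limitations

* Linear small-strain kinematics with per-step pairing updates: loading
  displacements (up to 117 um) are small against bone but not against
  cartilage thickness; no poroelasticity or viscoelasticity, no
  fibre-reinforced meniscus, no ligaments, displacement control only.
* Node-to-surface penalty approximates a surface-to-surface formulation;
  pressures carry discretisation noise at the contact rim, which the
  isolated-point rule addresses at the statistics level.
* Voxel geometry: surfaces are accurate to ~half a mesh cell even after
  smoothing; with 52 um cells the rest clearances (18-20 um) are partly
  sub-resolution, so contact engagement is gradual rather than sharp.
* The bonded meniscus-tibia interface arises from mesh conformity (shared
  nodes) in the standard pipeline; the explicit tied-interface constraint
  is exercised on separately meshed bodies.
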