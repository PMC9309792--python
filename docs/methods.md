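# Methods

This note documents the model, its assumptions, the parameters that
matter, and the design choices made where the design was genuinely open.

## Frames, units, conventions

Right-handed model frame: +X anterior, +Y superior, +Z subject-left;
gravity is (0, −9.81, 0) m/s². Geometry is in world millimetres (0-based
voxel indices through the NIfTI affine); forces in N, moments in N·m,
masses in kg. Moments about X are frontal-plane (lateral bending), about Z
sagittal; extension is positive about +Z, so flexion postures carry
negative sagittal rotations. All landmark math happens after the
craniocaudal realignment that maps the T1–L5 centroid line onto +Y.

## Synthetic spine generator

The generator emulates the output of a segmentation pipeline, not a CT
scanner. Each vertebra is an elliptic-cylinder body (44 mm wide, 24 mm
tall by default, split into a 3 mm cortical shell and a trabecular core)
with a posterior arch containing a canal opening, a spinous process and
two transverse processes — the simplest shape family that exposes every
subregion the landmark extractor probes. The sacrum is a plain taller
block acting as the ground side. Curvature is imposed by rotating and
translating successive vertebrae along circular arcs: the sagittal tilt
ramps by the requested lordosis over sacrum→L1 and by the kyphosis over
T12→T1; the frontal tilt ramps by the Cobb angle across the thoracic
levels. Because the alignment metrics are defined on boundary-vertebra
endplates, the requested angles are analytically recoverable; the
round-trip through voxelization and extraction agrees within about 1° at
the default 2 mm isotropic voxel (tolerance 3° in the tests covers coarse
grids).

The tissue volume is an elliptic torso cylinder around the spine: an
outer shell whose cross-sectional area fraction equals the requested fat
fraction carries fat intensities, two thoracic ellipsoids carry lung
intensities, the rest is soft tissue. Intensities sit mid-window (−750,
−100, +40 HU); air is at the scanner floor (−1024 HU) so it falls below
the lung window. Optional Gaussian intensity jitter exists but is off by
default — classifier tests need clean separability first. What this
fixture does *not* emulate: cortical/trabecular texture, CT artifacts,
realistic organ anatomy, inter-vertebra shape variation. Passing tests
demonstrate the mechanics and bookkeeping of the pipeline, not
segmentation robustness on real scans.

## Landmark extraction

Per-subregion landmarks are coordinate extremes (most
posterior/superior/inferior/lateral surface points), with ties broken
toward the subregion centroid. Vertebral-body rim points come from an
axis-aligned rectangle fitted to the sagittal midplane cross-section in
realigned coordinates; its corner and edge-centre points are projected to
the nearest body-surface voxel. Arch attachment points minimize the
distance between the arch's anterior border and posterior body surface in
a central sagittal slab and two slabs shifted ±12 mm.

**Endplate centres** (a definition the input data does not supply): each
endplate is treated as a near-planar cap of the body voxel cloud. Starting
from the centroid-chain tangent as an axis hint, a ~2-voxel slab is cut at
the extreme of the projection and the cap's plane normal re-estimated as
the slab's minimum-variance principal axis; three passes converge to
sub-degree normals. The vertebra's measured superior axis is the mean of
the two cap normals. A plain PCA of the whole body was rejected: the
eigenvalue gap between the craniocaudal and anterior-posterior axes of a
squat cylinder is small, and voxelization noise tilts the eigenvector by
several degrees — enough to corrupt the alignment metrics.

Joint centres are the midpoints of facing endplate centres; joint
orientation comes from a natural cubic spline through all centroids
(chord-length parameterized), its tangent evaluated at the parameter
closest to the inferior vertebra's superior endplate centre. The anterior
axis is the tangent's in-sagittal-plane normal; lateral completes the
right-handed frame.

## Tissue masses

HU windows default to lung [−1000, −500), fat [−200, −20), soft
[−20, 150) — configurable, pairwise disjoint, with instance-mask voxels
excluded. Each classified voxel is assigned to the vertebra with the
nearest centroid along the craniocaudal axis, slicing the torso into
contiguous axial slabs; this is the partition the per-level segment
pictures imply, and it is the one deliberate reinterpretation in the
pipeline (a literal anterior–posterior distance would interleave levels
unphysically). Densities: lung 0.25, fat 0.96, soft 1.06, bone
1.5 g/cm³. Generic head–neck and arm masses use Winter-style fractions
(8.1 % and 5.0 % of body mass) with body mass inferred from the
CT-derived torso mass through the trunk fraction (49.7 %); generic
geometry scales linearly with stature against a 1.75 m reference.

## Ligaments, discs

Each of ALL, PLL, LF, ISL, SSL is instantiated at every actuated joint
between named landmarks (posterior-element attachments fall back to the
sacral body rim at L5/S1). The elastic law is piecewise: slack below
`l₀ = (1 − ε_pre)·l_neut`, toe `K_nl·(l − l₀)^exp_nll` up to
`l_A = (1 + ε_A)·l₀`, linear `F_A,n + K_lin·(l − l_A)` beyond, where
`K_lin = (F_B,n − F_A,n)/(l_B − l_A)`, `ε_lin = F_A,n/(K_lin·l₀)`,
`exp_nll = ε_A/ε_lin` and `K_nl = F_A,n/(ε_A·l₀)^exp_nll`; this makes the
branches C0- and C1-continuous by construction (asserted numerically for
randomized parameter sets in the tests). Expressing breakpoints as strains
relative to the slack length gives uniform preload within one ligamentous
structure whose segments have different neutral lengths. `l_neut` is
measured in the assembled neutral model. Breakpoint strains/forces and
pre-strains ship in `data/ligaments.json` with a provenance note; they are
literature-range values, not measurements: notably the flaval pre-strain
default is 5 % (the reduced value that keeps flaval forces physiological
in upright flexion) and the supraspinous pre-strain is negative, making it
the one ligament slack in neutral standing. Viscous behavior is absent by
construction: at static equilibrium only the elastic law contributes.

Discs are rotational elements per joint with a neutral zone (no moment)
and a linear restoring stiffness beyond it, per axis; values in
`data/discs.json` are in the range of in vitro flexibility tests.

## Muscle apparatus

Nine groups, 103 point-to-point actuators. Globally acting RA, EO, IO and
the ribcage-attached fascicles of LL, IL, QL are one actuator per side;
lumbar fascicles are enumerated per level; the five interspinales are
midline actuators. Which fascicles merge into which actuator is a
*reconstruction* built to the published group/actuator counts — the
composition is not transcribed from any source. Three structural choices
were driven by static feasibility analysis (linear-programming feasibility
of the equilibrium constraints over the force cone) and are defensible
anatomy rather than tuning:

- the iliocostalis global actuator originates at the posterior rib angle
  (an anterior lower-rib origin makes it a flexor of the thoracolumbar
  junction and leaves the moment cone short there);
- the thoracic multifidus fascicles (six per side, PCSA 1 cm² each)
  insert on L1/L2, giving the thoracolumbar junction dedicated
  differential extensors;
- the global LL/IL actuators carry merged-fascicle cross-sections
  (12 / 9 cm² per side), consistent with summed pars-thoracis PCSAs.

Interspinales also carry the deliberately generous 1 cm² default.
Fascicles of one group sharing both endpoint references merge with summed
PCSA. Only active forces are modeled; there is no passive muscle
elasticity, no wrapping and no via-points, so lines of action degrade at
large flexion angles.

## Statics and optimization

Postures are chains of joint rotations applied caudal→cranial about each
joint's posed origin and frame; the sacral share of trunk flexion acts as
a base rotation at the lumbosacral joint (the pelvis is the mechanical
ground). The lumbopelvic rhythm (40 % sacral, 60 % lumbar split
25.5/23.1/20.4/18.5/12.5 %) is fixed for all flexion angles. The neutral
stance is found by minimizing the sum of squared sagittal net moments over
the six joints (Powell, zero start, ±10° bounds — deterministic), and task
postures superpose on it.

Required actuator moments are the moments of gravity and external loads on
the superstructure about each joint, net of ligament and disc
contributions, in the joint frame. The muscle problem minimizes
Σ(Fᵢ/PCSAᵢ)³ under 12 equality constraints (frontal and sagittal moments
at six joints; axial moments unconstrained) and bounds
0 ≤ Fᵢ ≤ σ_max·PCSAᵢ with σ_max defaulting to 1 MPa (100 N/cm²). The cost
is convex on the box, so SLSQP from a bounded least-squares start plus
nine deterministic random restarts (seeded) stands in for a global search;
the restarts are verification, not necessity. Equality residuals above
0.1 N·m (≪ the tens of N·m of physiological moments) raise an explicit
infeasibility error naming the worst joint. Joint reactions are minus the
resultant of all forces on the superstructure, decomposed in the joint
frame into compression (superior axis), AP shear (anterior) and lateral
shear; compressions are reported normalized to the upright-standing value
per joint. Ligament utilization is force divided by the force at the end
of the linear region (F/F_B), with values above 1 flagging
supra-physiological states.

## Problem sizes and numerical choices

Default grids are ≈135×325×150 voxels at 2 mm isotropic — small enough
that the full pipeline (generation, extraction, assembly, neutral-stance
optimization and a ten-case solved battery) runs in well under a minute on
one core, which is the problem size all shipped results use. Landmark ties
break toward subregion centroids; repeated centroids abort the spline;
degenerate (zero-length) fascicles are rejected at the moment-arm level.
The solver tolerance (0.1 N·m), σ_max (1 MPa), bounds (±10° neutral
stance) and the multi-start seeds are all recorded in the outputs; every
output file embeds the seed and a configuration hash.

## Known limitations

Spherical joints with fixed centres of rotation (no facet joints, no
center-of-rotation migration — flaval loads are correspondingly high in
flexion); no intra-abdominal pressure; no co-contraction (static
optimization silences antagonists); no "leaning back" compensation for
anterior hand loads, so heavy-carry cases overestimate extensor demand;
point-to-point muscle paths without wrapping; the fixed lumbopelvic rhythm
is a simplification at large flexion angles. The synthetic subject's
absolute loads depend on its torso composition and are not calibrated to
any individual; relative (normalized) quantities are the meaningful
outputs.
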