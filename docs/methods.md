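# Methods

## Coordinate conventions

All internal lengths are millimeters, all angles degrees. The room frame
has its origin at the machine isocenter, `+z` up, `+y` along the horizontal
gantry rotation axis pointing from the couch toward the gantry (this is
also the couch long axis at couch angle 0), and `+x` completing a
right-handed frame.

* **Gantry angle G**: rotation about `+y`; G = 0 places the radiation
  source above the isocenter with the beam pointing straight down; positive
  G rotates the source from `+z` toward `+x`. The half gantry permits
  G ∈ [0, 185] ∪ [355, 360) only; everything else is reported as
  `invalid_gantry_angle` (a status, not an exception, so whole-plan reports
  always complete).
* **Couch angle T**: rotation about `+z` through the isocenter, positive
  counterclockwise viewed from above.
* **Six-DoF corrections**: yaw → pitch → roll about room axes through the
  isocenter, then translation; limits ±3° and ±50 mm by default. The
  composition order is a documented choice — the source system publishes
  none.
* **CT coordinates**: patient-based LPS (`+x` patient left, `+y`
  posterior, `+z` superior). Only head-first supine is supported in v1;
  its mapping sends patient-superior to room `+y` and patient-posterior to
  room `−z`. Other orientations are rejected with a clear error rather
  than silently mishandled.

## JCT indexing

The junction-to-CT-origin value (JCT, cm at interfaces, converted once) is
the distance from the couch-extension connection junction to the CT
reference mark. The junction lies **inferior** of the mark — a
head-and-neck mark sits ~95 cm superior of where the extension couples to
the robot — so the junction is pinned at `z_ct = −JCT` on the couch surface
plane and the extension spans superior from it. Consequences that mirror
clinical experience: low-JCT (pelvic) targets pull the robotic arm close
under the isocenter, making posterior-oblique beams the type-3 hazard;
high-JCT (brain/head-and-neck) targets put the couch tip and corners near
the nozzle, making lateral beams the type-1 hazard. A beam whose isocenter
projects outside the modeled couch span raises an indexing error.

The plan context carries `couch_surface_y_ct`, the CT y-coordinate of the
couch-top plane, tying the patient's posterior skin to the couch height;
fixtures set it to their phantom convention (+100 mm).

## Machine model

Vendor CAD is proprietary, so every component is a parametric primitive
(capped cylinder, box, annulus, frustum) with documented placeholder
defaults in a versioned YAML config; all of them are overridable and none
is authoritative. Key defaults (mm): nozzle face to isocenter 420, ERS
face to isocenter 270 (the ERS sits strictly downstream of the nozzle, so
`ers_face_to_iso < nozzle_face_to_iso` is enforced), snout radius 160 and
length 350 ahead of a 450-radius casing, touch-guard skirt protruding
60 mm past the nozzle face, CIVCO full-body top 2000×530×70, Orfit
head-extension 1500×530×50 (sized to support the most superior reference
marks, ~mean+3SD of the craniospinal JCT plus the head), PPS base at
(900, −1400) on the floor with lower-arm 1500 and upper-arm+knuckle
1250+250 (equal effective link lengths, so the planar solve has no inner
dead zone and reaches every Table-style JCT/couch-angle combination).

The couch top carries an additional 10 mm safety margin at *each*
longitudinal end (20 mm total length increase) — a deliberate conservatism
in the model, not in the hardware. Tessellation resolution is a config
parameter as maximum chord deviation (default 5 mm), which bounds the
distance-query error for curved surfaces; rebuilt models are bit-identical
and the dimension self-check (`validate_dimensions`) re-measures nozzle,
ERS, couch and base distances from the meshes at 1 mm tolerance.

The two kV imaging cones are frustums from source points to detector
planes passing through the isocenter; they are obstruction-only: reported
when the gantry head or arm blocks them, never part of pass/warn/fail.

## Patient geometry

Structures arrive as stacks of closed planar contours (DICOM RT-STRUCT
CLOSED_PLANAR subset, or a plain-text per-slice polygon format used by the
fixtures). Meshing: normalize winding, resample each polygon by arc length
to the component's maximum vertex count (when counts already match, samples
land on the original vertices, so boxes stay boxes), align consecutive
rings by cyclic shift, stitch with quad strips, and cap the end slices by
ear clipping. Polygons are grouped into connected components across slices
by xy-overlap with heads that stay open across non-matching slices, so
solids sampled at different slice spacings (a raised arm next to a torso)
stitch independently; branching topologies become separate stacked solids.
Vertex merge tolerance is 1e-6 mm. Mesh volume agrees with the prism-sum
of the contour stack to well under 2 % at typical contour densities.

Structure roles (`body`, `immobilization`, `bolus_device`, `other`) are
inferred from names by a configurable pattern list (bolus patterns take
precedence over the generic mask/helmet/board patterns). A missing body
structure is a recorded warning, not an error.

## Collision engine

Clearance is the exact minimum surface-to-surface Euclidean distance —
the conservative choice versus center or bounding-box distances. The
primitive is a closed-form triangle-pair distance: the minimum over 9
edge-edge and 6 vertex-face candidates, with segment-triangle piercing
tests forcing 0 for crossing triangles. Two query paths exist by design:

* `brute_force_distance` — exhaustive over all triangle pairs (guarded to
  2,000 triangles total); the oracle for property tests and for labelling
  every generated fixture;
* `min_distance` — the same primitive under best-first branch-and-bound
  over per-mesh AABB trees, seeded with the closest vertex-pair distance
  as an upper bound. Any pair whose box lower bound exceeds the current
  bound cannot contain the minimizer, so the result is exact (verified to
  1e-6 mm against the oracle on randomized pairs).

With a `cutoff` (100 mm by default in beam checks, always above the warn
threshold), distances beyond it may be reported as the vertex-pair upper
bound instead of the exact value; statuses are unaffected. Containment of
one watertight solid inside another (surfaces disjoint) counts as overlap,
detected by a ray-parity test. Ties among equidistant pairs resolve by the
deterministic candidate order, keeping reports bit-reproducible.

Monitored pairs are gantry-side hazards {head, touch guard, ERS} against
{couch top → type 1, body → type 2, PPS arms → type 3,
immobilization/bolus → type 4}; couch-vs-patient is deliberately not
monitored (the patient rests on the couch by construction), and the touch
guard is treated as an ordinary collision surface since its trigger
behavior is not publicly specified. Structures with role `other` are
display-only.

## Plan checking

`fail` requires actual mesh contact or overlap; `warn` encodes the 3-cm
buffer below which a physical angle check is advised — the buffer applies
uniformly to every monitored pair. A result reports the worst (minimum
distance) pair plus all sub-warn pairs; the plan verdict is the maximum
severity over beams (pass < warn < fail < invalid gantry angle), and
per-beam configuration problems (ERS required but absent, unreachable
couch pose, junction off the couch) are collected in the report without
aborting the remaining beams. Feasibility sweeps run one independent beam
check per grid cell at the plan isocenter with zero six-DoF, so refining a
grid never changes existing cells.

## Synthetic fixtures

The generator emulates the study conditions rather than any real patient:

* **JCT sampling** — per-site normal distributions (head-and-neck
  94.7 ± 5.6 cm, GI 67 ± 5.8, GU 53.5 ± 6.7, breast/chestwall 54.2 ± 2.6,
  CSI 111 ± 5.7, brain 105.7 ± 3.2, thorax 75.4 ± 10.3), truncated at
  ±3 SD to avoid nonphysical values, deterministic per seed.
* **Phantoms** — flat-backed ellipse stacks (torso, shoulders, head)
  resting on the couch plane, with site devices: thermoplastic-mask slab
  (head-and-neck), Vac-Lok slab (GI/GU), breast board protruding beyond
  the couch edges plus a raised arm held anterior on a grip bar (breast),
  helmet baseplate with protruding corners and a bolus dome (brain). The
  raised arm is part of the Body solid (disjoint shells) so its collisions
  classify as patient (type 2). A ±2 % seeded width jitter varies
  realizations; contour density (24-point rings, 60 mm slices) keeps every
  hazard/obstacle pair within the brute-force oracle's size guard.
* **Staged scenarios** — `make_scenario` bisects the isocenter depth
  inside the body until the engine-measured clearance lands within 2 mm of
  a target (0-targets are pushed past grazing contact into solid overlap);
  every label is then re-verified with the brute-force oracle. The
  12-plan validation mix (1 CSI, 2 brain, 3 breast, 3 GI/GU, 3
  head-and-neck) stages exactly four collisions at the sites the clinic
  associates with each type: brain lateral at couch 270° → couch top
  (type 1), breast oblique with ERS → raised arm (type 2), GI
  posterior-oblique at couch 180° → robotic arm (type 3), head-and-neck
  lateral with ERS → couch edge (type 1); a separate per-type set adds the
  breast-board case (type 4).

What passing fixture tests does *not* show: anatomical realism (phantoms
are parametric solids), deformable or low-density devices (all solids are
rigid), vendor-exact machine geometry (dimensions are placeholders), or
dynamic motion between poses (checks are static per beam).

## Numerical choices and limitations

Distance tolerance in oracle comparisons is 1e-6 mm; rigid transforms are
validated orthonormal to 1e-8 with determinant +1; the arm solver closes
to < 0.1 mm on randomized reachable poses and always selects the
left-elbow branch (constant sign of the base–elbow–wrist area). Known
limitations: no penetration depth or swept-motion checking; single patient
orientation; plan input is the package's own schema (no DICOM RT-PLAN);
the GUI of the clinical workflow is replaced by scene export and reports.
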