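# gantryclear

Patient-specific collision avoidance for half-gantry proton therapy.

Scanning-beam proton systems with a half gantry (rotation restricted to the
arc 355° → 185° through 0°) and a robotic patient positioning system (PPS)
are prone to four collision scenarios that a full 360° gantry can often
sidestep by picking the complementary angle: the gantry head against
(1) the couch top, (2) the patient, (3) the robotic arm, and (4) the
immobilization devices. An insertable extended range shifter (ERS),
required for shallow targets, sits downstream of the nozzle and makes every
clearance tighter. `gantryclear` lets dosimetrists and physicists check a
treatment plan's beams *virtually* — at pre-plan and final-check time —
instead of discovering an interference at the machine.

## What it computes

Every machine part and patient structure is a watertight triangle mesh.
For a beam with gantry angle *G* and couch angle *T* the scene is posed by
IEC-style rigid kinematics: the gantry-fixed parts rotate about the
horizontal axis (*G* = 0 pointing the beam straight down), the couch yaws
about the vertical axis through the isocenter, and the patient contours are
placed so the planned isocenter lands on the room origin. The patient's
longitudinal position on the couch is indexed by the **junction-to-CT-origin
(JCT)** value measured at CT simulation: the distance from the
couch-extension connection junction to the CT reference mark. A two-link
left-elbow solver poses the robotic arm under the couch.

The safety quantity is the exact minimum surface-to-surface distance
*d*(A, B) between each gantry-side hazard (head casing, touch guard, range
shifter) and each monitored obstacle (couch top, PPS arms, body,
immobilization/bolus structures), computed by branch-and-bound over
axis-aligned bounding-box trees with closed-form triangle–triangle
distances at the leaves. Per beam:

* **fail** — any monitored pair touches or overlaps (*d* = 0);
* **warn** — 0 < min *d* < 30 mm (the 3-cm buffer margin): the beam is
  flagged for a physical "angle check" on the machine;
* **pass** — min *d* ≥ 30 mm.

The worst pair is classified into collision types 1–4, plans aggregate to a
verdict, and a gantry × couch feasibility map supports beam-angle selection.
Stereoscopic kV imaging cones are checked for obstruction by the gantry or
arm, informationally.

Vendor CAD being proprietary, all machine components are parametric
primitives with placeholder default dimensions (mm) in a versioned YAML
config — override them with site-measured values; `validate-machine`
re-measures every build against its config at 1 mm tolerance.

## Worked example

Generate the synthetic validation scenarios (site phantoms with Table-style
JCT values and beam presets, four of them staged to collide), then check
two of them:

```sh
$ gantryclear fixtures bundles --seed 0
12 scenario bundles written to bundles

$ gantryclear check bundles/gu_clear_8/plan.yaml bundles/gu_clear_8/contours.txt \
      --machine bundles/gu_clear_8/machine.yaml
Plan verdict: PASS

beam         status                 clearance mm  worst pair
gu_clear8    pass                          233.6  touch_guard vs Body (type2_gantry_vs_patient)

$ gantryclear check bundles/gi_gi_post_target0mm/plan.yaml \
      bundles/gi_gi_post_target0mm/contours.txt \
      --machine bundles/gi_gi_post_target0mm/machine.yaml
Plan verdict: FAIL

beam         status                 clearance mm  worst pair
gi_post      fail                            0.0  touch_guard vs pps_upper_arm_knuckle (type3_gantry_vs_pps_arm)
```

The first plan is a pelvis field whose nearest approach — 233.6 mm between
the touch guard and the patient surface — is comfortably outside the 3-cm
buffer (exit code 0). The second is a posterior-oblique pelvis beam at
couch 180°: with a low junction value the robotic arm reaches under the
isocenter and the touch guard contacts the upper arm/knuckle assembly — a
type-3 collision, exit code 3. Exit codes are stable for scripting:
0 pass, 2 warn, 3 fail, 4 invalid gantry angle, 64 usage error.

Other subcommands: `sweep` (feasibility map as CSV/heatmap), `export-scene`
(posed meshes as STL/OBJ for any viewer), `validate-machine`,
`write-machine-config`.

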