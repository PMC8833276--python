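"""Synthetic site phantoms, JCT sampling, beam presets, staged scenarios.

The generator emulates the clinical study conditions: per-site
junction-to-CT-origin (JCT) statistics and common couch/gantry angle
presets, simple parametric body phantoms (flat-backed ellipse stacks lying
on the couch plane) with site-appropriate immobilization devices, and a
12-plan validation mix whose colliding subset reproduces the four
collision types at their characteristic sites.  Everything is
deterministic for a fixed seed, and every staged outcome label is verified
against the brute-force distance oracle at generation time.

Phantom CT convention: LPS coordinates, couch-top surface plane at
``y = +100`` mm (patient posterior rests on it), CT origin on the patient
midline at the site's reference-mark level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .collision import brute_force_distance
from .kinematics import BeamConfig, PlanContext
from .machine import DimensionSet, MachineModel, build_machine
from .patient import Contour, StructureMesh, StructureSet, contours_to_mesh
from .plancheck import Thresholds, check_beam, pose_scene

__all__ = [
    "SitePreset",
    "Scenario",
    "SITE_PRESETS",
    "make_phantom",
    "sample_jct",
    "preset_beams",
    "make_scenario",
    "collision_mix_v1",
    "COUCH_SURFACE_Y",
]

COUCH_SURFACE_Y = 100.0  # mm, couch-top plane in phantom CT coordinates


@dataclass(frozen=True)
class SitePreset:
    """Per-site JCT statistics, common beam angle ranges, device templates."""

    site: str
    jct_mean: float  # cm
    jct_sd: float  # cm
    couch_angles: tuple  # (lo, hi) degree ranges, wrap-around allowed
    gantry_angles: tuple
    ers_default: bool
    couch_top_kind: str
    devices: tuple = ()


SITE_PRESETS = {
    "head_and_neck": SitePreset(
        "head_and_neck", 94.7, 5.6,
        ((180.0, 195.0), (270.0, 270.0), (0.0, 0.0)),
        ((10.0, 35.0), (40.0, 50.0), (80.0, 110.0), (150.0, 160.0), (175.0, 180.0)),
        ers_default=True, couch_top_kind="orfit", devices=("Mask",),
    ),
    "gi": SitePreset(
        "gi", 67.0, 5.8,
        ((350.0, 0.0), (175.0, 180.0)),
        ((150.0, 165.0),),
        ers_default=False, couch_top_kind="civco", devices=("VacLok",),
    ),
    "gu": SitePreset(
        "gu", 53.5, 6.7,
        ((0.0, 0.0), (180.0, 180.0)),
        ((50.0, 50.0), (90.0, 90.0)),
        ers_default=False, couch_top_kind="civco", devices=("VacLok",),
    ),
    "breast_chestwall": SitePreset(
        "breast_chestwall", 54.2, 2.6,
        ((0.0, 0.0), (180.0, 180.0)),
        ((0.0, 0.0), (15.0, 55.0), (110.0, 110.0)),
        ers_default=True, couch_top_kind="civco", devices=("BreastBoard",),
    ),
    "csi": SitePreset(
        "csi", 111.0, 5.7,
        ((0.0, 0.0), (180.0, 180.0), (270.0, 270.0)),
        ((180.0, 180.0), (45.0, 90.0), (120.0, 135.0)),
        ers_default=False, couch_top_kind="civco", devices=(),
    ),
    "brain": SitePreset(
        "brain", 105.7, 3.2,
        ((0.0, 350.0), (250.0, 270.0), (180.0, 200.0)),
        ((30.0, 80.0), (90.0, 90.0), (120.0, 160.0), (180.0, 180.0)),
        ers_default=False, couch_top_kind="orfit", devices=("HelmetBaseplate", "BolusHelmet"),
    ),
    "thorax": SitePreset(
        "thorax", 75.4, 10.3,
        ((350.0, 0.0), (180.0, 180.0)),
        ((0.0, 0.0), (30.0, 45.0), (90.0, 90.0), (145.0, 160.0), (180.0, 180.0)),
        ers_default=False, couch_top_kind="civco", devices=(),
    ),
}


@dataclass(frozen=True)
class Scenario:
    """A complete staged test case with an oracle-verified expected outcome."""

    name: str
    site: str
    machine: MachineModel
    structures: StructureSet
    ctx: PlanContext
    expected_outcome: str  # collide | warn | clear
    expected_type: str | None = None  # CollisionType name when colliding


# ---------------------------------------------------------------------------
# JCT sampling
# ---------------------------------------------------------------------------

def sample_jct(site: str, seed: int, size: int | None = None):
    """Draw JCT values (cm) from the site's normal, truncated at ±3 SD."""
    preset = _preset(site)
    rng = np.random.default_rng(seed)
    n = 1 if size is None else size
    out = np.empty(n)
    lo = preset.jct_mean - 3 * preset.jct_sd
    hi = preset.jct_mean + 3 * preset.jct_sd
    filled = 0
    while filled < n:
        draw = rng.normal(preset.jct_mean, preset.jct_sd, size=n - filled)
        keep = draw[(draw >= lo) & (draw <= hi)]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return float(out[0]) if size is None else out


def _preset(site: str) -> SitePreset:
    if site not in SITE_PRESETS:
        raise ValueError(f"unsupported site {site!r}; have {sorted(SITE_PRESETS)}")
    return SITE_PRESETS[site]


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def _flat_back_ellipse(half_width: float, height: float, n: int = 24,
                       center_x: float = 0.0) -> np.ndarray:
    """Ellipse cross-section clipped flat at the couch plane y=COUCH_SURFACE_Y.

    ``height`` is the anterior-posterior extent; the flat back sits exactly
    on the couch plane so the phantom rests on the couch top.
    """
    cy = COUCH_SURFACE_Y - height / 2.0
    b = height / 2.0
    # parametrize only the anterior arc, then close along the flat back
    t = np.linspace(0.0, np.pi, n)
    x = center_x + half_width * np.cos(t)
    y = cy - b * np.sin(t)
    pts = np.column_stack([x, y])
    back = np.array([[center_x - half_width, COUCH_SURFACE_Y],
                     [center_x + half_width, COUCH_SURFACE_Y]])
    ring = np.vstack([back[1], pts, back[0]])
    # drop near-duplicate endpoints
    keep = np.ones(len(ring), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(ring, axis=0), axis=1) > 1e-9
    return ring[keep]


def _circle(radius: float, cx: float, cy: float, n: int = 24) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + radius * np.cos(t), cy + radius * np.sin(t)])


def _rect(x0, x1, y0, y1) -> np.ndarray:
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)


def _segment_contours(segments, dz: float, jitter: float, rng) -> list:
    """Stack flat-back ellipse contours over piecewise body segments.

    ``segments``: list of (z_lo, z_hi, half_width, height); contours are laid
    every ``dz`` mm with a small seeded width jitter for realism.
    """
    contours = []
    for z_lo, z_hi, a, h in segments:
        zs = np.arange(z_lo, z_hi + 0.5 * dz, dz)
        for z in zs:
            scale = 1.0 + jitter * rng.uniform(-1.0, 1.0)
            contours.append(Contour(float(z), _flat_back_ellipse(a * scale, h * scale)))
    return contours


# per-site body segment tables (z mm relative to the CT reference mark)
_BODY_SEGMENTS = {
    # pelvis mark: torso up through chest, shoulders, head
    "gu": [(-200, 500, 180, 220), (510, 640, 180, 190), (650, 900, 85, 170)],
    "gi": [(-350, 400, 180, 220), (410, 540, 180, 190), (550, 800, 85, 170)],
    "thorax": [(-500, 250, 180, 220), (260, 390, 180, 190), (400, 650, 85, 170)],
    "breast_chestwall": [(-500, 250, 180, 220), (260, 390, 180, 190), (400, 650, 85, 170)],
    # neck-level mark: shoulders just inferior, head superior
    "head_and_neck": [(-700, -150, 180, 220), (-140, -40, 200, 180), (-30, 240, 85, 170)],
    # mid-head mark
    "brain": [(-900, -350, 180, 220), (-340, -240, 200, 180), (-230, 100, 85, 170)],
    # mark near the head top (most superior)
    "csi": [(-1000, -450, 180, 220), (-440, -340, 200, 180), (-330, 30, 85, 170)],
}


def _device_structures(site: str, rng) -> list:
    """Site-appropriate immobilization/bolus devices as contour stacks."""
    preset = _preset(site)
    out = []
    dz = 50.0
    for device in preset.devices:
        if device == "Mask":
            # five-point thermoplastic mask analog: shell slab over the head
            zs = np.arange(-60.0, 240.0, dz)
            cs = [Contour(float(z), _rect(-115, 115, -105, -65)) for z in zs]
            out.append(("Mask", "immobilization", cs))
        elif device == "VacLok":
            # vacuum cushion slab under/around the torso, slightly wider
            zs = np.arange(-250.0, 420.0, dz)
            cs = [Contour(float(z), _rect(-230, 230, 60, 100)) for z in zs]
            out.append(("VacLok", "immobilization", cs))
        elif device == "BreastBoard":
            # board base protruding laterally beyond the couch edges
            zs = np.arange(-450.0, 220.0, dz)
            cs = [Contour(float(z), _rect(-290, 290, 80, 100)) for z in zs]
            out.append(("BreastBoard", "immobilization", cs))
        elif device == "HelmetBaseplate":
            # baseplate under the head only, top corners protruding beyond it
            zs = np.arange(-200.0, 120.0, dz)
            cs = [Contour(float(z), _rect(-170, 170, 50, 100)) for z in zs]
            out.append(("HelmetBaseplate", "immobilization", cs))
        elif device == "BolusHelmet":
            # bolus dome capping the head top
            zs = np.arange(40.0, 180.0, 35.0)
            cs = [Contour(float(z), _circle(105.0, 0.0, -10.0)) for z in zs]
            out.append(("BolusHelmet", "bolus_device", cs))
    return out


def make_phantom(site: str, seed: int) -> StructureSet:
    """Build the site phantom: flat-backed body plus site devices.

    The body is a stack of flat-backed ellipse contours (torso, shoulders,
    head) resting on the couch plane; breast/chestwall phantoms add a raised
    arm as a disjoint sub-volume of the body structure and as a separate
    display structure.  Deterministic for a fixed seed.
    """
    _preset(site)
    rng = np.random.default_rng(seed)
    dz = 60.0
    body_contours = _segment_contours(_BODY_SEGMENTS[site], dz, 0.02, rng)

    arm_contours = []
    if site == "breast_chestwall":
        # arm raised above the head on a grip bar: a tube held well anterior
        # of the torso surface, superior-lateral of the chest
        for z in np.arange(150.0, 600.0, 75.0):
            arm_contours.append(Contour(float(z), _circle(45.0, 140.0, -150.0, n=16)))

    structures = [
        StructureMesh("Body", "body", contours_to_mesh(body_contours + arm_contours))
    ]
    if arm_contours:
        structures.append(
            StructureMesh("RaisedArm", "other", contours_to_mesh(arm_contours))
        )
    for name, role, cs in _device_structures(site, rng):
        structures.append(StructureMesh(name, role, contours_to_mesh(cs)))
    return StructureSet(tuple(structures))


def preset_beams(site: str, seed: int, isocenter_ct=(0.0, 0.0, 0.0), n_beams: int = 2):
    """Deterministic beams drawn from the site's couch/gantry angle presets."""
    preset = _preset(site)
    rng = np.random.default_rng(seed)

    def pick(ranges):
        lo, hi = ranges[rng.integers(len(ranges))]
        if hi < lo:  # wrap-around range like 350-0
            hi += 360.0
        return float(np.round(rng.uniform(lo, hi), 1)) % 360.0

    beams = []
    for i in range(n_beams):
        beams.append(
            BeamConfig(
                f"{site[:2]}{i + 1}",
                gantry_angle=pick(preset.gantry_angles),
                couch_angle=pick(preset.couch_angles),
                isocenter_ct=isocenter_ct,
                ers_required=preset.ers_default,
            )
        )
    return tuple(beams)


# ---------------------------------------------------------------------------
# staged scenarios
# ---------------------------------------------------------------------------

def _build_context(site: str, beams, jct_cm: float) -> PlanContext:
    preset = _preset(site)
    return PlanContext(
        jct_cm=jct_cm,
        beams=tuple(beams),
        couch_top_kind=preset.couch_top_kind,
        couch_surface_y_ct=COUCH_SURFACE_Y,
    )


def _machine_for(site: str, ers: bool | None = None) -> MachineModel:
    preset = _preset(site)
    use_ers = preset.ers_default if ers is None else ers
    return build_machine(DimensionSet(), preset.couch_top_kind, ers_attached=use_ers)


def _oracle_worst_pair_distance(machine, structures, ctx, beam) -> tuple:
    """Brute-force re-measurement of the engine's worst pair for one beam.

    The distance cutoff is disabled so the engine value is exact everywhere
    and directly comparable to the exhaustive oracle.
    """
    hazards, obstacles = pose_scene(machine, structures, ctx, beam)
    result = check_beam(machine, structures, ctx, beam, cutoff=1e6)
    wp = result.worst_pair
    mesh_a = next(m for n, _, m in hazards if n == wp.component_a)
    mesh_b = next(m for n, _, m in obstacles if n == wp.component_b)
    return result, brute_force_distance(mesh_a, mesh_b)


def make_scenario(
    site: str,
    beam: BeamConfig,
    target_clearance: float,
    seed: int,
    jct_cm: float | None = None,
) -> Scenario:
    """Stage a scenario whose minimum clearance hits ``target_clearance`` mm.

    The isocenter depth (CT y) is bisected within the body so the posed
    configuration's oracle-measured clearance lands within 2 mm of the
    target (0 mm targets produce actual contact/overlap).  Raises if the
    target is outside what the placement limits allow.
    """
    if target_clearance < 0:
        raise ValueError("target_clearance must be >= 0")
    structures = make_phantom(site, seed)
    machine = _machine_for(site, ers=beam.ers_required or None)
    jct = float(jct_cm if jct_cm is not None else _preset(site).jct_mean)

    def clearance_at(iso_y: float):
        b = BeamConfig(beam.beam_id, beam.gantry_angle, beam.couch_angle,
                       (beam.isocenter_ct[0], iso_y, beam.isocenter_ct[2]),
                       beam.ers_required)
        ctx = _build_context(site, (b,), jct)
        return check_beam(machine, structures, ctx, b).min_clearance, b, ctx

    lo, hi = -115.0, 95.0  # iso depth range within the phantom body
    c_lo, b_lo, ctx_lo = clearance_at(lo)
    c_hi, b_hi, ctx_hi = clearance_at(hi)
    # clearance shrinks as the isocenter moves anterior (deeper below skin)
    c_min, c_max = min(c_lo, c_hi), max(c_lo, c_hi)
    if not (c_min - 2.0 <= target_clearance <= c_max + 2.0):
        raise ValueError(
            f"target clearance {target_clearance} mm unreachable: placement "
            f"limits give [{c_min:.1f}, {c_max:.1f}] mm"
        )
    if c_lo > c_hi:
        y_far, y_near = lo, hi
    else:
        y_far, y_near = hi, lo
    best = None
    for _ in range(40):
        mid = 0.5 * (y_far + y_near)
        c_mid, b_mid, ctx_mid = clearance_at(mid)
        best = (c_mid, b_mid, ctx_mid)
        if abs(c_mid - target_clearance) <= 1.0:
            break
        if c_mid > target_clearance:
            y_far = mid
        else:
            y_near = mid
    clearance, staged_beam, ctx = best
    if target_clearance == 0.0 and clearance == 0.0:
        # push past grazing contact into solid overlap so the staged
        # collision is robust to contour re-export and re-meshing
        deeper = np.clip(staged_beam.isocenter_ct[1] + (10.0 if c_hi < c_lo else -10.0),
                         lo, hi)
        c_deep, b_deep, ctx_deep = clearance_at(float(deeper))
        if c_deep == 0.0:
            clearance, staged_beam, ctx = c_deep, b_deep, ctx_deep
    if abs(clearance - target_clearance) > 2.0 and target_clearance > 0:
        raise ValueError(
            f"bisection failed to reach target {target_clearance} mm "
            f"(closest {clearance:.2f} mm)"
        )
    result, oracle_d = _oracle_worst_pair_distance(machine, structures, ctx, staged_beam)
    if abs(oracle_d - result.min_clearance) > 1e-6:
        raise AssertionError("engine/oracle disagreement while staging scenario")
    expected = "collide" if result.status == "fail" else (
        "warn" if result.status == "warn" else "clear"
    )
    return Scenario(
        name=f"{site}_{beam.beam_id}_target{target_clearance:g}mm",
        site=site,
        machine=machine,
        structures=structures,
        ctx=ctx,
        expected_outcome=expected,
        expected_type=result.worst_pair.type.name if expected == "collide" else None,
    )


# the 12-plan validation mix: (site, colliding?, staged beam, staged target)
_MIX_SITES = (
    ("csi", False),
    ("brain", True),
    ("brain", False),
    ("breast_chestwall", True),
    ("breast_chestwall", False),
    ("breast_chestwall", False),
    ("gi", True),
    ("gi", False),
    ("gu", False),
    ("head_and_neck", True),
    ("head_and_neck", False),
    ("head_and_neck", False),
)

# staged colliding configurations per site, reproducing the collision types
# the clinic attributes to each site: brain -> couch top (type 1),
# breast -> patient arm (type 2), GI -> robotic arm (type 3),
# head and neck -> shoulder/couch with the range shifter (type 1/2)
_COLLIDING_CONFIG = {
    "brain": dict(beam=BeamConfig("b_lat", 90.0, 270.0), jct_cm=105.7),
    "breast_chestwall": dict(beam=BeamConfig("br_obl", 35.0, 0.0, ers_required=True), jct_cm=54.2),
    "gi": dict(beam=BeamConfig("gi_post", 165.0, 180.0), jct_cm=67.0),
    "head_and_neck": dict(beam=BeamConfig("hn_lat", 110.0, 0.0, ers_required=True), jct_cm=94.7),
}

# verified-clear beam choices: anterior-ish beams with a shallow-anterior
# isocenter, except GI whose presets are posterior-oblique only (there the
# isocenter sits posterior, as for rectal/para-spinal targets)
_CLEAR_BEAM = {
    "csi": BeamConfig("cl", 180.0, 0.0, (0.0, -60.0, 0.0)),
    "brain": BeamConfig("cl", 30.0, 0.0, (0.0, -60.0, 0.0)),
    "breast_chestwall": BeamConfig("cl", 0.0, 0.0, (0.0, -60.0, 0.0)),
    "gi": BeamConfig("cl", 150.0, 0.0, (0.0, 40.0, 0.0)),
    "gu": BeamConfig("cl", 50.0, 0.0, (0.0, -60.0, 0.0)),
    "head_and_neck": BeamConfig("cl", 10.0, 0.0, (0.0, -60.0, 0.0)),
    "thorax": BeamConfig("cl", 0.0, 0.0, (0.0, -60.0, 0.0)),
}


def _clear_scenario(site: str, seed: int, index: int) -> Scenario:
    """A verified-clear scenario: shallow anterior-ish beam, >=50 mm margin."""
    structures = make_phantom(site, seed)
    machine = _machine_for(site)
    base = _CLEAR_BEAM[site]
    beam = BeamConfig(f"{site[:2]}_clear{index}", base.gantry_angle, base.couch_angle,
                      base.isocenter_ct, ers_required=_preset(site).ers_default)
    ctx = _build_context(site, (beam,), _preset(site).jct_mean)
    result, oracle_d = _oracle_worst_pair_distance(machine, structures, ctx, beam)
    if result.status != "pass" or result.min_clearance < 50.0:
        raise AssertionError(
            f"clear scenario for {site} is not clear: {result.status} "
            f"at {result.min_clearance:.1f} mm"
        )
    if abs(oracle_d - result.min_clearance) > 1e-6:
        raise AssertionError("engine/oracle disagreement in clear scenario")
    return Scenario(f"{site}_clear_{index}", site, machine, structures, ctx, "clear")


# one staged configuration per collision type, at its characteristic site
_TABLE1_CONFIG = {
    "type1_gantry_vs_couch": ("brain", BeamConfig("t1", 90.0, 270.0), 105.7),
    "type2_gantry_vs_patient": ("breast_chestwall", BeamConfig("t2", 35.0, 0.0, ers_required=True), 54.2),
    "type3_gantry_vs_pps_arm": ("gi", BeamConfig("t3", 165.0, 180.0), 67.0),
    "type4_gantry_vs_immobilization": ("breast_chestwall", BeamConfig("t4", 110.0, 0.0, ers_required=True), 54.2),
}


def table1_scenarios(seed: int = 0) -> dict:
    """One staged colliding scenario per collision type (1-4).

    Each scenario is built at the disease site where the clinic observes
    that collision type: couch-top impacts for brain laterals, patient
    (raised-arm) and immobilization (breast board) impacts for breast with
    the range shifter, robotic-arm impacts for posterior GI beams.  The
    detected worst-pair classification is asserted at generation.
    """
    out = {}
    for type_name, (site, beam, jct) in _TABLE1_CONFIG.items():
        sc = make_scenario(site, beam, 0.0, seed, jct_cm=jct)
        if sc.expected_outcome != "collide" or sc.expected_type != type_name:
            raise AssertionError(
                f"staged {type_name} scenario produced {sc.expected_outcome} "
                f"({sc.expected_type})"
            )
        out[type_name] = sc
    return out


def collision_mix_v1(seed: int = 0):
    """The 12-scenario validation mix: 1 CSI, 2 brain, 3 breast, 3 GI/GU,
    3 head-and-neck; exactly four staged to collide (one brain, one breast,
    one GI, one head-and-neck), the rest verified clear with >=50 mm margin.
    """
    scenarios = []
    for i, (site, collide) in enumerate(_MIX_SITES):
        if collide:
            cfg = _COLLIDING_CONFIG[site]
            sc = make_scenario(site, cfg["beam"], 0.0, seed + i, jct_cm=cfg["jct_cm"])
            if sc.expected_outcome != "collide":
                raise AssertionError(f"staged collision for {site} did not collide")
        else:
            sc = _clear_scenario(site, seed + i, i)
        scenarios.append(sc)
    return scenarios
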