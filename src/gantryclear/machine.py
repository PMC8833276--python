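"""Parametric triangle-mesh model of a half-gantry proton treatment room.

Components modeled: the gantry body and head casing with its touch guard, an
insertable extended range shifter (ERS), the three-part robotic patient
positioning system (PPS: base + lower arm, upper arm + knuckle, and the
couch), two interchangeable couch tops, and the oblique stereoscopic kV
imaging field cones.

Vendor CAD is proprietary, so every component is a documented parametric
primitive (capped cylinders, boxes, annuli, frustums).  The shipped default
dimensions are plausible placeholders, NOT vendor values, and every one of
them is overridable through :class:`DimensionSet` or the YAML machine config.

Local frames: gantry-rotating components are meshed at gantry angle 0 with
the beam pointing straight down (+z is up, the nozzle face is above the
isocenter at ``nozzle_face_to_iso``); the couch top's local origin is the
center of its top surface at the junction (gantry-side) end, the couch
extending toward local ``-y``.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .collision import point_mesh_distance

__all__ = [
    "DimensionSet",
    "CouchTopDims",
    "MachineComponent",
    "MachineModel",
    "DimensionError",
    "build_machine",
    "attach_range_shifter",
    "build_kv_fields",
    "validate_dimensions",
    "export_component",
]

COMPONENT_KINDS = (
    "gantry_body",
    "gantry_head",
    "touch_guard",
    "range_shifter",
    "pps_base_lower_arm",
    "pps_upper_arm_knuckle",
    "couch_top",
    "kv_field",
)

FRAMES = ("gantry-rotating", "couch-mounted", "pps-articulated", "room-fixed")


class DimensionError(ValueError):
    """A machine dimension violates its physical invariant."""


@dataclass(frozen=True)
class CouchTopDims:
    """Nominal couch-top dimensions (mm), before the safety margin."""

    length: float = 2000.0
    width: float = 530.0
    thickness: float = 70.0


@dataclass(frozen=True)
class DimensionSet:
    """All tunable machine dimensions, in mm.

    Defaults are placeholder values for a half-gantry system layout and must
    be overridden with site-measured values for clinical-grade use.
    """

    nozzle_face_to_iso: float = 420.0
    ers_face_to_iso: float = 270.0
    snout_radius: float = 160.0
    snout_length: float = 350.0
    head_casing_radius: float = 450.0
    head_casing_depth: float = 600.0
    touch_guard_standoff: float = 60.0
    # civco: full-body universal top; orfit: shorter head-and-neck extension
    # sized to support the most superior reference marks (JCT up to ~128 cm)
    couch_tops: dict = field(
        default_factory=lambda: {
            "civco": CouchTopDims(2000.0, 530.0, 70.0),
            "orfit": CouchTopDims(1500.0, 530.0, 50.0),
        }
    )
    # base column height, lower arm, upper arm, knuckle offset; lower arm and
    # upper-arm+knuckle lengths match so the planar solve has no inner dead zone
    arm_link_lengths: tuple = (700.0, 1500.0, 1250.0, 250.0)
    base_position: tuple = (900.0, -1400.0, -1300.0)
    kv_source_positions: tuple = ((1400.0, 1000.0, 1700.0), (-1400.0, 1000.0, 1700.0))
    kv_detector_centers: tuple = ((-1260.0, -900.0, -1530.0), (1260.0, -900.0, -1530.0))
    longitudinal_safety_margin: float = 10.0
    chord_tolerance: float = 5.0  # max tessellation chord deviation, mm

    def __post_init__(self) -> None:
        positive = (
            "nozzle_face_to_iso",
            "ers_face_to_iso",
            "snout_radius",
            "snout_length",
            "head_casing_radius",
            "head_casing_depth",
            "touch_guard_standoff",
            "chord_tolerance",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise DimensionError(f"{name} must be strictly positive")
        if self.longitudinal_safety_margin < 0:
            raise DimensionError("longitudinal_safety_margin must be >= 0")
        if not self.ers_face_to_iso < self.nozzle_face_to_iso:
            raise DimensionError(
                "ers_face_to_iso must be smaller than nozzle_face_to_iso: the range "
                "shifter sits downstream of the nozzle, closer to the isocenter"
            )
        for kind, ct in self.couch_tops.items():
            for dim in ("length", "width", "thickness"):
                if not getattr(ct, dim) > 0:
                    raise DimensionError(f"couch_tops[{kind}].{dim} must be strictly positive")
        if len(self.arm_link_lengths) != 4 or any(v <= 0 for v in self.arm_link_lengths):
            raise DimensionError("arm_link_lengths must be 4 strictly positive lengths")

    def replace(self, **kw) -> "DimensionSet":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class MachineComponent:
    """A named mesh in its component-local frame with an attachment rule."""

    name: str
    kind: str
    mesh: trimesh.Trimesh
    frame: str
    obstruction_only: bool = False

    def __post_init__(self) -> None:
        if self.kind not in COMPONENT_KINDS:
            raise ValueError(f"unknown component kind {self.kind!r}")
        if self.frame not in FRAMES:
            raise ValueError(f"unknown attachment frame {self.frame!r}")
        if len(self.mesh.faces) == 0 or not np.isfinite(self.mesh.vertices).all():
            raise ValueError(f"component {self.name!r} mesh is empty or non-finite")
        if self.mesh.faces.max() >= len(self.mesh.vertices):
            raise ValueError(f"component {self.name!r} has out-of-range face indices")


@dataclass(frozen=True)
class MachineModel:
    components: tuple
    dimensions: DimensionSet
    couch_top_kind: str
    ers_attached: bool

    def __post_init__(self) -> None:
        kinds = [c.kind for c in self.components]
        if kinds.count("couch_top") != 1:
            raise ValueError("model must contain exactly one couch_top")
        if (kinds.count("range_shifter") == 1) != self.ers_attached:
            raise ValueError("model contains a range_shifter iff ers_attached")

    def component(self, name_or_kind: str) -> MachineComponent:
        for c in self.components:
            if c.name == name_or_kind or c.kind == name_or_kind:
                return c
        raise KeyError(name_or_kind)

    def by_frame(self, frame: str):
        return [c for c in self.components if c.frame == frame]


# ---------------------------------------------------------------------------
# tessellation helpers (deterministic)
# ---------------------------------------------------------------------------

def _sections(radius: float, chord: float) -> int:
    """Facet count keeping the sagitta (chord deviation) below ``chord``."""
    if chord >= radius:
        return 8
    n = int(np.ceil(np.pi / np.arccos(1.0 - chord / radius)))
    return max(n, 8)


def _cylinder(radius, z0, z1, chord) -> trimesh.Trimesh:
    m = trimesh.creation.cylinder(radius=radius, height=z1 - z0, sections=_sections(radius, chord))
    m.apply_translation([0, 0, 0.5 * (z0 + z1)])
    return m


def _box(extents, center) -> trimesh.Trimesh:
    m = trimesh.creation.box(extents)
    m.apply_translation(center)
    return m


def _annulus(r_min, r_max, z0, z1, chord) -> trimesh.Trimesh:
    m = trimesh.creation.annulus(
        r_min=r_min, r_max=r_max, height=z1 - z0, sections=_sections(r_max, chord)
    )
    m.apply_translation([0, 0, 0.5 * (z0 + z1)])
    return m


def _frustum(p0, r0, p1, r1, sections: int) -> trimesh.Trimesh:
    """Watertight capped frustum from disc (p0, r0) to disc (p1, r1)."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    if length < 1e-9:
        raise ValueError("degenerate frustum: coincident end points")
    w = axis / length
    u = np.cross(w, [0.0, 0.0, 1.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(w, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    ang = np.linspace(0.0, 2 * np.pi, sections, endpoint=False)
    ring = np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v
    verts = np.vstack([p0 + r0 * ring, p1 + r1 * ring, p0, p1])
    c0, c1 = 2 * sections, 2 * sections + 1
    faces = []
    for i in range(sections):
        j = (i + 1) % sections
        faces.append([i, j, sections + i])
        faces.append([j, sections + j, sections + i])
        faces.append([c0, j, i])  # bottom cap, normal along -w
        faces.append([c1, sections + i, sections + j])  # top cap, normal +w
    m = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
    if m.volume < 0:
        m.invert()
    return m


# ---------------------------------------------------------------------------
# component builders
# ---------------------------------------------------------------------------

def _build_gantry_head(d: DimensionSet) -> MachineComponent:
    # two-part head: narrow nozzle snout with the beam exit face closest to
    # the isocenter, wide casing behind it (two closed shells, 1 mm apart)
    z0 = d.nozzle_face_to_iso
    snout = _cylinder(d.snout_radius, z0, z0 + d.snout_length, d.chord_tolerance)
    casing = _cylinder(
        d.head_casing_radius,
        z0 + d.snout_length + 1.0,
        z0 + d.snout_length + 1.0 + d.head_casing_depth,
        d.chord_tolerance,
    )
    mesh = trimesh.util.concatenate([snout, casing])
    return MachineComponent("gantry_head", "gantry_head", mesh, "gantry-rotating")


def _build_gantry_body(d: DimensionSet) -> MachineComponent:
    # rotating drum coaxial with the gantry rotation axis (room +y), set back
    # behind the treatment area; rotation about its own axis keeps it there
    mesh = _cylinder(2000.0, 1500.0, 2700.0, d.chord_tolerance)
    mesh.apply_transform(
        trimesh.transformations.rotation_matrix(-np.pi / 2.0, [1.0, 0.0, 0.0])
    )
    return MachineComponent("gantry_body", "gantry_body", mesh, "gantry-rotating")


def _build_touch_guard(d: DimensionSet) -> MachineComponent:
    # thin collision skirt around the snout, protruding toward the isocenter
    z0 = d.nozzle_face_to_iso - d.touch_guard_standoff
    mesh = _annulus(
        d.snout_radius + 5.0,
        d.snout_radius + 30.0,
        z0,
        d.nozzle_face_to_iso + 100.0,
        d.chord_tolerance,
    )
    return MachineComponent("touch_guard", "touch_guard", mesh, "gantry-rotating")


def _build_range_shifter(d: DimensionSet) -> MachineComponent:
    # insertable slab attached to the nozzle exit, downstream face closest to iso
    thickness = d.nozzle_face_to_iso - d.ers_face_to_iso
    mesh = _box((450.0, 450.0, thickness), (0, 0, d.ers_face_to_iso + 0.5 * thickness))
    return MachineComponent("range_shifter", "range_shifter", mesh, "gantry-rotating")


def _build_couch_top(d: DimensionSet, kind: str) -> MachineComponent:
    # local origin at the junction (inferior) end, top surface center; the
    # extension spans local +y (patient superior) with a symmetric margin
    ct = d.couch_tops[kind]
    m = d.longitudinal_safety_margin
    length = ct.length + 2.0 * m
    mesh = _box(
        (ct.width, length, ct.thickness),
        (0.0, 0.5 * length - m, -0.5 * ct.thickness),
    )
    return MachineComponent(f"couch_top_{kind}", "couch_top", mesh, "couch-mounted")


def _build_pps_lower(d: DimensionSet) -> MachineComponent:
    col_h, l1, _, _ = d.arm_link_lengths
    # local origin at the shoulder pivot; column drops to the floor below it
    column = _box((500.0, 500.0, col_h), (0.0, 0.0, -0.5 * col_h - 1.0))
    arm = _box((l1, 250.0, 180.0), (0.5 * l1, 0.0, 0.0))
    mesh = trimesh.util.concatenate([column, arm])
    return MachineComponent("pps_base_lower_arm", "pps_base_lower_arm", mesh, "pps-articulated")


def _build_pps_upper(d: DimensionSet) -> MachineComponent:
    _, _, l2, knuckle = d.arm_link_lengths
    arm = _box((l2, 250.0, 180.0), (0.5 * l2, 0.0, 0.0))
    kn = _box((knuckle, 300.0, 260.0), (l2 + 1.0 + 0.5 * knuckle, 0.0, 0.0))
    mesh = trimesh.util.concatenate([arm, kn])
    return MachineComponent("pps_upper_arm_knuckle", "pps_upper_arm_knuckle", mesh, "pps-articulated")


def build_kv_fields(dimensions: DimensionSet):
    """Two room-fixed oblique kV imaging cones, source to detector plane.

    The cones pass through the isocenter region and are flagged
    obstruction-only: they never contribute to collision pass/fail status.
    """
    comps = []
    for i, (src, det) in enumerate(
        zip(dimensions.kv_source_positions, dimensions.kv_detector_centers), start=1
    ):
        if np.linalg.norm(np.asarray(src) - np.asarray(det)) < 1e-6:
            raise ValueError(f"kV pair {i}: source and detector coincide")
        mesh = _frustum(src, 20.0, det, 250.0, _sections(250.0, dimensions.chord_tolerance))
        comps.append(
            MachineComponent(f"kv_field_{i}", "kv_field", mesh, "room-fixed", obstruction_only=True)
        )
    return comps


def build_machine(
    dimensions: DimensionSet | None = None,
    couch_top_kind: str = "civco",
    ers_attached: bool = False,
    include_kv: bool = False,
) -> MachineModel:
    """Assemble the full machine model from a dimension set.

    The kV imaging cones are optional (``include_kv``) since they are
    obstruction-visualization surfaces, not collision hazards.  Raises
    :class:`DimensionError` naming the offending field for invalid
    dimensions, and ``KeyError`` for an unknown couch-top kind.
    """
    d = dimensions or DimensionSet()
    if couch_top_kind not in d.couch_tops:
        raise KeyError(
            f"unknown couch top kind {couch_top_kind!r}; have {sorted(d.couch_tops)}"
        )
    comps = [
        _build_gantry_body(d),
        _build_gantry_head(d),
        _build_touch_guard(d),
        _build_couch_top(d, couch_top_kind),
        _build_pps_lower(d),
        _build_pps_upper(d),
    ]
    if include_kv:
        comps.extend(build_kv_fields(d))
    if ers_attached:
        comps.insert(3, _build_range_shifter(d))
    return MachineModel(tuple(comps), d, couch_top_kind, ers_attached)


def attach_range_shifter(model: MachineModel) -> MachineModel:
    """Insert the extended range shifter; idempotent."""
    if model.ers_attached:
        return model
    comps = list(model.components)
    comps.insert(3, _build_range_shifter(model.dimensions))
    return MachineModel(tuple(comps), model.dimensions, model.couch_top_kind, True)


# ---------------------------------------------------------------------------
# dimension self-check
# ---------------------------------------------------------------------------

def validate_dimensions(model: MachineModel, tolerance_mm: float = 1.0):
    """Re-measure key distances from the meshes and compare to the config.

    Mirrors the in-room tape-measure validation one would perform on the real
    machine: nozzle face to isocenter, ERS face to isocenter, couch-top
    dimensions, and the isocenter-to-PPS-base distance.  Returns a list of
    ``{name, expected_mm, measured_mm, passed}`` dicts; mismatches are
    reported, never raised.
    """
    d = model.dimensions
    origin = np.zeros(3)
    checks = []

    def add(name, expected, measured):
        checks.append(
            {
                "name": name,
                "expected_mm": float(expected),
                "measured_mm": float(measured),
                "passed": bool(abs(expected - measured) <= tolerance_mm),
            }
        )

    head = model.component("gantry_head").mesh
    add("nozzle_face_to_iso", d.nozzle_face_to_iso, point_mesh_distance(origin, head))
    add("head_total_length", d.snout_length + 1.0 + d.head_casing_depth, head.extents[2])
    add("head_casing_radius", d.head_casing_radius, 0.5 * head.extents[0])
    if model.ers_attached:
        ers = model.component("range_shifter").mesh
        add("ers_face_to_iso", d.ers_face_to_iso, point_mesh_distance(origin, ers))
    couch = model.component("couch_top").mesh
    ct = d.couch_tops[model.couch_top_kind]
    add("couch_top_length", ct.length + 2 * d.longitudinal_safety_margin, couch.extents[1])
    add("couch_top_width", ct.width, couch.extents[0])
    add("couch_top_thickness", ct.thickness, couch.extents[2])

    # horizontal distance from isocenter to the nearest face of the base column
    bx, by, _ = d.base_position
    ex = max(abs(bx) - 250.0, 0.0)
    ey = max(abs(by) - 250.0, 0.0)
    expected_base = float(np.hypot(ex, ey))
    lower = model.component("pps_base_lower_arm").mesh
    col_h = d.arm_link_lengths[0]
    # pose the assembly at home (shoulder above the base), keep the column part
    verts = lower.vertices.view(np.ndarray)
    column = verts[verts[:, 2] < -0.5] + np.array([bx, by, d.base_position[2] + col_h])
    lo, hi = column[:, :2].min(axis=0), column[:, :2].max(axis=0)
    closest = np.clip(np.zeros(2), lo, hi)
    add("base_to_iso", expected_base, float(np.linalg.norm(closest)))
    return checks


def export_component(component: MachineComponent, path: str) -> None:
    """Write a component mesh to STL or OBJ, chosen by file extension."""
    component.mesh.export(path)


def export_component_bytes(component: MachineComponent, file_type: str = "stl") -> bytes:
    buf = io.BytesIO()
    component.mesh.export(buf, file_type=file_type)
    return buf.getvalue()
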