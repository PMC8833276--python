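"""File formats: machine config, plan files, contour files, RT-STRUCT input.

All formats are plain text and versioned:

* machine config — YAML, mm units, schema ``gantryclear-machine/1``;
* plan file — YAML or JSON, schema ``gantryclear-plan/1``;
* contour file — a simple per-slice polygon listing (see
  :func:`write_contours` for the layout), used for fixtures and as the
  lightweight alternative to DICOM RT-STRUCT;
* RT-STRUCT — the CLOSED_PLANAR subset of DICOM structure sets, read with
  pydicom.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .kinematics import BeamConfig, PlanContext, SixDofCorrection
from .machine import CouchTopDims, DimensionSet
from .patient import Contour, StructureMesh, StructureSet, contours_to_mesh, infer_role

__all__ = [
    "PlanParseError",
    "read_machine_config",
    "write_machine_config",
    "read_plan",
    "write_plan",
    "read_contours",
    "write_contours",
    "read_rtstruct",
    "write_scenario_bundle",
]

MACHINE_SCHEMA = "gantryclear-machine/1"
PLAN_SCHEMA = "gantryclear-plan/1"


class PlanParseError(ValueError):
    """Schema violation in a plan/machine/contour file, with a field path."""


# ---------------------------------------------------------------------------
# machine config
# ---------------------------------------------------------------------------

def _dimensions_to_dict(d: DimensionSet) -> dict:
    return {
        "schema": MACHINE_SCHEMA,
        "units": "mm",
        "nozzle_face_to_iso": d.nozzle_face_to_iso,
        "ers_face_to_iso": d.ers_face_to_iso,
        "snout_radius": d.snout_radius,
        "snout_length": d.snout_length,
        "head_casing_radius": d.head_casing_radius,
        "head_casing_depth": d.head_casing_depth,
        "touch_guard_standoff": d.touch_guard_standoff,
        "couch_tops": {
            k: {"length": v.length, "width": v.width, "thickness": v.thickness}
            for k, v in d.couch_tops.items()
        },
        "arm_link_lengths": list(d.arm_link_lengths),
        "base_position": list(d.base_position),
        "kv_source_positions": [list(p) for p in d.kv_source_positions],
        "kv_detector_centers": [list(p) for p in d.kv_detector_centers],
        "longitudinal_safety_margin": d.longitudinal_safety_margin,
        "chord_tolerance": d.chord_tolerance,
    }


def write_machine_config(dims: DimensionSet, path) -> None:
    Path(path).write_text(yaml.safe_dump(_dimensions_to_dict(dims), sort_keys=False))


def read_machine_config(path) -> DimensionSet:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise PlanParseError(f"{path}: machine config must be a mapping")
    schema = data.pop("schema", MACHINE_SCHEMA)
    if schema != MACHINE_SCHEMA:
        raise PlanParseError(f"{path}: unsupported machine schema {schema!r}")
    data.pop("units", None)
    try:
        couch_tops = {
            k: CouchTopDims(v["length"], v["width"], v["thickness"])
            for k, v in data.pop("couch_tops", {}).items()
        } or None
        kwargs = dict(data)
        if couch_tops:
            kwargs["couch_tops"] = couch_tops
        for key in ("arm_link_lengths", "base_position"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        for key in ("kv_source_positions", "kv_detector_centers"):
            if key in kwargs:
                kwargs[key] = tuple(tuple(p) for p in kwargs[key])
        return DimensionSet(**kwargs)
    except (KeyError, TypeError) as exc:
        raise PlanParseError(f"{path}: invalid machine config: {exc}") from exc


# ---------------------------------------------------------------------------
# plan files
# ---------------------------------------------------------------------------

def _require(data: dict, key: str, path: str):
    if key not in data:
        raise PlanParseError(f"{path}: missing required field '{key}'")
    return data[key]


def read_plan(path):
    """Read a plan file; returns ``(PlanContext, sixdof_by_beam, warnings)``.

    All schema and unit checks happen at parse time; a beam with a gantry
    angle outside the half-gantry arc is parsed with a warning (the check
    later reports it as ``invalid_gantry_angle`` rather than failing here).
    """
    p = Path(path)
    text = p.read_text()
    data = json.loads(text) if p.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise PlanParseError(f"{path}: plan must be a mapping")
    schema = data.get("schema", PLAN_SCHEMA)
    if schema != PLAN_SCHEMA:
        raise PlanParseError(f"{path}: unsupported plan schema {schema!r}")
    jct = _require(data, "jct_cm", str(path))
    beams_raw = _require(data, "beams", str(path))
    if not isinstance(beams_raw, list) or not beams_raw:
        raise PlanParseError(f"{path}: beams must be a non-empty list")

    from .kinematics import is_gantry_angle_allowed

    warnings = []
    beams = []
    sixdof_by_beam = {}
    for i, b in enumerate(beams_raw):
        loc = f"{path}: beams[{i}]"
        try:
            beam = BeamConfig(
                beam_id=str(_require(b, "id", loc)),
                gantry_angle=float(_require(b, "gantry_deg", loc)),
                couch_angle=float(_require(b, "couch_deg", loc)),
                isocenter_ct=tuple(b.get("isocenter_ct_mm", (0.0, 0.0, 0.0))),
                ers_required=bool(b.get("ers", False)),
            )
        except ValueError as exc:
            raise PlanParseError(f"{loc}: {exc}") from exc
        if not is_gantry_angle_allowed(beam.gantry_angle):
            warnings.append(
                f"beam {beam.beam_id!r}: gantry angle {beam.gantry_angle:g} is outside "
                "the half-gantry arc; it will be reported as invalid_gantry_angle"
            )
        if "sixdof" in b:
            s = b["sixdof"]
            try:
                sixdof_by_beam[beam.beam_id] = SixDofCorrection(
                    yaw=float(s.get("yaw", 0)), pitch=float(s.get("pitch", 0)),
                    roll=float(s.get("roll", 0)), dx=float(s.get("dx", 0)),
                    dy=float(s.get("dy", 0)), dz=float(s.get("dz", 0)),
                )
            except ValueError as exc:
                raise PlanParseError(f"{loc}.sixdof: {exc}") from exc
        beams.append(beam)
    try:
        ctx = PlanContext(
            jct_cm=float(jct),
            beams=tuple(beams),
            couch_top_kind=str(data.get("couch_top", "civco")),
            patient_orientation=str(data.get("orientation", "head-first-supine")),
            couch_surface_y_ct=float(data.get("couch_surface_y_ct", 0.0)),
        )
    except ValueError as exc:
        raise PlanParseError(f"{path}: {exc}") from exc
    return ctx, sixdof_by_beam, warnings


def write_plan(ctx: PlanContext, path, patient_id: str = "anon",
               sixdof_by_beam: dict | None = None) -> None:
    data = {
        "schema": PLAN_SCHEMA,
        "patient_id": patient_id,
        "jct_cm": ctx.jct_cm,
        "couch_top": ctx.couch_top_kind,
        "orientation": ctx.patient_orientation,
        "couch_surface_y_ct": ctx.couch_surface_y_ct,
        "beams": [
            {
                "id": b.beam_id,
                "gantry_deg": b.gantry_angle,
                "couch_deg": b.couch_angle,
                "isocenter_ct_mm": list(b.isocenter_ct),
                "ers": b.ers_required,
                **(
                    {"sixdof": vars_sixdof(sixdof_by_beam[b.beam_id])}
                    if sixdof_by_beam and b.beam_id in sixdof_by_beam
                    else {}
                ),
            }
            for b in ctx.beams
        ],
    }
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(data, indent=2))
    else:
        p.write_text(yaml.safe_dump(data, sort_keys=False))


def vars_sixdof(s: SixDofCorrection) -> dict:
    return {k: getattr(s, k) for k in ("yaw", "pitch", "roll", "dx", "dy", "dz")}


# ---------------------------------------------------------------------------
# contour files
# ---------------------------------------------------------------------------

def write_contours(structures_contours: dict, path) -> None:
    """Write ``{name: (role, [Contour, ...])}`` to the plain contour format::

        # gantryclear contours v1
        structure Body role=body
        slice 0.0
        -10.0 0.0
        ...
    """
    lines = ["# gantryclear contours v1"]
    for name, (role, contours) in structures_contours.items():
        lines.append(f"structure {name} role={role}")
        for c in contours:
            lines.append(f"slice {c.plane_z:g}")
            for x, y in c.points:
                lines.append(f"{x:.4f} {y:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_contours(path) -> dict:
    """Read the plain contour format back to ``{name: (role, [Contour...])}``."""
    out: dict = {}
    name = role = None
    plane_z = None
    points: list = []
    contours: list = []

    def flush_slice():
        nonlocal points, plane_z
        if plane_z is not None and points:
            contours.append(Contour(plane_z, np.array(points)))
        points = []
        plane_z = None

    def flush_structure():
        nonlocal contours
        flush_slice()
        if name is not None:
            out[name] = (role, contours)
        contours = []

    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("structure "):
            flush_structure()
            parts = line.split()
            name = parts[1]
            role = "infer"
            for tok in parts[2:]:
                if tok.startswith("role="):
                    role = tok[5:]
        elif line.startswith("slice "):
            flush_slice()
            plane_z = float(line.split()[1])
        else:
            try:
                x, y = line.split()
                points.append((float(x), float(y)))
            except ValueError as exc:
                raise PlanParseError(f"{path}:{ln}: bad contour point {line!r}") from exc
    flush_structure()
    return out


def structures_from_contours(named_contours: dict) -> StructureSet:
    """Mesh a ``{name: (role, contours)}`` mapping into a StructureSet."""
    structures = []
    warnings = []
    for name, (role, contours) in named_contours.items():
        if role in (None, "infer"):
            role = infer_role(name)
        structures.append(StructureMesh(name, role, contours_to_mesh(contours)))
    if not any(s.role == "body" for s in structures):
        warnings.append("no body/external structure found in contour input")
    return StructureSet(tuple(structures), warnings=tuple(warnings))


def load_structure_set(path) -> StructureSet:
    """Load structures from a plain contour file or a DICOM RT-STRUCT."""
    p = Path(path)
    if p.suffix.lower() == ".dcm":
        return read_rtstruct(p)
    return structures_from_contours(read_contours(p))


# ---------------------------------------------------------------------------
# DICOM RT-STRUCT subset
# ---------------------------------------------------------------------------

def read_rtstruct(path) -> StructureSet:
    """Read the CLOSED_PLANAR subset of a DICOM RT-STRUCT file.

    Every ROI becomes one structure; roles are inferred from ROI names with
    the configurable pattern map.  Axial CLOSED_PLANAR contours only; other
    geometric types are skipped with a warning.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    roi_names = {
        int(r.ROINumber): str(r.ROIName) for r in getattr(ds, "StructureSetROISequence", [])
    }
    structures = []
    warnings = []
    for roi in getattr(ds, "ROIContourSequence", []):
        number = int(roi.ReferencedROINumber)
        name = roi_names.get(number, f"ROI{number}")
        contours = []
        for c in getattr(roi, "ContourSequence", []):
            if getattr(c, "ContourGeometricType", "CLOSED_PLANAR") != "CLOSED_PLANAR":
                warnings.append(f"{name}: skipped non-planar contour")
                continue
            pts = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            contours.append(Contour(float(pts[0, 2]), pts[:, :2]))
        if contours:
            structures.append(StructureMesh(name, infer_role(name), contours_to_mesh(contours)))
    if not any(s.role == "body" for s in structures):
        warnings.append("no body/external structure found in RT-STRUCT")
    return StructureSet(tuple(structures), warnings=tuple(warnings))


# ---------------------------------------------------------------------------
# scenario bundles
# ---------------------------------------------------------------------------

def write_scenario_bundle(scenario, directory) -> dict:
    """Write a fixture scenario to disk as machine config + plan + manifest.

    The contour file is regenerated from the scenario's structure meshes by
    slicing them back to planar sections, so the bundle is fully text-based
    and end-to-end loadable by the CLI.  Returns the file path mapping.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    machine_path = d / "machine.yaml"
    plan_path = d / "plan.yaml"
    contour_path = d / "contours.txt"
    manifest_path = d / "manifest.json"

    write_machine_config(scenario.machine.dimensions, machine_path)
    write_plan(scenario.ctx, plan_path, patient_id=scenario.name)

    named = {}
    for s in scenario.structures:
        named[s.name] = (s.role, _mesh_to_contours(s.mesh))
    write_contours(named, contour_path)

    manifest = {
        "name": scenario.name,
        "site": scenario.site,
        "couch_top": scenario.machine.couch_top_kind,
        "ers_attached": scenario.machine.ers_attached,
        "expected_outcome": scenario.expected_outcome,
        "expected_type": scenario.expected_type,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return {
        "machine": str(machine_path),
        "plan": str(plan_path),
        "contours": str(contour_path),
        "manifest": str(manifest_path),
    }


def _mesh_to_contours(mesh, max_slices: int = 40) -> list:
    """Slice a mesh back into planar contours (for bundle export)."""
    lo, hi = mesh.bounds[:, 2]
    zs = np.linspace(lo + 1.0, hi - 1.0, min(max_slices, max(2, int((hi - lo) / 25.0))))
    contours = []
    for z in zs:
        section = mesh.section(plane_origin=[0, 0, z], plane_normal=[0, 0, 1])
        if section is None:
            continue
        for poly in section.discrete:
            pts = np.asarray(poly)[:, :2]
            if len(pts) >= 3:
                contours.append(Contour(float(z), pts))
    if len({c.plane_z for c in contours}) < 2:
        raise ValueError("mesh slicing produced fewer than 2 contour planes")
    return contours
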