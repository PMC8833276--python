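"""Per-beam and per-plan collision evaluation and feasibility sweeps.

A beam check poses the machine (gantry rotation), the couch/PPS (couch
rotation + JCT indexing + arm solve) and the patient structures, then
evaluates the minimum clearance of every monitored component pair:

* gantry-side hazards: gantry head casing, touch guard, and the range
  shifter when attached;
* obstacles: couch top (type 1), patient body (type 2), the two PPS arm
  assemblies (type 3), immobilization and bolus devices (type 4).

Status per beam: ``fail`` on any mesh contact/overlap, ``warn`` when the
minimum clearance falls below the 3-cm buffer margin (a physical
angle check on the machine is then advised), ``pass`` otherwise, and
``invalid_gantry_angle`` for beams outside the half-gantry arc.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import trimesh

from . import __version__
from .collision import ClearancePair, classify_pair, intersects, min_distance
from .kinematics import (
    BeamConfig,
    IndexingError,
    PlanContext,
    ReachabilityError,
    SixDofCorrection,
    couch_top_transform,
    gantry_transform,
    is_gantry_angle_allowed,
    patient_to_room_transform,
    solve_pps_pose,
)
from .machine import MachineModel, build_kv_fields
from .patient import StructureSet
from .transforms import RigidTransform

__all__ = [
    "Thresholds",
    "ClearanceResult",
    "PlanCheckReport",
    "FeasibilityMap",
    "ConfigurationError",
    "check_beam",
    "check_plan",
    "sweep_feasibility",
    "check_kv_obstruction",
    "pose_scene",
]

STATUS_SEVERITY = {"pass": 0, "warn": 1, "fail": 2, "invalid_gantry_angle": 3}


class ConfigurationError(ValueError):
    """Inconsistent plan/machine combination (e.g. ERS required but absent)."""


@dataclass(frozen=True)
class Thresholds:
    """Clearance thresholds in mm.

    ``warn_below`` defaults to 30 mm (the 3-cm buffer margin below which a
    physical angle check is advised); ``fail_at`` defaults to 0, i.e. a beam
    fails only on actual mesh contact or overlap.
    """

    fail_at: float = 0.0
    warn_below: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fail_at < self.warn_below:
            raise ValueError("thresholds must satisfy 0 <= fail_at < warn_below")


@dataclass(frozen=True)
class ClearanceResult:
    beam_id: str
    status: str
    min_clearance: float | None = None
    worst_pair: ClearancePair | None = None
    all_pairs_below_warn: tuple = ()

    def to_dict(self) -> dict:
        def pair_dict(p):
            return {
                "component_a": p.component_a,
                "component_b": p.component_b,
                "distance_mm": round(p.distance, 6),
                "point_a": [round(float(v), 4) for v in p.point_a],
                "point_b": [round(float(v), 4) for v in p.point_b],
                "collision_type": p.type.name if p.type else None,
            }

        return {
            "beam_id": self.beam_id,
            "status": self.status,
            "min_clearance_mm": None if self.min_clearance is None else round(self.min_clearance, 6),
            "worst_pair": pair_dict(self.worst_pair) if self.worst_pair else None,
            "pairs_below_warn": [pair_dict(p) for p in self.all_pairs_below_warn],
        }


@dataclass(frozen=True)
class PlanCheckReport:
    beam_results: tuple
    verdict: str
    angle_check_beams: tuple
    kv_obstructions: tuple
    errors: tuple
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "beams": [r.to_dict() for r in self.beam_results],
            "angle_check_beams": list(self.angle_check_beams),
            "kv_obstructions": [list(t) for t in self.kv_obstructions],
            "errors": [list(e) for e in self.errors],
            "provenance": self.provenance,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_text(self) -> str:
        lines = [f"Plan verdict: {self.verdict.upper()}", ""]
        lines.append(f"{'beam':<12} {'status':<22} {'clearance mm':>12}  worst pair")
        for r in self.beam_results:
            clr = "-" if r.min_clearance is None else f"{r.min_clearance:.1f}"
            wp = ""
            if r.worst_pair:
                t = r.worst_pair.type.name if r.worst_pair.type else "?"
                wp = f"{r.worst_pair.component_a} vs {r.worst_pair.component_b} ({t})"
            lines.append(f"{r.beam_id:<12} {r.status:<22} {clr:>12}  {wp}")
        if self.angle_check_beams:
            lines.append("")
            lines.append("Beams requiring a physical angle check (< 3 cm clearance): "
                         + ", ".join(self.angle_check_beams))
        for beam_id, msg in self.errors:
            lines.append(f"ERROR [{beam_id}]: {msg}")
        return "\n".join(lines)


@dataclass(frozen=True)
class FeasibilityMap:
    """Gantry x couch grid of clearance summaries at a fixed isocenter."""

    gantry_grid: tuple
    couch_grid: tuple
    cells: dict  # (gantry, couch) -> {"status": str, "min_clearance_mm": float}

    def to_csv(self) -> str:
        lines = ["gantry_deg,couch_deg,status,clearance_mm"]
        for (g, t), cell in sorted(self.cells.items()):
            clr = cell["min_clearance_mm"]
            lines.append(f"{g:g},{t:g},{cell['status']},{'' if clr is None else f'{clr:.3f}'}")
        return "\n".join(lines) + "\n"

    def to_png(self, path: str) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        gs = sorted(self.gantry_grid)
        ts = sorted(self.couch_grid)
        grid = np.full((len(ts), len(gs)), np.nan)
        for (g, t), cell in self.cells.items():
            if cell["min_clearance_mm"] is not None:
                grid[ts.index(t), gs.index(g)] = cell["min_clearance_mm"]
        fig, ax = plt.subplots(figsize=(9, 3 + 0.3 * len(ts)))
        im = ax.imshow(grid, aspect="auto", origin="lower", cmap="RdYlGn",
                       extent=(min(gs), max(gs), min(ts) - 5, max(ts) + 5))
        ax.set_xlabel("gantry angle (deg)")
        ax.set_ylabel("couch angle (deg)")
        fig.colorbar(im, ax=ax, label="min clearance (mm)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# scene posing
# ---------------------------------------------------------------------------

def _posed(mesh: trimesh.Trimesh, xf: RigidTransform) -> trimesh.Trimesh:
    out = mesh.copy()
    out.vertices = xf.apply(out.vertices.view(np.ndarray))
    return out


def pose_scene(
    machine: MachineModel,
    patient: StructureSet,
    ctx: PlanContext,
    beam: BeamConfig,
    sixdof: SixDofCorrection | None = None,
):
    """Pose every scene element for one beam.

    Returns ``(hazards, obstacles)``: lists of ``(name, kind_or_role, mesh)``
    in room coordinates.  Raises kinematics errors (indexing, reachability)
    and :class:`ConfigurationError` for an ERS-requiring beam on a machine
    without the range shifter.
    """
    if beam.ers_required and not machine.ers_attached:
        raise ConfigurationError(
            f"beam {beam.beam_id!r} requires the range shifter but the machine "
            "model has none attached"
        )
    g_xf = gantry_transform(beam.gantry_angle)
    hazards = [
        (c.name, c.kind, _posed(c.mesh, g_xf))
        for c in machine.by_frame("gantry-rotating")
        if c.kind in ("gantry_head", "touch_guard", "range_shifter")
    ]

    couch_xf = couch_top_transform(ctx, beam, machine.dimensions, sixdof)
    pps = solve_pps_pose(couch_xf, machine.dimensions, ctx.couch_top_kind)
    obstacles = [
        (
            machine.component("couch_top").name,
            "couch_top",
            _posed(machine.component("couch_top").mesh, couch_xf),
        )
    ]
    for kind in ("pps_base_lower_arm", "pps_upper_arm_knuckle"):
        obstacles.append((kind, kind, _posed(machine.component(kind).mesh, pps[kind])))

    pat_xf = patient_to_room_transform(ctx, beam, sixdof)
    for s in patient:
        if s.role in ("body", "immobilization", "bolus_device"):
            obstacles.append((s.name, s.role, _posed(s.mesh, pat_xf)))
    return hazards, obstacles


# ---------------------------------------------------------------------------
# checks
# ---------------------------------------------------------------------------

def check_beam(
    machine: MachineModel,
    patient: StructureSet,
    ctx: PlanContext,
    beam: BeamConfig,
    sixdof: SixDofCorrection | None = None,
    thresholds: Thresholds = Thresholds(),
    cutoff: float = 100.0,
) -> ClearanceResult:
    """Evaluate all monitored pairs for one beam and classify the result.

    Deterministic for fixed inputs.  Distances above ``cutoff`` (mm) may be
    reported as the closest-vertex-pair distance instead of the exact
    surface distance; the cutoff always exceeds the warn threshold, so the
    status itself is exact.
    """
    if not is_gantry_angle_allowed(beam.gantry_angle):
        return ClearanceResult(beam.beam_id, "invalid_gantry_angle")
    cutoff = max(cutoff, thresholds.warn_below + 10.0)

    hazards, obstacles = pose_scene(machine, patient, ctx, beam, sixdof)
    pairs = []
    for name_a, kind_a, mesh_a in hazards:
        for name_b, kind_b, mesh_b in obstacles:
            d, pa, pb = min_distance(mesh_a, mesh_b, cutoff=cutoff)
            pairs.append(
                ClearancePair(name_a, name_b, d, pa, pb, classify_pair(kind_a, kind_b))
            )
    pairs.sort(key=lambda p: (p.distance, p.component_a, p.component_b))
    worst = pairs[0]
    below = tuple(p for p in pairs if p.distance < thresholds.warn_below)
    if worst.distance <= thresholds.fail_at:
        status = "fail"
    elif worst.distance < thresholds.warn_below:
        status = "warn"
    else:
        status = "pass"
    return ClearanceResult(beam.beam_id, status, worst.distance, worst, below)


def check_kv_obstruction(
    machine: MachineModel,
    ctx: PlanContext,
    beam: BeamConfig,
    sixdof: SixDofCorrection | None = None,
):
    """Which machine components block the stereoscopic kV imaging cones.

    Informational only: results never alter a beam's pass/warn/fail status,
    and patient structures are not considered.
    """
    if not is_gantry_angle_allowed(beam.gantry_angle):
        return []
    kv = [c for c in machine.components if c.kind == "kv_field"]
    if not kv:
        kv = build_kv_fields(machine.dimensions)
    g_xf = gantry_transform(beam.gantry_angle)
    movers = [
        (c.name, _posed(c.mesh, g_xf))
        for c in machine.by_frame("gantry-rotating")
    ]
    couch_xf = couch_top_transform(ctx, beam, machine.dimensions, sixdof)
    pps = solve_pps_pose(couch_xf, machine.dimensions, ctx.couch_top_kind)
    for kind in ("pps_base_lower_arm", "pps_upper_arm_knuckle"):
        movers.append((kind, _posed(machine.component(kind).mesh, pps[kind])))
    out = []
    for cone in kv:
        for name, mesh in movers:
            if intersects(cone.mesh, mesh):
                out.append((cone.name, name))
    return out


def _config_hash(machine: MachineModel, ctx: PlanContext) -> str:
    payload = json.dumps(
        {
            "dimensions": str(machine.dimensions),
            "couch_top": machine.couch_top_kind,
            "ers": machine.ers_attached,
            "jct_cm": ctx.jct_cm,
            "orientation": ctx.patient_orientation,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def check_plan(
    machine: MachineModel,
    patient: StructureSet,
    ctx: PlanContext,
    thresholds: Thresholds = Thresholds(),
    sixdof_by_beam: dict | None = None,
    with_kv: bool = False,
) -> PlanCheckReport:
    """Run :func:`check_beam` over every beam and aggregate a plan verdict.

    Per-beam configuration problems (ERS missing, unreachable couch pose,
    junction off the couch) are recorded in the report's error list without
    aborting the remaining beams.  The plan verdict is the worst beam status
    (pass < warn < fail < invalid_gantry_angle); warn beams are listed for a
    physical angle check.
    """
    results = []
    errors = []
    kv_notes = []
    for beam in ctx.beams:
        sixdof = (sixdof_by_beam or {}).get(beam.beam_id)
        try:
            results.append(check_beam(machine, patient, ctx, beam, sixdof, thresholds))
            if with_kv:
                for cone, comp in check_kv_obstruction(machine, ctx, beam, sixdof):
                    kv_notes.append((beam.beam_id, cone, comp))
        except (ConfigurationError, IndexingError, ReachabilityError) as exc:
            errors.append((beam.beam_id, str(exc)))
    verdict = "pass"
    for r in results:
        if STATUS_SEVERITY[r.status] > STATUS_SEVERITY[verdict]:
            verdict = r.status
    angle_check = tuple(r.beam_id for r in results if r.status == "warn")
    provenance = {
        "package": "gantryclear",
        "version": __version__,
        "config_hash": _config_hash(machine, ctx),
        "thresholds_mm": {"fail_at": thresholds.fail_at, "warn_below": thresholds.warn_below},
    }
    return PlanCheckReport(tuple(results), verdict, angle_check, tuple(kv_notes), tuple(errors), provenance)


def sweep_feasibility(
    machine: MachineModel,
    patient: StructureSet,
    ctx: PlanContext,
    couch_grid,
    gantry_grid,
    thresholds: Thresholds = Thresholds(),
    isocenter_ct=None,
) -> FeasibilityMap:
    """Clearance status over a gantry x couch grid at the plan isocenter.

    Disallowed gantry angles are silently excluded from the grid.  Each cell
    is an independent beam check (six-DoF zero), so refining the grid never
    changes existing cells.  Cells whose couch pose is unreachable or whose
    junction indexing fails are marked with status ``error``.
    """
    iso = tuple(isocenter_ct) if isocenter_ct is not None else ctx.beams[0].isocenter_ct
    gantry_grid = tuple(g for g in gantry_grid if is_gantry_angle_allowed(g))
    cells = {}
    for t in couch_grid:
        for g in gantry_grid:
            beam = BeamConfig(f"G{g:g}T{t:g}", g, t, iso, ers_required=False)
            cell_ctx = PlanContext(
                ctx.jct_cm, (beam,), ctx.couch_top_kind, ctx.patient_orientation,
                ctx.couch_surface_y_ct,
            )
            try:
                r = check_beam(machine, patient, cell_ctx, beam, None, thresholds)
                cells[(g, t)] = {"status": r.status, "min_clearance_mm": r.min_clearance}
            except (ConfigurationError, IndexingError, ReachabilityError):
                cells[(g, t)] = {"status": "error", "min_clearance_mm": None}
    return FeasibilityMap(gantry_grid, tuple(couch_grid), cells)
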