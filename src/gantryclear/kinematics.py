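"""IEC-style rigid kinematics: gantry, couch, patient indexing, PPS solver.

Coordinate conventions (fixed for the whole package, see docs/methods.md):

* room frame: origin at the isocenter, ``+z`` up, ``+y`` the horizontal
  gantry rotation axis pointing from the couch toward the gantry (also the
  couch long axis at couch angle 0), ``+x`` right-handed completion;
* gantry angle 0 points the beam straight down from above; positive angles
  rotate the source from ``+z`` toward ``+x``; the half gantry allows
  0..185 and 355..360 degrees only;
* couch angle is a rotation about the vertical axis through the isocenter,
  positive counterclockwise viewed from above;
* CT coordinates are patient-based LPS (``+x`` patient left, ``+y``
  posterior, ``+z`` superior); head-first supine maps patient-superior to
  room ``+y`` and patient-posterior to room ``-z``;
* the JCT junction value is the distance from the couch extension
  connection junction to the CT origin along the couch long axis, given in
  cm at interfaces and converted to mm once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .machine import DimensionSet
from .transforms import RigidTransform, rot_x, rot_y, rot_z

__all__ = [
    "BeamConfig",
    "SixDofCorrection",
    "PlanContext",
    "GantryLimitError",
    "IndexingError",
    "ReachabilityError",
    "is_gantry_angle_allowed",
    "gantry_transform",
    "couch_transform",
    "patient_to_room_transform",
    "couch_top_transform",
    "solve_pps_pose",
    "CT_TO_COUCH_HFS",
]

GANTRY_ARC = (185.0, 355.0)  # allowed: [0, 185] U [355, 360)

# head-first supine: x_ct (patient left) -> +x, y_ct (posterior) -> -z,
# z_ct (superior) -> +y
CT_TO_COUCH_HFS = RigidTransform(
    np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, -1.0, 0.0]]), np.zeros(3)
)


class GantryLimitError(ValueError):
    """Gantry angle outside the half-gantry arc [355deg..185deg through 0]."""


class IndexingError(ValueError):
    """The JCT/isocenter combination places the junction off the couch."""


class ReachabilityError(ValueError):
    """The PPS arm cannot reach the requested couch mount point."""

    def __init__(self, message: str, shortfall_mm: float):
        super().__init__(message)
        self.shortfall_mm = shortfall_mm


@dataclass(frozen=True)
class SixDofCorrection:
    """Small rotational/translational setup corrections applied at the couch."""

    yaw: float = 0.0
    pitch: float = 0.0
    roll: float = 0.0
    dx: float = 0.0
    dy: float = 0.0
    dz: float = 0.0
    rotation_limit: float = 3.0  # degrees
    translation_limit: float = 50.0  # mm

    def __post_init__(self) -> None:
        for name in ("yaw", "pitch", "roll"):
            if abs(getattr(self, name)) > self.rotation_limit:
                raise ValueError(f"six-DoF {name} exceeds ±{self.rotation_limit} degrees")
        for name in ("dx", "dy", "dz"):
            if abs(getattr(self, name)) > self.translation_limit:
                raise ValueError(f"six-DoF {name} exceeds ±{self.translation_limit} mm")

    @property
    def is_zero(self) -> bool:
        return all(getattr(self, n) == 0.0 for n in ("yaw", "pitch", "roll", "dx", "dy", "dz"))


@dataclass(frozen=True)
class BeamConfig:
    """One treatment beam: gantry/couch angles, isocenter, range-shifter flag."""

    beam_id: str
    gantry_angle: float
    couch_angle: float
    isocenter_ct: tuple = (0.0, 0.0, 0.0)
    ers_required: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.gantry_angle < 360.0:
            raise ValueError("gantry_angle must be in [0, 360)")
        if not 0.0 <= self.couch_angle < 360.0:
            raise ValueError("couch_angle must be in [0, 360)")
        object.__setattr__(self, "isocenter_ct", tuple(float(v) for v in self.isocenter_ct))


@dataclass(frozen=True)
class PlanContext:
    """Plan-level context: JCT indexing, beams, couch top, orientation.

    ``couch_surface_y_ct`` is the CT y-coordinate of the couch-top surface
    plane (the plane the patient rests on); it ties the patient's posterior
    skin to the couch height.
    """

    jct_cm: float
    beams: tuple
    couch_top_kind: str = "civco"
    patient_orientation: str = "head-first-supine"
    couch_surface_y_ct: float = 0.0

    def __post_init__(self) -> None:
        if not self.jct_cm > 0:
            raise ValueError("jct_cm must be strictly positive")
        if len(self.beams) == 0:
            raise ValueError("plan must contain at least one beam")
        if self.patient_orientation != "head-first-supine":
            raise ValueError(
                f"unsupported patient orientation {self.patient_orientation!r}; "
                "only head-first-supine is handled"
            )
        object.__setattr__(self, "beams", tuple(self.beams))

    @property
    def jct_mm(self) -> float:
        return self.jct_cm * 10.0


def is_gantry_angle_allowed(angle: float) -> bool:
    """True iff ``angle`` lies on the half-gantry arc [355..185 through 0]."""
    if not 0.0 <= angle < 360.0:
        raise ValueError("gantry angle must be in [0, 360)")
    return angle <= GANTRY_ARC[0] or angle >= GANTRY_ARC[1]


def gantry_transform(angle: float) -> RigidTransform:
    """Rotation of gantry-fixed components for gantry angle ``angle``."""
    if not is_gantry_angle_allowed(angle):
        raise GantryLimitError(
            f"gantry angle {angle} outside the half-gantry arc "
            f"[{GANTRY_ARC[1]}..360) U [0..{GANTRY_ARC[0]}]"
        )
    return rot_y(angle)


def couch_transform(couch_angle: float, sixdof: SixDofCorrection | None = None) -> RigidTransform:
    """Couch yaw about the vertical axis composed with six-DoF corrections.

    Six-DoF rotations compose yaw -> pitch -> roll about room axes through
    the isocenter, applied after the couch rotation; translations are in
    room coordinates.
    """
    xf = rot_z(couch_angle)
    if sixdof is not None and not sixdof.is_zero:
        # yaw applied first, then pitch, then roll, about room axes
        rot = (rot_x(sixdof.roll) @ rot_y(sixdof.pitch) @ rot_z(sixdof.yaw)).rotation
        corr = RigidTransform(rot, np.array([sixdof.dx, sixdof.dy, sixdof.dz]))
        xf = corr @ xf
    return xf


def patient_to_room_transform(
    ctx: PlanContext, beam: BeamConfig, sixdof: SixDofCorrection | None = None
) -> RigidTransform:
    """CT -> room transform placing ``beam.isocenter_ct`` at the room origin.

    The couch junction sits ``jct`` from the CT origin along the patient
    superior axis; after the move it must still lie over the modeled couch
    span, otherwise an :class:`IndexingError` is raised.
    """
    if beam not in ctx.beams:
        raise ValueError(f"beam {beam.beam_id!r} is not part of the plan context")
    iso = np.asarray(beam.isocenter_ct, dtype=float)
    to_couch = CT_TO_COUCH_HFS @ RigidTransform.from_translation(-iso)
    return couch_transform(beam.couch_angle, sixdof) @ to_couch


def couch_top_transform(
    ctx: PlanContext,
    beam: BeamConfig,
    dims: DimensionSet,
    sixdof: SixDofCorrection | None = None,
) -> RigidTransform:
    """Pose of the couch-top component for a beam.

    The couch-top local origin (junction end, top surface center) is pinned
    to the junction point implied by the JCT value: the junction lies
    ``jct`` inferior of the CT reference mark on the couch surface plane,
    laterally centered on the patient axis; the extension spans superior
    from there.
    """
    jct_ct = np.array([0.0, ctx.couch_surface_y_ct, -ctx.jct_mm])
    patient = patient_to_room_transform(ctx, beam, sixdof)
    # couch local axes coincide with room axes at couch angle 0
    local_to_ct = RigidTransform(CT_TO_COUCH_HFS.rotation.T, jct_ct)
    xf = patient @ local_to_ct
    # indexing check: the isocenter must project onto the couch span
    ct = dims.couch_tops[ctx.couch_top_kind]
    iso_offset = ctx.jct_mm + beam.isocenter_ct[2]
    if not -dims.longitudinal_safety_margin <= iso_offset <= ct.length + dims.longitudinal_safety_margin:
        raise IndexingError(
            f"isocenter sits {iso_offset:.1f} mm superior of the junction along the "
            f"couch axis, outside the modeled couch span [0, {ct.length:.0f}] mm"
        )
    return xf


def solve_pps_pose(
    couch_pose: RigidTransform,
    dims: DimensionSet,
    couch_top_kind: str = "civco",
) -> dict:
    """Left-elbow two-link solve for the PPS arm poses supporting the couch.

    The arm works in a horizontal plane (vertical travel is absorbed by the
    base column): shoulder fixed above ``dims.base_position``, lower arm and
    upper arm lengths from ``dims.arm_link_lengths``, wrist pinned to the
    couch mount point (under the couch near its inferior end).  Of the two
    planar solutions the left-elbow branch is always selected; at maximum
    reach they coincide.  Returns ``{"pps_base_lower_arm": RigidTransform,
    "pps_upper_arm_knuckle": RigidTransform, "wrist": point}``.
    """
    _, l1, l2, knuckle = dims.arm_link_lengths
    ct = dims.couch_tops[couch_top_kind]
    # the robot grips the extension just inferior of the junction, below deck
    mount_local = np.array([0.0, -150.0, -ct.thickness - 140.0])
    target = couch_pose.apply(mount_local)

    base = np.asarray(dims.base_position, dtype=float)
    dx, dy = target[0] - base[0], target[1] - base[1]
    d = float(np.hypot(dx, dy))
    reach = l1 + l2 + knuckle
    if d > reach:
        raise ReachabilityError(
            f"couch mount point {d:.1f} mm from the PPS base exceeds the "
            f"{reach:.1f} mm arm reach",
            shortfall_mm=d - reach,
        )
    if d < abs(l1 - (l2 + knuckle)):
        raise ReachabilityError(
            "couch mount point inside the arm's inner dead zone",
            shortfall_mm=abs(l1 - (l2 + knuckle)) - d,
        )
    ltip = l2 + knuckle  # knuckle extends the upper arm toward the wrist
    alpha = float(np.arctan2(dy, dx))
    cos_g = np.clip((l1 * l1 + d * d - ltip * ltip) / (2.0 * l1 * d), -1.0, 1.0)
    gamma = float(np.arccos(cos_g))
    theta1 = alpha + gamma  # left-elbow branch: elbow on the CCW side
    elbow = base[:2] + l1 * np.array([np.cos(theta1), np.sin(theta1)])
    theta2 = float(np.arctan2(target[1] - elbow[1], target[0] - elbow[0]))

    z_plane = float(target[2])
    lower = RigidTransform(
        rot_z(np.degrees(theta1)).rotation, np.array([base[0], base[1], z_plane])
    )
    upper = RigidTransform(
        rot_z(np.degrees(theta2)).rotation, np.array([elbow[0], elbow[1], z_plane])
    )
    return {"pps_base_lower_arm": lower, "pps_upper_arm_knuckle": upper, "wrist": target}
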