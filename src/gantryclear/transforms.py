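"""Rigid-body transforms in the room coordinate frame.

Conventions (see docs/methods.md for the full coordinate reference):

* room frame origin at the machine isocenter, ``+z`` up,
  ``+y`` along the gantry rotation axis (couch long axis at couch angle 0,
  pointing from the couch toward the gantry), ``+x`` completing a
  right-handed frame;
* all lengths in millimeters, all angles in degrees at public interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform", "rot_x", "rot_y", "rot_z"]

_ORTHO_TOL = 1e-9


def _rotation_matrix(axis: int, degrees: float) -> np.ndarray:
    t = np.radians(degrees)
    c, s = np.cos(t), np.sin(t)
    m = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    m[i, i] = c
    m[j, j] = c
    if axis == 1:  # y keeps right-handed sign pattern
        m[i, j] = s
        m[j, i] = -s
    else:
        m[i, j] = -s
        m[j, i] = s
    return m


def rot_x(degrees: float) -> "RigidTransform":
    """Rotation about the room +x axis (pitch)."""
    return RigidTransform(_rotation_matrix(0, degrees), np.zeros(3))


def rot_y(degrees: float) -> "RigidTransform":
    """Rotation about the room +y axis; positive angle maps +z toward +x."""
    return RigidTransform(_rotation_matrix(1, degrees), np.zeros(3))


def rot_z(degrees: float) -> "RigidTransform":
    """Rotation about the room +z axis (counterclockwise viewed from above)."""
    return RigidTransform(_rotation_matrix(2, degrees), np.zeros(3))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``p -> R p + t`` (rotation + translation, mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > 1e-6:
            raise ValueError("rotation matrix determinant is not +1 (improper rotation)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def apply(self, points) -> np.ndarray:
        """Transform an ``(n, 3)`` array (or a single point) of mm coordinates."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        out = np.atleast_2d(p) @ self.rotation.T + self.translation
        return out[0] if single else out

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (for trimesh ``apply_transform``)."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def is_identity(self, tol: float = _ORTHO_TOL) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=tol)
            and np.allclose(self.translation, 0.0, atol=tol)
        )
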