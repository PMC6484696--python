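"""Rigid transforms in world (RAS, millimetre) coordinates.

A :class:`RigidTransform` is parametrised by three Euler angles in degrees
(intrinsic Z-Y-X order) and a translation in mm, with the rotation applied
about a fixed pivot point (typically the centroid of the anatomy mask) before
the translation::

    T(p) = R (p - c) + c + t

Rotating about the mask centroid rather than the world origin keeps the
rotation and translation parameters approximately decoupled for the small
motions typical of a fetus, which matters for derivative-free optimisation.
Transforms form a group under :meth:`compose` / :meth:`invert`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(3)
    return v


@dataclass(frozen=True)
class RigidTransform:
    """6-parameter rigid motion: rotation (deg) about ``center``, then translation (mm).

    ``rotation`` holds ``(rx, ry, rz)`` in degrees; the rotation matrix is the
    intrinsic Z-Y-X composition ``Rz(rz) @ Ry(ry) @ Rx(rx)``.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "rotation", _as_vec3(self.rotation))
        object.__setattr__(self, "translation", _as_vec3(self.translation))
        object.__setattr__(self, "center", _as_vec3(self.center))

    # -- conversions ---------------------------------------------------------

    @property
    def rotation_matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation
        return Rotation.from_euler("ZYX", [rz, ry, rx], degrees=True).as_matrix()

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 world-to-world matrix."""
        R = self.rotation_matrix
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = self.center + self.translation - R @ self.center
        return m

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        matrix = np.asarray(matrix, dtype=float)
        c = _as_vec3(center)
        R = Rotation.from_matrix(matrix[:3, :3])
        rz, ry, rx = R.as_euler("ZYX", degrees=True)
        t = matrix[:3, 3] - c + matrix[:3, :3] @ c
        return cls(rotation=(rx, ry, rz), translation=t, center=c)

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(center=center)

    @classmethod
    def from_params(cls, params, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from a flat 6-vector ``(rx, ry, rz, tx, ty, tz)`` (deg, mm)."""
        p = np.asarray(params, dtype=float).reshape(6)
        return cls(rotation=p[:3], translation=p[3:], center=center)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.rotation, self.translation])

    # -- group operations ----------------------------------------------------

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map world points (.., 3) through the transform."""
        p = np.asarray(points, dtype=float)
        R = self.rotation_matrix
        return (p - self.center) @ R.T + self.center + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first), pivot kept from ``self``."""
        return RigidTransform.from_matrix(self.matrix @ other.matrix, center=self.center)

    def invert(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix), center=self.center)

    def with_center(self, center) -> "RigidTransform":
        """Same world mapping, re-expressed about a different pivot."""
        return RigidTransform.from_matrix(self.matrix, center=center)

    def magnitude(self, radius_mm: float = 25.0) -> float:
        """Scalar motion size: translation plus small-angle arc at ``radius_mm``."""
        rot = float(np.linalg.norm(self.rotation))
        return float(np.linalg.norm(self.translation)) + np.deg2rad(rot) * radius_mm


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    return a.compose(b)


def invert(t: RigidTransform) -> RigidTransform:
    return t.invert()


def apply(t: RigidTransform, points: np.ndarray) -> np.ndarray:
    return t.apply(points)
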