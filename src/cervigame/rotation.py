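"""Rotation algebra for head-orientation tracking.

Orientations are carried as a unit quaternion / direction cosine matrix
(DCM) pair.  The DCM ``R`` maps head-frame vectors into the world frame
(``v_world = R @ v_head``).  Frames follow the convention used throughout
the package:

* world: X magnetic north (anterior at calibration), Y left, Z up
  (gravity along −Z);
* head: X anterior, Y left (through the ears), Z up.

Cervical motions therefore decompose as flexion-extension about the head
Y axis, axial rotation about Z and lateral inclination about X, and the
YZX Euler sequence extracts flexion-extension first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation as _Rotation

__all__ = [
    "RotationState",
    "EulerYZX",
    "GimbalLockError",
    "compose_yzx",
    "decompose_yzx",
    "rotation_x",
    "rotation_y",
    "rotation_z",
    "nearest_rotation",
    "angular_distance_deg",
]

_ORTHONORMALITY_TOL = 1e-9
#: |cos(middle angle)| below which the YZX decomposition is degenerate.
GIMBAL_COS_TOL = 1e-7


class GimbalLockError(ValueError):
    """The YZX decomposition is degenerate (axial rotation near ±90°).

    At the lock the flexion-extension (Y) and lateral-inclination (X)
    axes coincide and only their sum is observable.
    """


def rotation_x(angle_deg: float) -> np.ndarray:
    """DCM of a rotation by ``angle_deg`` about the X (anterior) axis."""
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rotation_y(angle_deg: float) -> np.ndarray:
    """DCM of a rotation by ``angle_deg`` about the Y (lateral) axis."""
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_z(angle_deg: float) -> np.ndarray:
    """DCM of a rotation by ``angle_deg`` about the Z (vertical) axis."""
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class RotationState:
    """A rigid-body orientation as a consistent quaternion/DCM pair.

    Parameters
    ----------
    dcm:
        3×3 orthonormal matrix with determinant +1 mapping head-frame
        vectors to world-frame vectors.
    quaternion:
        Unit quaternion in scalar-last ``(x, y, z, w)`` order, derived
        from ``dcm`` when not supplied.
    """

    dcm: np.ndarray
    quaternion: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        dcm = np.asarray(self.dcm, dtype=float)
        if dcm.shape != (3, 3):
            raise ValueError(f"DCM must be 3x3, got shape {dcm.shape}")
        err = np.abs(dcm.T @ dcm - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"matrix is not orthonormal (max |R'R - I| = {err:.3g})")
        if err > _ORTHONORMALITY_TOL:
            dcm = nearest_rotation(dcm)
        if np.linalg.det(dcm) < 0:
            raise ValueError("matrix has determinant -1 (reflection, not a rotation)")
        object.__setattr__(self, "dcm", dcm)
        q = self.quaternion
        if q is None:
            q = _Rotation.from_matrix(dcm).as_quat()
        else:
            q = np.asarray(q, dtype=float)
            if abs(np.linalg.norm(q) - 1.0) > _ORTHONORMALITY_TOL:
                raise ValueError("quaternion is not unit norm")
        object.__setattr__(self, "quaternion", q)

    @classmethod
    def identity(cls) -> "RotationState":
        return cls(np.eye(3))

    @classmethod
    def from_quaternion(cls, q: np.ndarray) -> "RotationState":
        """Build from a scalar-last unit quaternion."""
        q = np.asarray(q, dtype=float)
        q = q / np.linalg.norm(q)
        return cls(_Rotation.from_quat(q).as_matrix(), q)

    @classmethod
    def from_rotvec_deg(cls, rotvec_deg: np.ndarray) -> "RotationState":
        """Build from an axis-angle rotation vector in degrees."""
        return cls(_Rotation.from_rotvec(np.asarray(rotvec_deg, float), degrees=True).as_matrix())

    def inverse(self) -> "RotationState":
        return RotationState(self.dcm.T)

    def __matmul__(self, other: "RotationState") -> "RotationState":
        return RotationState(self.dcm @ other.dcm)

    def apply(self, v: np.ndarray) -> np.ndarray:
        """Rotate a head-frame vector into the world frame."""
        return self.dcm @ np.asarray(v, dtype=float)

    def angle_to(self, other: "RotationState") -> float:
        """Geodesic angle in degrees between two orientations."""
        return angular_distance_deg(self.dcm, other.dcm)


@dataclass(frozen=True)
class EulerYZX:
    """Cervical angles of the YZX Euler factorisation ``R = Ry(α)·Rz(rot)·Rx(incl)``.

    Attributes
    ----------
    alpha:
        Flexion-extension, degrees; positive tips the face downward
        (flexion), negative is extension.
    rot:
        Axial rotation about the vertical axis, degrees; positive turns
        the head to the left.
    incl:
        Lateral inclination about the anterior axis, degrees; positive
        tilts the head toward the left shoulder.
    """

    alpha: float
    rot: float
    incl: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.rot, self.incl)


def compose_yzx(e: EulerYZX | tuple[float, float, float]) -> RotationState:
    """Compose a head orientation from YZX Euler angles (degrees).

    Returns ``R = Ry(alpha) @ Rz(rot) @ Rx(incl)``.
    """
    if not isinstance(e, EulerYZX):
        e = EulerYZX(*e)
    return RotationState(rotation_y(e.alpha) @ rotation_z(e.rot) @ rotation_x(e.incl))


def decompose_yzx(R: RotationState | np.ndarray) -> EulerYZX:
    """Extract YZX Euler angles (degrees) from an orientation.

    Closed form from the composed matrix: with ``R = Ry(a)·Rz(r)·Rx(i)``
    the middle row is ``(sin r, cos r·cos i, −cos r·sin i)`` and the first
    column is ``(cos a·cos r, sin r, −sin a·cos r)``.

    Raises
    ------
    GimbalLockError
        If ``|cos(rot)| <= 1e-7``, i.e. axial rotation within ~6e-6° of
        ±90°, where flexion-extension and inclination are inseparable.
    """
    M = R.dcm if isinstance(R, RotationState) else np.asarray(R, dtype=float)
    sin_rot = min(1.0, max(-1.0, M[1, 0]))
    cos_rot = math.hypot(M[1, 1], M[1, 2])
    if cos_rot <= GIMBAL_COS_TOL:
        raise GimbalLockError(
            "axial rotation at ±90°: flexion-extension (Y) and lateral "
            "inclination (X) axes are aligned and cannot be separated"
        )
    alpha = math.degrees(math.atan2(-M[2, 0], M[0, 0]))
    rot = math.degrees(math.atan2(sin_rot, cos_rot))
    incl = math.degrees(math.atan2(-M[1, 2], M[1, 1]))
    return EulerYZX(alpha=alpha, rot=rot, incl=incl)


def nearest_rotation(M: np.ndarray) -> np.ndarray:
    """Project a near-rotation matrix to the closest proper rotation.

    Orthogonal Procrustes via SVD; used by the chordal mean and to
    re-orthonormalise drifting filter states.
    """
    U, _, Vt = np.linalg.svd(np.asarray(M, dtype=float))
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


def angular_distance_deg(R1: np.ndarray, R2: np.ndarray) -> float:
    """Geodesic distance between two DCMs, degrees in [0, 180]."""
    cos_theta = (np.trace(R1.T @ R2) - 1.0) / 2.0
    return math.degrees(math.acos(min(1.0, max(-1.0, cos_theta))))
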