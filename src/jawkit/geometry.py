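"""Core 3D primitives: planes, lines, rigid transforms, line fitting, screw axes.

All distances are in millimetres and all angles in degrees.  Points are plain
``numpy`` arrays of shape ``(3,)``; point clouds are ``(n, 3)`` arrays.  These
primitives underpin every measurement module: reference-plane construction,
best-fit border/eminence lines, per-frame mandibular pose estimation, and the
terminal-hinge-axis (screw-axis) decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import DegenerateGeometry, NearIdentityRotation

_UNIT_TOL = 1e-9


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite coordinates")
    return a


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _UNIT_TOL:
        raise DegenerateGeometry("cannot normalize a (near-)zero vector")
    return v / n


@dataclass(frozen=True)
class Plane:
    """Oriented plane ``{p : normal . p = offset}`` with a unit normal."""

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        n = _as_point(self.normal)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("plane normal must be a unit vector")
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "offset", float(self.offset))


@dataclass(frozen=True)
class Line3:
    """Line through ``point`` with unit ``direction``."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        p = _as_point(self.point)
        d = _as_point(self.direction)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("line direction must be a unit vector")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d)

    def closest_point_to_origin(self) -> np.ndarray:
        return self.point - np.dot(self.point, self.direction) * self.direction

    def project(self, p) -> np.ndarray:
        p = _as_point(p)
        return self.point + np.dot(p - self.point, self.direction) * self.direction


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> R p + t`` (rotation + translation, no scaling)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = _as_point(self.translation)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if np.max(np.abs(R @ R.T - np.eye(3))) > 1e-6 or abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be orthonormal with det +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def apply(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other`` (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


class LineFit(NamedTuple):
    line: Line3
    rms_residual: float


class ScrewAxis(NamedTuple):
    axis: Line3
    angle_deg: float
    pitch_mm: float  # translation component along the axis


def plane_from_points(p1, p2, p3) -> Plane:
    """Plane through three non-collinear points.

    The normal follows the right-hand rule on ``(p2 - p1, p3 - p1)``.
    """
    p1, p2, p3 = _as_point(p1), _as_point(p2), _as_point(p3)
    c = np.cross(p2 - p1, p3 - p1)
    # |c| is twice the triangle area
    if np.linalg.norm(c) <= 2e-6:
        raise DegenerateGeometry("points are collinear or coincident")
    n = c / np.linalg.norm(c)
    return Plane(n, float(np.dot(n, p1)))


def signed_distance(p, plane: Plane) -> float:
    """Signed point-plane distance; positive on the side of the normal."""
    return float(np.dot(plane.normal, _as_point(p)) - plane.offset)


def project_point(p, plane: Plane) -> np.ndarray:
    p = _as_point(p)
    return p - signed_distance(p, plane) * plane.normal


def angle_line_plane(line: Line3, plane: Plane) -> float:
    """Angle between a line and a plane in degrees, folded to [0, 90]."""
    s = abs(float(np.dot(line.direction, plane.normal)))
    return float(np.degrees(np.arcsin(np.clip(s, 0.0, 1.0))))


def fit_line(points, min_points: int = 3) -> LineFit:
    """Total-least-squares line through a point cloud.

    The direction is the first principal axis through the centroid, which makes
    the fit rotation-invariant (unlike y-on-x regression).  The residual is the
    root-mean-square perpendicular distance.  The direction sign is fixed so
    its largest-magnitude component is positive.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if pts.shape[0] < min_points:
        raise DegenerateGeometry(f"need at least {min_points} points, got {pts.shape[0]}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.max(np.linalg.norm(centered, axis=1)) < _UNIT_TOL:
        raise DegenerateGeometry("all points coincide")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    k = int(np.argmax(np.abs(d)))
    if d[k] < 0:
        d = -d
    perp = centered - np.outer(centered @ d, d)
    rms = float(np.sqrt(np.mean(np.sum(perp ** 2, axis=1))))
    return LineFit(Line3(centroid, d), rms)


def estimate_rigid_transform(ref_markers, cur_markers) -> RigidTransform:
    """Least-squares rigid transform mapping ``ref`` onto ``cur`` (Kabsch).

    Minimizes ``sum |R ref_i + t - cur_i|^2`` over proper rotations ``R`` and
    translations ``t``.  Requires >= 3 paired, non-collinear reference markers.
    """
    ref = np.asarray(ref_markers, dtype=float)
    cur = np.asarray(cur_markers, dtype=float)
    if ref.shape != cur.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("marker sets must be matching (n, 3) arrays")
    if ref.shape[0] < 3:
        raise DegenerateGeometry("need at least 3 markers")
    ref_c = ref - ref.mean(axis=0)
    cur_c = cur - cur.mean(axis=0)
    sv = np.linalg.svd(ref_c, compute_uv=False)
    if sv[1] < 1e-9:
        raise DegenerateGeometry("reference markers are collinear")
    H = ref_c.T @ cur_c
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = cur.mean(axis=0) - R @ ref.mean(axis=0)
    return RigidTransform(R, t)


def batch_rigid_transforms(ref_markers: np.ndarray, cur_stack: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Kabsch: least-squares rigid transforms mapping one reference
    marker set onto each of a stack of marker sets.

    Returns rotation matrices ``(n, 3, 3)`` and translations ``(n, 3)``.
    """
    ref = np.asarray(ref_markers, dtype=float)
    cur = np.asarray(cur_stack, dtype=float)
    if ref.ndim != 2 or cur.ndim != 3 or cur.shape[1:] != ref.shape or ref.shape[1] != 3:
        raise ValueError("expected ref (k, 3) and stack (n, k, 3)")
    if ref.shape[0] < 3:
        raise DegenerateGeometry("need at least 3 markers")
    ref_c = ref - ref.mean(axis=0)
    if np.linalg.svd(ref_c, compute_uv=False)[1] < 1e-9:
        raise DegenerateGeometry("reference markers are collinear")
    cur_mean = cur.mean(axis=1)
    cur_c = cur - cur_mean[:, None, :]
    H = np.einsum("ki,nkj->nij", ref_c, cur_c)
    U, _, Vt = np.linalg.svd(H)
    s = np.sign(np.linalg.det(Vt) * np.linalg.det(U))
    V = np.swapaxes(Vt, 1, 2)
    V[:, :, 2] *= s[:, None]
    R = V @ np.swapaxes(U, 1, 2)
    t = cur_mean - np.einsum("nij,j->ni", R, ref.mean(axis=0))
    return R, t


def rotation_angles_deg(R_stack: np.ndarray) -> np.ndarray:
    """Rotation angles of a stack of rotation matrices, degrees."""
    c = (np.trace(R_stack, axis1=-2, axis2=-1) - 1.0) / 2.0
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def rotation_angle_deg(R: np.ndarray) -> float:
    """Rotation angle of a 3x3 rotation matrix, in degrees."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def screw_axis(transform: RigidTransform, angle_floor: float = 1.0) -> ScrewAxis:
    """Chasles decomposition of a rigid transform into rotation about an axis
    plus translation (pitch) along it.

    The axis direction is the rotation eigenvector for eigenvalue 1 (oriented
    by the rotation vector so that the angle is positive); the axis point is
    the on-axis point closest to the origin.  Raises ``NearIdentityRotation``
    when the rotation angle is below ``angle_floor`` degrees, where the axis is
    ill-conditioned.
    """
    return _screw(transform.rotation, transform.translation, angle_floor)


def _screw(R: np.ndarray, t: np.ndarray, angle_floor: float) -> ScrewAxis:
    angle = rotation_angle_deg(R)
    if angle < angle_floor:
        raise NearIdentityRotation(f"rotation angle {angle:.4g} deg < floor {angle_floor} deg")
    # rotation vector direction (eigenvector for eigenvalue 1, oriented)
    if angle < 179.0:
        w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        d = _unit(w)
    else:  # near pi: extract axis from R + I
        M = R + np.eye(3)
        d = _unit(M[:, int(np.argmax(np.linalg.norm(M, axis=0)))])
    pitch = float(np.dot(t, d))
    t_perp = t - pitch * d
    # solve (I - R) p = t_perp with p . d = 0 -> on-axis point closest to origin
    A = np.vstack([np.eye(3) - R, d[None, :]])
    b = np.concatenate([t_perp, [0.0]])
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    return ScrewAxis(Line3(p, d), angle, pitch)
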