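"""Rotations, quaternions, rigid transforms and RMSD primitives.

Conventions
-----------
* Column-vector action: a transform maps a point ``x`` to ``R @ x + t``.
* Quaternions are scalar-first ``[q0, q1, q2, q3]`` with the canonical
  representative chosen so that ``q0 >= 0`` (a quaternion and its negation
  encode the same rotation).
* Angles cross the public API in degrees; radians are used internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "RegistrationVector",
    "quat_to_rotation",
    "rotation_about_axis",
    "rmsd",
    "apply_transform",
]

_ORTHO_TOL = 1e-8


def _as_points(obj) -> np.ndarray:
    """Coerce a PointSet or array-like into an (N, 3) float array."""
    coords = getattr(obj, "coords", obj)
    arr = np.asarray(coords, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected an (N, 3) coordinate array, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x' = R @ x + t`` (rotation + translation, Å)."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float).reshape(3, 3)
        t = np.asarray(self.t, dtype=float).reshape(3)
        if not np.isfinite(R).all() or not np.isfinite(t).all():
            raise ValueError("transform entries must be finite")
        if np.abs(R.T @ R - np.eye(3)).max() > _ORTHO_TOL:
            raise ValueError("R is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("R is a reflection (det < 0); only proper rotations allowed")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        """Transform an (N, 3) array of coordinates."""
        return _as_points(points) @ self.R.T + self.t

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``first`` then ``self``."""
        return RigidTransform(self.R @ first.R, self.R @ first.t + self.t)

    def invert(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t)

    def is_identity(self, tol: float = 1e-10) -> bool:
        return (
            np.abs(self.R - np.eye(3)).max() <= tol and np.abs(self.t).max() <= tol
        )


def compose(t2: RigidTransform, t1: RigidTransform) -> RigidTransform:
    """Transform equivalent to applying ``t1`` then ``t2``."""
    return t2.compose(t1)


def invert(t: RigidTransform) -> RigidTransform:
    return t.invert()


def canonical_quaternion(q: np.ndarray) -> np.ndarray:
    """Pick the sign representative with ``q0 >= 0``.

    When ``q0 == 0`` exactly the first nonzero component is made positive,
    which keeps the representative unique.
    """
    q = np.asarray(q, dtype=float).reshape(4)
    for comp in q:
        if comp > 0:
            return q.copy()
        if comp < 0:
            return -q
    raise ValueError("zero quaternion has no canonical form")


@dataclass(frozen=True)
class RegistrationVector:
    """The 7-vector state of a registration: unit quaternion + translation.

    ``qR`` is the scalar-first unit quaternion (canonical sign, ``q0 >= 0``)
    and ``qT`` the translation in Å.  Together they act as
    ``x' = R(qR) @ x + qT``.
    """

    qR: np.ndarray
    qT: np.ndarray

    def __post_init__(self):
        qR = np.asarray(self.qR, dtype=float).reshape(4)
        qT = np.asarray(self.qT, dtype=float).reshape(3)
        norm = np.linalg.norm(qR)
        if abs(norm - 1.0) > _ORTHO_TOL:
            raise ValueError(f"quaternion is not unit norm (|q| = {norm!r})")
        qR = canonical_quaternion(qR / norm)
        object.__setattr__(self, "qR", qR)
        object.__setattr__(self, "qT", qT)

    @classmethod
    def identity(cls) -> "RegistrationVector":
        return cls(np.array([1.0, 0.0, 0.0, 0.0]), np.zeros(3))

    def as_transform(self) -> RigidTransform:
        return RigidTransform(quat_to_rotation(self.qR), self.qT)

    def apply(self, points) -> np.ndarray:
        return self.as_transform().apply(points)


def quat_to_rotation(qR) -> np.ndarray:
    """Rotation matrix of a unit quaternion ``[q0, q1, q2, q3]`` (scalar first).

    Raises
    ------
    ValueError
        If the quaternion norm deviates from 1 by more than 1e-8.
    """
    q = np.asarray(qR, dtype=float).reshape(4)
    if abs(np.linalg.norm(q) - 1.0) > _ORTHO_TOL:
        raise ValueError("quaternion must have unit norm")
    q0, q1, q2, q3 = q
    return np.array(
        [
            [
                q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3,
                2 * (q1 * q2 - q0 * q3),
                2 * (q1 * q3 + q0 * q2),
            ],
            [
                2 * (q1 * q2 + q0 * q3),
                q0 * q0 + q2 * q2 - q1 * q1 - q3 * q3,
                2 * (q2 * q3 - q0 * q1),
            ],
            [
                2 * (q1 * q3 - q0 * q2),
                2 * (q2 * q3 + q0 * q1),
                q0 * q0 + q3 * q3 - q1 * q1 - q2 * q2,
            ],
        ]
    )


def rotation_about_axis(u, theta: float) -> np.ndarray:
    """Proper rotation by ``theta`` degrees about the axis ``u`` through the origin.

    The axis is normalized internally; the positive sense is right-handed.
    """
    u = np.asarray(u, dtype=float).reshape(3)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("rotation axis must be a nonzero vector")
    u = u / norm
    half = 0.5 * np.deg2rad(theta)
    q = np.concatenate([[np.cos(half)], np.sin(half) * u])
    return quat_to_rotation(q / np.linalg.norm(q))


def rmsd(A, B) -> float:
    """Root-mean-square deviation between index-paired point sets, in Å."""
    a = _as_points(A)
    b = _as_points(B)
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"size mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] == 0:
        raise ValueError("point sets must be non-empty")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def apply_transform(ps, t: RigidTransform):
    """Apply a rigid transform to a PointSet, returning a new PointSet.

    Accepts a bare coordinate array too, in which case an array is returned.
    """
    if hasattr(ps, "with_coords"):
        return ps.with_coords(t.apply(ps.coords))
    return t.apply(ps)
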