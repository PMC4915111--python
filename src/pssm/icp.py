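"""Quaternion least-squares registration and the iterative closest point loop.

The paired-registration solver is the classical quaternion method: the
optimal rotation is the unit eigenvector, for the maximum eigenvalue, of a
symmetric 4x4 matrix built from the cross-covariance of the two point sets;
the optimal translation then maps the data centroid onto the model centroid.
ICP alternates closest-point correspondence against the model shape with
this closed-form registration of the *original* data set onto the matched
points, so the registration vector at every step is the complete transform.
Its mean-square error is non-increasing and converges to a local minimum.

A Kabsch/SVD solver for the same paired problem is provided as an
independent baseline; the two agree to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    RegistrationVector,
    RigidTransform,
    _as_points,
    canonical_quaternion,
)

__all__ = [
    "ICPResult",
    "cross_covariance",
    "q_matrix",
    "optimal_registration",
    "closest_points",
    "icp_register",
    "kabsch_superpose",
]

DEFAULT_TAU = 1e-10  # Å², threshold on the change of mean-square error
DEFAULT_MAX_ITER = 200


@dataclass(frozen=True)
class ICPResult:
    """Outcome of an ICP run.

    ``transform`` is the cumulative rigid motion taking the initial data set
    onto the model; ``errors_by_iteration`` lists the mean-square error d_k
    (Å²) of each registration, a non-increasing sequence.
    """

    transform: RigidTransform
    registration: RegistrationVector
    errors_by_iteration: tuple
    iterations: int
    converged: bool

    @property
    def final_mse(self) -> float:
        return self.errors_by_iteration[-1]


def _paired(P, X):
    p = _as_points(P)
    x = _as_points(X)
    if p.shape[0] != x.shape[0]:
        raise ValueError(f"size mismatch: {p.shape[0]} vs {x.shape[0]}")
    if p.shape[0] == 0:
        raise ValueError("point sets must be non-empty")
    return p, x


def cross_covariance(P, X) -> np.ndarray:
    """Cross-covariance Σpx = (1/N) Σ p_i x_iᵀ − μp μxᵀ of index-paired sets."""
    p, x = _paired(P, X)
    mu_p = p.mean(axis=0)
    mu_x = x.mean(axis=0)
    return p.T @ x / p.shape[0] - np.outer(mu_p, mu_x)


def q_matrix(sigma: np.ndarray) -> np.ndarray:
    """Symmetric 4x4 matrix whose top eigenvector is the optimal quaternion.

    Top-left entry is tr(Σ); the off-diagonal block is
    Δ = [A23, A31, A12] with A = Σ − Σᵀ; the lower-right 3x3 block is
    Σ + Σᵀ − tr(Σ)·I.
    """
    sigma = np.asarray(sigma, dtype=float).reshape(3, 3)
    A = sigma - sigma.T
    delta = np.array([A[1, 2], A[2, 0], A[0, 1]])
    Q = np.empty((4, 4))
    Q[0, 0] = np.trace(sigma)
    Q[0, 1:] = delta
    Q[1:, 0] = delta
    Q[1:, 1:] = sigma + sigma.T - np.trace(sigma) * np.eye(3)
    return Q


def optimal_registration(P, X) -> tuple[RegistrationVector, float]:
    """Closed-form least-squares registration of paired sets (O(N)).

    Returns the registration vector (unit quaternion with q0 >= 0 plus
    translation) minimizing the mean-square error
    (1/N) Σ ‖x_i − R p_i − t‖², and that minimal value in Å².
    """
    p, x = _paired(P, X)
    sigma = cross_covariance(p, x)
    Q = q_matrix(sigma)
    eigenvalues, eigenvectors = np.linalg.eigh(Q)
    qR = canonical_quaternion(eigenvectors[:, -1])  # max eigenvalue is last
    reg = RegistrationVector(qR, np.zeros(3))
    R = reg.as_transform().R
    qT = x.mean(axis=0) - R @ p.mean(axis=0)
    reg = RegistrationVector(qR, qT)
    d_ms = float(np.mean(np.sum((x - p @ R.T - qT) ** 2, axis=1)))
    return reg, d_ms


def closest_points(P, X) -> np.ndarray:
    """For each point of P, its nearest Euclidean neighbor in X.

    Ties are broken deterministically toward the lowest index in X.  The map
    need not be one-to-one.  Returns an (|P|, 3) array.
    """
    x = _as_points(X)
    if x.shape[0] == 0:
        raise ValueError("model set X must be non-empty")
    p = _as_points(P)
    tree = cKDTree(x)
    dist, idx = tree.query(p)
    # enforce lowest-index tie-break: look for equally near neighbors
    radii = dist + 1e-9 * np.maximum(dist, 1.0)
    balls = tree.query_ball_point(p, radii)
    for i, near in enumerate(balls):
        if len(near) > 1:
            d2 = np.sum((x[near] - p[i]) ** 2, axis=1)
            tied = [n for n, dd in zip(near, d2) if dd <= dist[i] ** 2 + 1e-18]
            if tied:
                idx[i] = min(tied)
    return x[idx]


def icp_register(P0, X, tau: float = DEFAULT_TAU,
                 max_iter: int = DEFAULT_MAX_ITER) -> ICPResult:
    """Iterative closest point registration of data P0 onto model X.

    Each iteration matches the current data position against X, solves the
    paired registration of the *original* P0 onto the matched points, and
    re-applies it to P0, so the returned registration is cumulative.  Stops
    when the mean-square error changes by less than ``tau`` (Å²) or after
    ``max_iter`` iterations (then ``converged=False``).
    """
    p0 = _as_points(P0)
    x = _as_points(X)
    if p0.shape[0] < 3 or x.shape[0] < 3:
        raise ValueError("ICP needs at least 3 points in each set")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    tree = cKDTree(x)
    current = p0
    errors: list[float] = []
    reg = RegistrationVector.identity()
    converged = False
    for _ in range(max_iter):
        _, idx = tree.query(current)
        Y = x[idx]
        reg, d = optimal_registration(p0, Y)
        current = reg.apply(p0)
        if errors and abs(errors[-1] - d) < tau:
            errors.append(d)
            converged = True
            break
        errors.append(d)
    return ICPResult(
        transform=reg.as_transform(),
        registration=reg,
        errors_by_iteration=tuple(errors),
        iterations=len(errors),
        converged=converged,
    )


def kabsch_superpose(P, X) -> tuple[RigidTransform, float]:
    """SVD-based optimal superposition of index-paired sets.

    Returns the proper rigid transform minimizing the paired RMSD of P onto
    X, with the reflection corrected through the sign of the determinant,
    and the minimal RMSD in Å.
    """
    p, x = _paired(P, X)
    if p.shape[0] < 3:
        raise ValueError("need at least 3 paired points")
    mu_p = p.mean(axis=0)
    mu_x = x.mean(axis=0)
    H = (p - mu_p).T @ (x - mu_x)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = mu_x - R @ mu_p
    residual = float(np.sqrt(np.mean(np.sum((x - p @ R.T - t) ** 2, axis=1))))
    return RigidTransform(R, t), residual
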