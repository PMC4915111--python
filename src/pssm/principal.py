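"""Principal axes of a structure and the principal-axes rough superposition.

The principal frame of a point set is its center of mass (unweighted mean)
together with the eigenvectors of the second-moment (covariance) tensor of
the centered coordinates, ordered by decreasing eigenvalue.  Aligning two
frames — centers onto centers, axes onto axes in eigenvalue order — gives a
rough rigid superposition that is insensitive to noise and to moderate
amounts of missing atoms, and serves as the initializer for ICP refinement.

Eigenvectors are only defined up to sign, so four proper rotations are
consistent with any axes-onto-axes alignment (flip an even number of axes).
``axes_superpose`` scores all four by closest-point mean-square error and
returns the best; reflections are never candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import RigidTransform, _as_points

__all__ = ["PrincipalFrame", "principal_frame", "axes_superpose"]

# relative eigenvalue gap below which the frame is flagged degenerate
_DEGENERATE_RTOL = 1e-9


@dataclass(frozen=True)
class PrincipalFrame:
    """Center of mass plus principal axes of a point set.

    ``axes`` holds the three orthonormal eigenvectors as *rows*, sorted by
    decreasing eigenvalue, forming a right-handed triad; ``eigenvalues`` are
    the corresponding second moments in Å².
    """

    center: np.ndarray
    axes: np.ndarray
    eigenvalues: np.ndarray

    @property
    def degenerate(self) -> bool:
        """True when two eigenvalues coincide within relative tolerance."""
        lam = self.eigenvalues
        scale = max(lam[0], 1e-30)
        return bool(
            (lam[0] - lam[1]) <= _DEGENERATE_RTOL * scale
            or (lam[1] - lam[2]) <= _DEGENERATE_RTOL * scale
        )


def principal_frame(ps) -> PrincipalFrame:
    """Compute the principal frame of a point set.

    Requires at least 3 points.  The covariance is unweighted and divided by
    N.  Deterministic sign convention: each of the first two eigenvectors is
    oriented so its largest-magnitude component is positive; the third is
    their cross product, which guarantees a right-handed triad.
    """
    pts = _as_points(ps)
    if pts.shape[0] < 3:
        raise ValueError(f"need at least 3 points for a principal frame, got {pts.shape[0]}")
    center = pts.mean(axis=0)
    centered = pts - center
    second_moment = centered.T @ centered / pts.shape[0]
    eigenvalues, eigenvectors = np.linalg.eigh(second_moment)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    axes = eigenvectors[:, order].T  # rows = eigenvectors, descending eigenvalue
    for i in range(2):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    return PrincipalFrame(center=center, axes=axes,
                          eigenvalues=np.maximum(eigenvalues, 0.0))


def _sign_candidates():
    # flip signs of the first two axes; the third follows to keep det = +1
    for s1, s2 in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        yield np.array([s1, s2, s1 * s2], dtype=float)


def axes_superpose(moving, fixed, return_details: bool = False):
    """Rough superposition mapping ``moving``'s frame onto ``fixed``'s.

    Centers of mass are brought into coincidence and principal axes aligned
    in order of decreasing eigenvalue.  Among the four proper sign
    assignments of the axis directions the one minimizing the closest-point
    mean-square error of the transformed moving set against the fixed set is
    returned; ties are broken by enumeration order (++, +-, -+, --).

    Returns a :class:`~pssm.geometry.RigidTransform`; with
    ``return_details=True`` also a dict carrying the candidate errors and a
    degenerate-spectrum ambiguity flag.
    """
    frame_m = principal_frame(moving)
    frame_f = principal_frame(fixed)
    pts_m = _as_points(moving)
    tree = cKDTree(_as_points(fixed))

    best = None
    errors = []
    for signs in _sign_candidates():
        # rotation taking moving's axes (rows) onto fixed's sign-flipped axes
        R = (frame_f.axes * signs[:, None]).T @ frame_m.axes
        t = frame_f.center - R @ frame_m.center
        candidate = RigidTransform(R, t)
        d, _ = tree.query(pts_m @ R.T + t)
        mse = float(np.mean(d**2))
        errors.append(mse)
        if best is None or mse < best[0]:
            best = (mse, candidate)
    transform = best[1]
    if return_details:
        details = {
            "candidate_mse": errors,
            "ambiguous": frame_m.degenerate or frame_f.degenerate,
            "moving_frame": frame_m,
            "fixed_frame": frame_f,
        }
        return transform, details
    return transform
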