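"""Pairwise structure superposition: principal-axes start, ICP refinement,
rotational-search fallback.

The procedure first tries the principal-axes rough alignment followed by
ICP.  If the resulting closest-point RMSD does not fall below the threshold
``c`` (default 1.5 Å), the moving structure is re-oriented by rotating it
about axes built from its own principal frame — v1, v1±v2, v1±v3, through
its centroid — in fixed angular steps (default 10°, i.e. 35 orientations per
axis), re-initializing from the principal axes and re-running ICP at each
orientation; the search exits early when an attempt beats ``c``, otherwise
the minimum-RMSD attempt wins.

RMSD for structures of unequal size is the closest-point RMSD driven by the
smaller structure; the reported aligned count is the smaller structure's
size.  The whole pipeline is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .geometry import RigidTransform, _as_points, rotation_about_axis
from .icp import DEFAULT_MAX_ITER, DEFAULT_TAU, icp_register
from .principal import axes_superpose, principal_frame

__all__ = ["PairwiseResult", "closest_point_rmsd", "pairwise_superpose"]

DEFAULT_C = 1.5  # Å, success threshold on the closest-point RMSD
DEFAULT_INTERVAL = 10.0  # degrees, rotational-search step

# axis labels in sweep order; built from the moving structure's eigenvectors
_AXIS_COMBOS = (
    ("v1", (1, 0, 0)),
    ("v1+v2", (1, 1, 0)),
    ("v1-v2", (1, -1, 0)),
    ("v1+v3", (1, 0, 1)),
    ("v1-v3", (1, 0, -1)),
)


@dataclass(frozen=True)
class PairwiseResult:
    """Result of a pairwise superposition of structure B onto structure A.

    ``transform`` acts on B's original coordinates; ``rmsd`` is the
    closest-point RMSD over the smaller structure; ``aligned`` its size.
    ``search_trace`` records every attempt as (axis label, angle°, rmsd).
    """

    transform: RigidTransform
    rmsd: float
    aligned: int
    search_trace: tuple
    succeeded: bool
    icp_iterations: int = 0
    ambiguous_frames: bool = False


def closest_point_rmsd(A, B) -> tuple[float, int]:
    """Closest-point RMSD between two point sets of possibly unequal size.

    The smaller set drives: each of its points is matched to its nearest
    neighbor in the larger set, and the RMSD over those matches is returned
    along with the aligned count (the smaller size).  Symmetric in its
    arguments.
    """
    a = _as_points(A)
    b = _as_points(B)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("point sets must be non-empty")
    small, large = (a, b) if a.shape[0] <= b.shape[0] else (b, a)
    dist, _ = cKDTree(large).query(small)
    return float(np.sqrt(np.mean(dist**2))), small.shape[0]


def _attempt(A, b_pts, pre: RigidTransform, tau, max_iter):
    """One initialization attempt: axes alignment + ICP, on pre-rotated B."""
    a_pts = _as_points(A)
    moved = pre.apply(b_pts)
    t_axes, details = axes_superpose(moved, a_pts, return_details=True)
    start = t_axes.compose(pre)
    b_start = t_axes.apply(moved)

    # the smaller structure is the ICP data set P; the model is the larger
    if b_pts.shape[0] <= a_pts.shape[0]:
        icp = icp_register(b_start, a_pts, tau=tau, max_iter=max_iter)
        total = icp.transform.compose(start)
    else:
        icp = icp_register(a_pts, b_start, tau=tau, max_iter=max_iter)
        total = icp.transform.invert().compose(start)
    value, aligned = closest_point_rmsd(a_pts, total.apply(b_pts))
    return value, aligned, total, icp, details["ambiguous"]


def pairwise_superpose(
    A,
    B,
    c: float = DEFAULT_C,
    interval: float = DEFAULT_INTERVAL,
    tau: float = DEFAULT_TAU,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PairwiseResult:
    """Superpose structure B onto structure A without sequence alignment.

    Parameters
    ----------
    A, B : PointSet or (N, 3) array
        Fixed and moving structures; each needs at least 3 points.
    c : float
        Success threshold in Å on the closest-point RMSD.
    interval : float
        Rotational-search step in degrees (sweep 10°..350° for the default).
    tau, max_iter :
        ICP stopping controls (Å² change threshold, iteration cap).

    Returns
    -------
    PairwiseResult
        With the transform expressed on B's original coordinates.
    """
    a_pts = _as_points(A)
    b_pts = _as_points(B)
    if a_pts.shape[0] < 3 or b_pts.shape[0] < 3:
        raise ValueError("both structures need at least 3 points")
    if not 0 < interval <= 120:
        raise ValueError("interval must be in (0, 120] degrees")
    if c <= 0:
        raise ValueError("threshold c must be positive")

    trace: list[tuple[str, float, float]] = []
    best: Optional[tuple] = None
    ambiguous = False

    def record(label, angle, pre):
        nonlocal best, ambiguous
        value, aligned, total, icp, amb = _attempt(A, b_pts, pre, tau, max_iter)
        trace.append((label, float(angle), value))
        ambiguous = ambiguous or amb
        if best is None or value < best[0]:
            best = (value, aligned, total, icp)
        return value

    # initial attempt: plain principal-axes start
    if record("initial", 0.0, RigidTransform.identity()) < c:
        return _finish(trace, best, c, ambiguous)

    # rotational search about axes from B's centered principal frame
    frame_b = principal_frame(b_pts)
    center_b = frame_b.center
    angles = np.arange(interval, 360.0 - interval / 2, interval)
    for label, combo in _AXIS_COMBOS:
        axis = combo[0] * frame_b.axes[0] + combo[1] * frame_b.axes[1] \
            + combo[2] * frame_b.axes[2]
        for angle in angles:
            R = rotation_about_axis(axis, float(angle))
            pre = RigidTransform(R, center_b - R @ center_b)  # about centroid
            if record(label, angle, pre) < c:
                return _finish(trace, best, c, ambiguous)
    return _finish(trace, best, c, ambiguous)


def _finish(trace, best, c, ambiguous) -> PairwiseResult:
    value, aligned, total, icp = best
    return PairwiseResult(
        transform=total,
        rmsd=value,
        aligned=aligned,
        search_trace=tuple(trace),
        succeeded=value < c,
        icp_iterations=icp.iterations,
        ambiguous_frames=ambiguous,
    )
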