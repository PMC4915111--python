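"""Multiple structure superposition by iterative template selection.

The first template is the structure of median length; every other structure
is pairwise-superposed onto it, and those landing below the RMSD threshold
``c`` are *resolved*.  Each following round promotes the resolved structure
with the largest RMSD to template and retries the unresolved ones against
it; an unresolved structure's recorded RMSD is overwritten only when the new
attempt improves it.  The loop stops when the unresolved set stops shrinking
or empties.  All transforms are composed through the template chain into the
frame of the first template, so every resolved structure lands in one common
frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .geometry import RigidTransform
from .pairwise import DEFAULT_C, closest_point_rmsd, pairwise_superpose

__all__ = ["MultipleResult", "multiple_superpose", "consensus_rmsd"]


@dataclass(frozen=True)
class MultipleResult:
    """Outcome of a multiple superposition.

    ``transforms`` maps each structure id to the rigid transform carrying it
    into the first template's frame.  ``resolved`` and ``unresolved`` list
    (id, rmsd) pairs; the template itself is resolved with rmsd 0.
    """

    transforms: dict
    template_chain: tuple
    resolved: tuple
    unresolved: tuple
    rounds: int

    @property
    def resolved_ids(self) -> tuple:
        return tuple(sid for sid, _ in self.resolved)


def _median_index(structures: Sequence) -> int:
    """Index of the median-length structure (lower median; ties by id)."""
    order = sorted(range(len(structures)),
                   key=lambda i: (len(structures[i]), structures[i].id))
    return order[(len(order) - 1) // 2]


def multiple_superpose(structures: Sequence, c: float = DEFAULT_C,
                       **pairwise_options) -> MultipleResult:
    """Superpose three or more structures into one common frame.

    Parameters
    ----------
    structures : sequence of PointSet
        At least 3 structures with unique ids (pairs belong in
        :func:`~pssm.pairwise.pairwise_superpose`).
    c : float
        RMSD threshold in Å separating resolved from unresolved.
    **pairwise_options
        Forwarded to every pairwise call (interval, tau, max_iter).
    """
    structures = list(structures)
    if len(structures) < 3:
        raise ValueError(
            "multiple_superpose needs n >= 3 structures; use pairwise_superpose for a pair"
        )
    ids = [s.id for s in structures]
    if len(set(ids)) != len(ids):
        raise ValueError("structure ids must be unique")
    by_id = {s.id: s for s in structures}

    m1 = structures[_median_index(structures)]
    # transform of each template into M1's frame
    template_frames = {m1.id: RigidTransform.identity()}
    transforms = {m1.id: RigidTransform.identity()}
    resolved: dict[str, float] = {m1.id: 0.0}
    template_chain = [m1.id]

    # round 1: everything against the median-length template
    pending: dict[str, float] = {}
    for s in structures:
        if s.id == m1.id:
            continue
        res = pairwise_superpose(m1, s, c=c, **pairwise_options)
        if res.succeeded:
            resolved[s.id] = res.rmsd
            transforms[s.id] = res.transform
        else:
            pending[s.id] = res.rmsd
            transforms[s.id] = res.transform
    rounds = 1

    while pending:
        candidates = [sid for sid in resolved if sid not in template_chain]
        if not candidates:
            break
        # promote the resolved structure with the largest rmsd to template
        new_template = max(candidates, key=lambda sid: (resolved[sid], sid))
        template_chain.append(new_template)
        template_frames[new_template] = transforms[new_template]
        before = len(pending)
        rounds += 1
        for sid in list(pending):
            res = pairwise_superpose(by_id[new_template], by_id[sid],
                                     c=c, **pairwise_options)
            into_m1 = template_frames[new_template].compose(res.transform)
            if res.succeeded:
                resolved[sid] = res.rmsd
                transforms[sid] = into_m1
                del pending[sid]
            elif res.rmsd < pending[sid]:  # keep the best failed attempt
                pending[sid] = res.rmsd
                transforms[sid] = into_m1
        if len(pending) == before:
            break

    return MultipleResult(
        transforms=transforms,
        template_chain=tuple(template_chain),
        resolved=tuple(sorted(resolved.items())),
        unresolved=tuple(sorted(pending.items())),
        rounds=rounds,
    )


def consensus_rmsd(result: MultipleResult, structures: Sequence) -> tuple[float, int]:
    """Mean pairwise closest-point RMSD over resolved structures.

    Structures are mapped into the common frame by their fitted transforms;
    the mean runs over all unordered resolved pairs.  The aligned count is
    the smallest resolved structure's size.

    Requires at least two resolved structures.
    """
    by_id = {s.id: s for s in structures}
    ids = [sid for sid in result.resolved_ids if sid in by_id]
    if len(ids) < 2:
        raise ValueError("need at least 2 resolved structures for a consensus RMSD")
    placed = {sid: result.transforms[sid].apply(by_id[sid].coords) for sid in ids}
    values = [closest_point_rmsd(placed[a], placed[b])[0]
              for a, b in combinations(ids, 2)]
    aligned = min(len(by_id[sid]) for sid in ids)
    return float(np.mean(values)), aligned
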