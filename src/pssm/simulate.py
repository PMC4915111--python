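"""Synthetic structures, random rotations, reference rotation matrices and
the atom-deletion robustness harness.

Everything here is a pure function of its parameters and seed, so fixtures
and experiments are reproducible without downloading any real structure.
The synthetic structures are helical backbone traces bent along a smooth
random curve: anisotropic enough for well-separated principal axes, with
realistic local geometry (≈1.5 Å rise and ≈2.3 Å radius per residue, the
dimensions of an α-helix).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import RigidTransform, canonical_quaternion, quat_to_rotation
from .pairwise import pairwise_superpose
from .structio import PointSet

__all__ = [
    "DeletionExperiment",
    "random_rotation",
    "paper_matrices",
    "reference_matrices",
    "delete_atoms",
    "make_synthetic_structure",
    "deletion_experiment",
]

# published example rotations: r1-r3 random orthogonal, r4 = 90° about z,
# fig3a used for the Cα deletion scan, fig3b for the main-chain scan.
_REFERENCE_MATRICES = {
    "r1": [[-0.2579, 0.8740, 0.4117],
           [-0.7291, 0.1035, -0.6766],
           [-0.6339, -0.4747, 0.6106]],
    "r2": [[0.1853, 0.5045, -0.8433],
           [0.8945, -0.4419, -0.0678],
           [-0.4069, -0.7417, -0.5332]],
    "r3": [[-0.6533, -0.7515, -0.0926],
           [0.2860, -0.3581, 0.8888],
           [-0.7010, 0.5541, 0.4489]],
    "r4": [[0.0, -1.0, 0.0],
           [1.0, 0.0, 0.0],
           [0.0, 0.0, 1.0]],
    "r_fig3a": [[0.9548, 0.2182, 0.2019],
                [-0.1777, 0.9634, -0.2007],
                [-0.2383, 0.1558, 0.9586]],
    # note: r_fig3b swaps x and y and has det = -1 (a reflection); it is
    # returned exactly as published — consumers should check the determinant
    "r_fig3b": [[0.0, 1.0, 0.0],
                [1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0]],
}


@dataclass(frozen=True)
class DeletionExperiment:
    """A missing-data robustness scan: superposition RMSD vs atoms deleted."""

    base: PointSet
    rotation: RigidTransform
    mode: str
    region: str
    ks: tuple
    seed: int
    results: tuple  # (k, rmsd Å) in ks order

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": [k for k, _ in self.results],
                "rmsd_angstrom": [r for _, r in self.results],
                "mode": self.mode,
                "region": self.region,
                "seed": self.seed,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def random_rotation(seed) -> RigidTransform:
    """A uniformly distributed proper rotation (no translation), seeded.

    Sampled as a normalized 4-D Gaussian quaternion, which is uniform on
    SO(3); the determinant is always +1.
    """
    rng = np.random.default_rng(seed)
    q = rng.standard_normal(4)
    q = canonical_quaternion(q / np.linalg.norm(q))
    return RigidTransform(quat_to_rotation(q), np.zeros(3))


def reference_matrices() -> dict:
    """The published example rotation matrices, exactly as printed.

    Keys r1–r3 are rounded random orthogonal matrices (orthogonal only to
    their 4-decimal precision), r4 is a 90° rotation about z, r_fig3a the
    deletion-scan rotation, and r_fig3b an x/y swap whose determinant is −1.
    """
    return {name: np.array(mat, dtype=float)
            for name, mat in _REFERENCE_MATRICES.items()}


# historical alias
paper_matrices = reference_matrices


def delete_atoms(ps: PointSet, k: int, mode: str = "ordered",
                 region: str = "whole", seed: Optional[int] = None) -> PointSet:
    """Remove ``k`` atoms from a structure, preserving order of survivors.

    ``mode="ordered"`` removes the first k atoms of the region;
    ``mode="random"`` removes k atoms uniformly without replacement from the
    region (seeded).  ``region="first-100"`` restricts candidate deletions
    to the first 100 atoms of the chain.
    """
    n = len(ps)
    if mode not in ("ordered", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    if region not in ("whole", "first-100"):
        raise ValueError(f"unknown region {region!r}")
    limit = min(100, n) if region == "first-100" else n
    if not 0 <= k < n or k > limit:
        raise ValueError(f"k={k} out of range for {n} atoms (region limit {limit})")
    if k == 0:
        return ps
    if mode == "ordered":
        removed = np.arange(k)
    else:
        rng = np.random.default_rng(seed)
        removed = rng.choice(limit, size=k, replace=False)
    keep = np.setdiff1d(np.arange(n), removed)
    return ps.subset(keep)


def make_synthetic_structure(n: int, seed: int = 0, noise: float = 0.0) -> PointSet:
    """Generate a protein-like backbone trace of ``n`` points.

    A helix (1.5 Å rise, 2.3 Å radius, 100°/residue) is wound along a
    smooth random space curve built from a few low-frequency sinusoids, so
    the point cloud is anisotropic with well-separated principal moments.
    Optional isotropic Gaussian jitter of standard deviation ``noise`` (Å)
    mimics coordinate error.
    """
    if n < 4:
        raise ValueError("need n >= 4 points")
    rng = np.random.default_rng(seed)
    t = np.arange(n, dtype=float)
    z = 1.5 * t
    x = 2.3 * np.cos(np.deg2rad(100.0) * t)
    y = 2.3 * np.sin(np.deg2rad(100.0) * t)
    coords = np.column_stack([x, y, z])
    # gentle random bends: distinct low frequencies in x and y break the
    # cylindrical symmetry of the bare helix
    for axis, freqs in ((0, (1.0, 2.0)), (1, (1.5, 3.0))):
        for f in freqs:
            amp = rng.uniform(3.0, 6.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            coords[:, axis] += amp * np.sin(2.0 * np.pi * f * t / n + phase)
    if noise > 0:
        coords += rng.normal(scale=noise, size=coords.shape)
    return PointSet(id=f"synthetic-{n}-{seed}", coords=coords, selection="ca")


def deletion_experiment(
    base: PointSet,
    rotation: RigidTransform,
    mode: str = "ordered",
    region: str = "first-100",
    ks: Sequence[int] = tuple(range(0, 101, 5)),
    seed: int = 0,
    **pairwise_options,
) -> DeletionExperiment:
    """Missing-data robustness scan against a rotated copy of ``base``.

    For each deletion count k, a copy of ``base`` is rotated by ``rotation``
    and k atoms are deleted from it; the depleted copy is then superposed
    back onto the intact base and the closest-point RMSD recorded.
    """
    ks = tuple(int(k) for k in ks)
    if any(k2 <= k1 for k1, k2 in zip(ks, ks[1:])):
        raise ValueError("ks must be strictly increasing")
    results = []
    for j, k in enumerate(ks):
        copy = base.transformed(rotation)
        # per-k subseed keeps random deletions independent across rows
        depleted = delete_atoms(copy, k, mode=mode, region=region,
                                seed=(seed + 7919 * j) % (2**31))
        res = pairwise_superpose(base, depleted, **pairwise_options)
        results.append((k, res.rmsd))
    return DeletionExperiment(
        base=base, rotation=rotation, mode=mode, region=region,
        ks=ks, seed=seed, results=tuple(results),
    )
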