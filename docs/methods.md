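# Methods

## Model and procedure

The package solves rigid-body superposition: given a fixed structure *A*
and a moving structure *B*, find the proper rotation *R* (det = +1) and
translation *t* minimizing the deviation of *R·B + t* from *A*, without any
residue–residue correspondence. Proper rotations only: a reflected copy of
a chiral molecule is a different molecule, so reflections are excluded at
every stage (the quaternion parameterization cannot produce them; the
Kabsch baseline corrects the determinant sign; the principal-axes candidate
set enumerates only proper sign assignments).

**Paired registration.** For index-paired sets the optimum of
(1/N) Σ‖x_i − R p_i − t‖² is closed-form: with cross-covariance
Σ_px = (1/N) Σ p_i x_iᵀ − μ_p μ_xᵀ, the 4×4 symmetric matrix

    Q = [[tr Σ,      Δᵀ           ],
         [Δ,  Σ + Σᵀ − tr(Σ)·I₃  ]],   Δ = [A₂₃, A₃₁, A₁₂], A = Σ − Σᵀ,

has the optimal unit quaternion as its maximum-eigenvalue eigenvector; the
translation is t = μ_x − R μ_p. We solve the 4×4 eigenproblem with
`numpy.linalg.eigh`. The quaternion sign is canonicalized to q₀ ≥ 0 (first
nonzero component positive when q₀ = 0), making the representative unique.

**ICP.** Correspondence is re-estimated each iteration as the nearest
Euclidean neighbor in the model shape (k-d tree, `scipy.spatial.cKDTree`),
then the *original* data set is registered onto the matched points, so every
registration vector is cumulative and the final one is the complete
transform. The mean-square error sequence is non-increasing and converges
to a local minimum; we stop when it changes by less than τ (default
1e-10 Å², chosen well below atomic-coordinate precision) or at 200
iterations, returning `converged=False` in the latter case rather than
raising. Nearest-neighbor ties are broken toward the lowest model index for
bit-reproducible runs; the correspondence map need not be one-to-one, which
is exactly why atoms missing from one structure do not corrupt the fit.

**Initialization.** ICP only finds the local minimum nearest its start, so
a rough alignment precedes it: centers of mass are superposed and the
principal axes (eigenvectors of the unweighted, N-normalized second-moment
tensor of centered coordinates) aligned in order of decreasing eigenvalue.
Eigenvector sign is fixed deterministically (largest-magnitude component
positive for the first two axes, third axis their cross product), and the
axes-onto-axes fit is an orthogonal Procrustes problem over the four proper
sign assignments; candidates are scored by closest-point mean-square error
with ties broken by enumeration order (++, +−, −+, −−). When this start
still leaves the refined closest-point RMSD at or above the threshold *c*,
a rotational search sweeps pre-rotations of the moving structure about the
axes v₁, v₁±v₂, v₁±v₃ of its own frame, through its centroid, at a fixed
angular interval (default 10°, i.e. 35 orientations per axis, at most 176
attempts including the initial one), re-deriving the principal-axes start
at every orientation and exiting early on the first success; if nothing
reaches *c* the minimum-RMSD attempt is returned with `succeeded=False`.

**Unequal sizes.** RMSD between structures of different size is defined as
the closest-point RMSD driven by the smaller structure (each of its points
matched to its nearest neighbor in the larger), and the aligned count is the
smaller size. Inside ICP the smaller structure always plays the data role —
this avoids forcing unmatched extra atoms of the larger structure to find
partners — and the returned transform is re-expressed to act on *B*
regardless of which structure drove the fit.

**Multiple structures.** The first template is the structure of median
length (lower median for even counts, ties by id). Every other structure is
pairwise-superposed onto it; those below *c* are resolved. Each later round
promotes the resolved structure with the *largest* RMSD to template —
deliberately, since it is the resolved member closest to the unresolved
ones — and retries the rest against it, overwriting an unresolved
structure's record only when the retry improves it. The loop terminates
when the unresolved set empties or stops shrinking (bounded by n rounds).
All transforms are composed through the template chain into the first
template's frame, so one transform per structure lands it in a single
common frame. The family-level summary (`consensus_rmsd`) is the mean
closest-point RMSD over all unordered resolved pairs in that frame; an
alternative would average only template-vs-member values, but the all-pairs
mean does not privilege the template's idiosyncrasies.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `c` | 1.5 | Å | success threshold on the closest-point RMSD; also the resolved/unresolved split in multiple superposition |
| `interval` | 10 | degrees | rotational-search step (sweep 10°…350°) |
| `tau` | 1e-10 | Å² | ICP stop: change in mean-square error |
| `max_iter` | 200 | — | ICP iteration cap |
| `selection` | `ca` | — | atom subset: `ca` (one Cα/residue), `backbone` (N, CA, C, O), `heavy` (all non-hydrogen) |

`c` = 1.5 Å is the conventional "same fold" scale for Cα superpositions;
τ and the iteration cap are set so clean inputs converge to machine
precision while pathological ones terminate in bounded time.

## Structure input

PDB files are parsed with gemmi: first model only, ATOM records only
(HETATM including waters excluded), hydrogens excluded, and for alternate
locations only the blank or 'A' conformer — one deterministic conformer per
structure. Occupancies and B-factors are ignored; file order is preserved.
A plain whitespace-separated xyz text format (one atom per line, extra
fields ignored) covers preprocessed coordinate dumps. PDB output keeps the
fixed-column format, which rounds coordinates to 3 decimals — round-trip
accuracy through files is therefore ~5·10⁻⁴ Å per coordinate, and
pipelines that pass through PDB files bottom out near 10⁻³ Å rather than
10⁻¹⁴ Å.

## Synthetic structures

`make_synthetic_structure` emulates a protein-sized point cloud as a helix
with α-helical local geometry (1.5 Å rise, 2.3 Å radius, 100°/residue)
wound along a smooth random space curve (a few low-frequency sinusoids with
seeded amplitudes 3–6 Å and random phases). The bends break the cylindrical
symmetry of a bare helix so all three principal moments are well separated
(λ₁/λ₃ > 10), giving the initializer the anisotropy real chains have.
What it does *not* emulate: side-chain packing, secondary-structure
diversity, density inhomogeneity, or internal flexibility. Passing the
synthetic recovery tests therefore demonstrates the correctness of the
geometry and optimization machinery — exact rigid relations are recovered to
machine precision, deletions are tolerated — but not biological alignment
quality across genuinely different folds; for that the
`scripts/reproduce_tables.py` harness runs the identical pipeline on real
PDB entries supplied locally.

`random_rotation` samples uniformly on SO(3) via a normalized 4-D Gaussian
quaternion and always returns a proper rotation. MATLAB-style
`orth(rand(3,3))` can yield reflections; since no rotation can superpose a
reflected copy, we treat det = −1 as a pathological input rather than a
rotation to sample. Among the published example matrices kept in
`reference_matrices()`, `r_fig3b` (the x/y swap) has determinant −1 and is
returned exactly as printed with that caveat documented, not silently
repaired; the rounded 4-decimal matrices r1–r3 are orthogonal only to about
5·10⁻⁴ and are projected to the nearest proper rotation (SVD) before being
used to *generate* rotated copies, because applying them raw would shear
the coordinates rather than rotate them.

The deletion harness rotates a copy of a base structure, removes k atoms
(either the first k in chain order, or k drawn uniformly without
replacement, optionally restricted to the first 100 atoms), superposes the
depleted copy back onto the intact base, and tabulates RMSD against k. With
a 108-point structure and 10 random deletions the recovered RMSD stays
below 0.1 Å.

## Numerical choices and degenerate inputs

- Eigen-solvers: `numpy.linalg.eigh` for the symmetric 4×4 and 3×3
  problems; `numpy.linalg.svd` for the Kabsch baseline. The quaternion and
  SVD solutions of the paired problem agree to < 1e-10 Å in RMSD on random
  instances — a standing cross-check in the test suite, alongside
  `scipy.spatial.transform.Rotation.align_vectors` as an external oracle.
- Degenerate principal spectra (near-spherical or cylindrical clouds, gap
  below 1e-9 relative) keep their deterministic ordering and are flagged as
  ambiguous in the rough-alignment details; the rotational search is the
  fallback that makes the overall pipeline insensitive to a wrong initial
  axis choice.
- Structures with fewer than 3 points are rejected everywhere a frame or a
  unique rotation is needed.
- The whole pipeline contains no randomness: repeated runs on identical
  inputs give bit-identical traces. All simulation entry points take
  explicit seeds.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run on synthetic structures of
108 points (the size of a small single-domain Cα trace) and one 835-point
case (a heavy-atom-scale chain), with 100-instance batches for the solver
equivalence and monotonicity properties and 10,000 samples for the
random-rotation angle statistic. These sizes exercise every code path while
keeping the full suite under a minute; the method itself has no intrinsic
size limit beyond the O(m·n) worst-case of nearest-neighbor search.

## Known limitations

- ICP refines to the *local* minimum nearest its start; the rotational
  search widens but does not guarantee the basin of the global optimum for
  genuinely dissimilar structures.
- The closest-point RMSD is not symmetric in information content: the
  larger structure's unmatched atoms are simply ignored, so a small
  fragment can score well against a large structure it partially matches.
- Sustained length mismatch degrades the fit; with much more than ~20% of
  atoms missing from one copy the superposition quality drops sharply,
  ordered (prefix) deletions being harsher than random ones because they
  shift the center of mass and principal axes coherently.
- No scaling, shearing, or flexible/hinge alignment: the model is a single
  global rigid motion.
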