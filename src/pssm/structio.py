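"""Reading and writing structure coordinates.

Two formats are supported: PDB (ATOM records, fixed columns, parsed with
gemmi) and a plain whitespace-separated xyz text format with one atom per
line.  Atom selection happens at read time: ``ca`` keeps one Cα per residue,
``backbone`` keeps N/CA/C/O, ``heavy`` keeps every non-hydrogen protein atom.
Only the first model is read; HETATM records (including waters) and
hydrogens are always excluded; for alternate locations only the blank or 'A'
conformer is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

from .geometry import RigidTransform

__all__ = [
    "AtomLabel",
    "PointSet",
    "SELECTIONS",
    "read_pdb",
    "read_xyz",
    "write_xyz",
    "write_pdb",
    "write_transformed",
    "EmptySelectionError",
    "XYZParseError",
]

SELECTIONS = ("ca", "backbone", "heavy")
_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


class EmptySelectionError(ValueError):
    """No atoms survived the requested selection."""


class XYZParseError(ValueError):
    """A line of an xyz text file could not be parsed."""


@dataclass(frozen=True)
class AtomLabel:
    """Descriptor of one atom: name, residue, chain and insertion code."""

    name: str = ""
    resname: str = ""
    chain: str = ""
    resseq: int = 0
    icode: str = ""
    element: str = ""


@dataclass(frozen=True)
class PointSet:
    """An ordered, labeled set of 3-D atom coordinates for one structure.

    ``coords`` is an (N, 3) float array in Å, in file order.  ``labels`` has
    one :class:`AtomLabel` per point (empty labels for xyz input).
    """

    id: str
    coords: np.ndarray
    labels: tuple = ()
    selection: str = "heavy"

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if coords.shape[0] < 1:
            raise ValueError("a PointSet needs at least one point")
        if not np.isfinite(coords).all():
            raise ValueError("coordinates must be finite")
        coords = coords.copy()
        coords.flags.writeable = False
        object.__setattr__(self, "coords", coords)
        labels = tuple(self.labels)
        if labels and len(labels) != coords.shape[0]:
            raise ValueError("labels length must match the number of points")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def center(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def with_coords(self, coords: np.ndarray) -> "PointSet":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def subset(self, indices) -> "PointSet":
        indices = np.asarray(indices, dtype=int)
        labels = tuple(self.labels[i] for i in indices) if self.labels else ()
        return replace(self, coords=self.coords[indices], labels=labels)

    def transformed(self, t: RigidTransform) -> "PointSet":
        return self.with_coords(t.apply(self.coords))


def _want_atom(atom: gemmi.Atom, selection: str) -> bool:
    if atom.is_hydrogen():
        return False
    if atom.altloc not in ("", "\0", "A"):
        return False
    if selection == "ca":
        return atom.name == "CA" and atom.element.name == "C"
    if selection == "backbone":
        return atom.name in _BACKBONE_NAMES and atom.element.name in ("C", "N", "O")
    return True  # heavy


def read_pdb(path, selection: str = "ca", chain: Optional[str] = None) -> PointSet:
    """Read ATOM coordinates from a PDB file into a :class:`PointSet`.

    Parameters
    ----------
    path : str or Path
        PDB file with at least one ATOM record.
    selection : {"ca", "backbone", "heavy"}
        Atom subset to keep.
    chain : str, optional
        Restrict to a single chain identifier.

    Raises
    ------
    EmptySelectionError
        If no atom passes the selection (wrong chain, HETATM-only file, ...).
    """
    if selection not in SELECTIONS:
        raise ValueError(f"unknown selection {selection!r}; choose from {SELECTIONS}")
    path = Path(path)
    structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    structure.setup_entities()
    coords: list[list[float]] = []
    labels: list[AtomLabel] = []
    if len(structure) == 0:
        raise EmptySelectionError(f"{path}: no model found")
    model = structure[0]  # first model only
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for residue in ch:
            if residue.het_flag != "A":  # skip HETATM, incl. waters/ligands
                continue
            for atom in residue:
                if _want_atom(atom, selection):
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    labels.append(
                        AtomLabel(
                            name=atom.name,
                            resname=residue.name,
                            chain=ch.name,
                            resseq=residue.seqid.num,
                            icode=(residue.seqid.icode or "").strip(),
                            element=atom.element.name,
                        )
                    )
    if not coords:
        where = f" in chain {chain!r}" if chain else ""
        raise EmptySelectionError(
            f"{path}: no atoms match selection {selection!r}{where}"
        )
    return PointSet(id=path.stem, coords=np.array(coords), labels=tuple(labels),
                    selection=selection)


def read_xyz(path) -> PointSet:
    """Read a plain text coordinate file: one atom per line, ``x y z [...]``.

    Blank lines are skipped; fields beyond the third are ignored.
    """
    path = Path(path)
    coords = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            fields = stripped.split()
            if len(fields) < 3:
                raise XYZParseError(
                    f"{path}:{lineno}: expected at least 3 numeric fields, "
                    f"got {len(fields)}"
                )
            try:
                coords.append([float(f) for f in fields[:3]])
            except ValueError as exc:
                raise XYZParseError(f"{path}:{lineno}: {exc}") from exc
    if not coords:
        raise XYZParseError(f"{path}: file contains no coordinates")
    return PointSet(id=path.stem, coords=np.array(coords), selection="heavy")


def write_xyz(ps: PointSet, path) -> None:
    """Write coordinates as plain text, three ``%.3f`` fields per line."""
    with open(path, "w") as fh:
        for x, y, z in ps.coords:
            fh.write(f"{x:.3f} {y:.3f} {z:.3f}\n")


def write_pdb(ps: PointSet, path) -> None:
    """Write a PointSet as fixed-column PDB ATOM records.

    Labels are used when present; unlabeled points become CA atoms of
    consecutive GLY residues in chain A.
    """
    with open(path, "w") as fh:
        for i in range(len(ps)):
            if ps.labels:
                lab = ps.labels[i]
            else:
                lab = AtomLabel(name="CA", resname="GLY", chain="A",
                                resseq=i + 1, element="C")
            name = lab.name if len(lab.name) == 4 else f" {lab.name:<3s}"
            x, y, z = ps.coords[i]
            fh.write(
                f"ATOM  {i + 1:5d} {name}{'':1s}{lab.resname:>3s} "
                f"{(lab.chain or 'A')[:1]}{lab.resseq:4d}{lab.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{lab.element:>2s}\n"
            )
        fh.write("END\n")


def write_transformed(ps: PointSet, t: RigidTransform, path) -> None:
    """Apply ``t`` to ``ps`` and write the result; format chosen by suffix.

    ``.pdb``/``.ent`` give fixed-column PDB output, anything else the plain
    xyz text format.  Atom count and labels are preserved.
    """
    moved = ps.transformed(t)
    suffix = Path(path).suffix.lower()
    if suffix in (".pdb", ".ent"):
        write_pdb(moved, path)
    else:
        write_xyz(moved, path)
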