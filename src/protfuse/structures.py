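"""Protein structures: PDB ingestion, alpha-carbon geometry, rigid transforms.

A :class:`ProteinStructure` is the single object every modality constructor
consumes: an ordered list of heavy protein atoms plus the amino-acid sequence
derived from residues that carry an alpha carbon (CA).  HETATM records
(waters, ligands, ions) and hydrogens are excluded, so point clouds stay
ligand-free and graphs stay CA-anchored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
from biotite.sequence import ProteinSequence

__all__ = [
    "Atom",
    "ProteinStructure",
    "RigidTransform",
    "PDBParseError",
    "parse_pdb",
    "write_pdb",
    "alpha_carbon_coords",
    "apply_transform",
    "three_to_one",
]


class PDBParseError(ValueError):
    """Raised for files with no usable ATOM records or no alpha carbons."""


@dataclass(frozen=True)
class Atom:
    """One heavy protein atom.

    ``residue_index`` is a zero-based ordinal that is globally unique across
    chains (chains are concatenated in file order), not the author residue
    number from the PDB file.
    """

    element: str
    residue_index: int
    residue_type: str  # 3-letter code
    coords: np.ndarray  # shape (3,), Angstrom
    is_alpha_carbon: bool

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("atom coordinates must be a finite 3-vector")
        object.__setattr__(self, "coords", c)


@dataclass(frozen=True)
class ProteinStructure:
    """Parsed structure: atoms in record order plus the CA-derived sequence."""

    id: str
    atoms: tuple[Atom, ...]
    sequence: str = field(default="")

    def __post_init__(self):
        if not self.sequence:
            object.__setattr__(self, "sequence", _sequence_from_atoms(self.atoms))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_coords(self) -> np.ndarray:
        """All atom coordinates as an (n_atoms, 3) array, record order."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProteinStructure):
            return NotImplemented
        if self.id != other.id or self.sequence != other.sequence:
            return False
        if len(self.atoms) != len(other.atoms):
            return False
        for a, b in zip(self.atoms, other.atoms):
            if (a.element, a.residue_index, a.residue_type, a.is_alpha_carbon) != (
                b.element,
                b.residue_index,
                b.residue_type,
                b.is_alpha_carbon,
            ):
                return False
            if not np.array_equal(a.coords, b.coords):
                return False
        return True


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (R in SO(3), t in Angstrom)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-8:
            raise ValueError("rotation matrix is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation matrix must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_THREE_LETTER = {v: k for k, v in _ONE_LETTER.items()}
_THREE_LETTER["X"] = "UNK"


def three_to_one(res_type: str) -> str:
    """3-letter residue code to 1-letter; non-standard residues become 'X'."""
    return _ONE_LETTER.get(res_type.upper(), "X")


def _sequence_from_atoms(atoms) -> str:
    seen: dict[int, str] = {}
    for a in atoms:
        if a.is_alpha_carbon and a.residue_index not in seen:
            seen[a.residue_index] = three_to_one(a.residue_type)
    return "".join(seen[i] for i in sorted(seen))


def parse_pdb(path, structure_id: str | None = None) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Keeps heavy protein atoms (ATOM records) only: HETATM records and
    hydrogens/deuteriums are dropped.  Alternate locations collapse to the
    first-occurring conformer.  Chains are concatenated in file order and
    ``residue_index`` is renumbered to a global zero-based ordinal.

    Raises
    ------
    PDBParseError
        If no protein ATOM records survive filtering, or no residue has a CA.
    """
    pdb_file = pdb.PDBFile.read(str(path))
    try:
        arr = pdb.get_structure(pdb_file, model=1, altloc="first")
    except Exception as exc:  # biotite raises on files without coordinates
        raise PDBParseError(f"{path}: no parsable ATOM records ({exc})") from None

    keep = (~arr.hetero) & ~np.isin(arr.element, ("H", "D"))
    arr = arr[keep]
    if arr.array_length() == 0:
        raise PDBParseError(f"{path}: no protein ATOM records")

    atoms: list[Atom] = []
    res_key_to_index: dict[tuple, int] = {}
    for i in range(arr.array_length()):
        key = (arr.chain_id[i], arr.res_id[i], arr.ins_code[i])
        if key not in res_key_to_index:
            res_key_to_index[key] = len(res_key_to_index)
        atoms.append(
            Atom(
                element=str(arr.element[i]),
                residue_index=res_key_to_index[key],
                residue_type=str(arr.res_name[i]),
                coords=arr.coord[i].astype(float),
                is_alpha_carbon=(arr.atom_name[i] == "CA" and arr.element[i] == "C"),
            )
        )
    if not any(a.is_alpha_carbon for a in atoms):
        raise PDBParseError(f"{path}: structure has no alpha carbons")

    if structure_id is None:
        import os

        structure_id = os.path.splitext(os.path.basename(str(path)))[0]
    return ProteinStructure(id=structure_id, atoms=tuple(atoms))


def write_pdb(s: ProteinStructure, path) -> None:
    """Serialize a structure back to a single-chain PDB file."""
    n = s.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = s.atom_coords().astype(np.float32)
    # per-residue atom naming: CA for alpha carbons, element+ordinal otherwise
    counters: dict[tuple[int, str], int] = {}
    for i, a in enumerate(s.atoms):
        arr.chain_id[i] = "A"
        arr.res_id[i] = a.residue_index + 1
        arr.res_name[i] = _THREE_LETTER.get(three_to_one(a.residue_type), "UNK")
        if a.is_alpha_carbon:
            name = "CA"
        else:
            counters[(a.residue_index, a.element)] = (
                counters.get((a.residue_index, a.element), 0) + 1
            )
            name = f"{a.element}B{counters[(a.residue_index, a.element)]}"[:4]
        arr.atom_name[i] = name
        arr.element[i] = a.element
        arr.hetero[i] = False
    pdb_file = pdb.PDBFile()
    pdb.set_structure(pdb_file, arr)
    pdb_file.write(str(path))


def alpha_carbon_coords(s: ProteinStructure) -> np.ndarray:
    """CA coordinates, one row per sequence position, residue order. (N, 3) Angstrom."""
    rows: dict[int, np.ndarray] = {}
    for a in s.atoms:
        if a.is_alpha_carbon and a.residue_index not in rows:
            rows[a.residue_index] = a.coords
    if not rows:
        raise ValueError("structure has no alpha carbons")
    return np.array([rows[i] for i in sorted(rows)], dtype=float)


def apply_transform(s: ProteinStructure, T: RigidTransform) -> ProteinStructure:
    """Map every atom coordinate x -> R x + t; all other fields unchanged."""
    R, t = T.rotation, T.translation
    new_atoms = tuple(replace(a, coords=R @ a.coords + t) for a in s.atoms)
    return ProteinStructure(id=s.id, atoms=new_atoms, sequence=s.sequence)
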