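"""Molecular data model and chemical/tabular file I/O.

The screening substrate is a small molecule with explicit 3D coordinates
(``Molecule3D``); docking results are rows of a compound x target score
table (``ScoreRecord``, binding free energy in kcal/mol, more negative =
predicted stronger binding).  SDF V2000 is the interchange format for
structures and plain CSV for score tables.  Only pre-generated 3D input is
accepted: no conformer embedding or minimisation happens here, and explicit
hydrogens are expected when hydrogen-bond donors are to be perceived.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

# RDKit prints every parse failure to stderr; failures are re-raised below
# as SDFParseError with the record number, so silence the duplicate noise.
RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ("compound_id", "target_id", "binding_energy")


class SDFParseError(ValueError):
    """A structure record could not be parsed (names the record number)."""


class ScoreTableError(ValueError):
    """A docking score table is malformed or ambiguous."""


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, formal charge and coordinates in Angstrom."""

    element: str
    formal_charge: int
    xyz: tuple[float, float, float]


@dataclass(frozen=True)
class Bond:
    """A bond between atom indices ``i`` and ``j`` (0-based, i < j stored as given)."""

    i: int
    j: int
    order: int = 1
    aromatic: bool = False


@dataclass
class Molecule3D:
    """A 3D small molecule with atoms, bonds and free-form property tags."""

    id: str
    atoms: list[Atom]
    bonds: list[Bond]
    properties: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.id!r}: at least one atom required")
        n = len(self.atoms)
        for a in self.atoms:
            if not all(math.isfinite(c) for c in a.xyz):
                raise ValueError(f"molecule {self.id!r}: non-finite coordinate")
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"molecule {self.id!r}: bond index out of range")
            if b.i == b.j:
                raise ValueError(f"molecule {self.id!r}: self-bond on atom {b.i}")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"molecule {self.id!r}: duplicate bond {key}")
            seen.add(key)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Angstrom."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def adjacency(self) -> list[set[int]]:
        """Neighbour sets per atom index."""
        adj: list[set[int]] = [set() for _ in self.atoms]
        for b in self.bonds:
            adj[b.i].add(b.j)
            adj[b.j].add(b.i)
        return adj

    def has_explicit_hydrogens(self) -> bool:
        return any(a.element == "H" for a in self.atoms)


@dataclass(frozen=True)
class ScoreRecord:
    """One docking result: compound x target binding free energy (kcal/mol)."""

    compound_id: str
    target_id: str
    binding_energy: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.binding_energy):
            raise ValueError(
                f"({self.compound_id}, {self.target_id}): non-finite binding energy"
            )


_BOND_TYPES = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}


def _from_rdkit(rdmol: Chem.Mol, index: int) -> Molecule3D:
    name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
    if not name:
        name = f"record-{index}"
    conf = rdmol.GetConformer()
    atoms = []
    for a in rdmol.GetAtoms():
        p = conf.GetAtomPosition(a.GetIdx())
        atoms.append(Atom(a.GetSymbol(), a.GetFormalCharge(), (p.x, p.y, p.z)))
    bonds = []
    for b in rdmol.GetBonds():
        aromatic = b.GetBondType() == Chem.BondType.AROMATIC
        order = 1
        if b.GetBondType() == Chem.BondType.DOUBLE:
            order = 2
        elif b.GetBondType() == Chem.BondType.TRIPLE:
            order = 3
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order, aromatic))
    props = {k: rdmol.GetProp(k) for k in rdmol.GetPropNames()}
    return Molecule3D(id=name, atoms=atoms, bonds=bonds, properties=props)


def _to_rdkit(mol: Molecule3D) -> Chem.Mol:
    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    for b in mol.bonds:
        bt = Chem.BondType.AROMATIC if b.aromatic else _BOND_TYPES[b.order]
        rw.AddBond(b.i, b.j, bt)
        if b.aromatic:
            rw.GetAtomWithIdx(b.i).SetIsAromatic(True)
            rw.GetAtomWithIdx(b.j).SetIsAromatic(True)
            rw.GetBondBetweenAtoms(b.i, b.j).SetIsAromatic(True)
    conf = Chem.Conformer(len(mol.atoms))
    for idx, a in enumerate(mol.atoms):
        conf.SetAtomPosition(idx, a.xyz)
    out = rw.GetMol()
    out.AddConformer(conf)
    out.UpdatePropertyCache(strict=False)
    out.SetProp("_Name", mol.id)
    for k, v in mol.properties.items():
        out.SetProp(k, str(v))
    return out


def read_sdf(path: str | Path) -> list[Molecule3D]:
    """Read an SDF V2000 file into a list of :class:`Molecule3D`.

    Atom order, explicit hydrogens, aromatic bond flags and property tags
    are preserved.  A malformed record (bad counts line, dangling bond
    index, unreadable coordinates) raises :class:`SDFParseError` naming the
    1-based record number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:  # an empty file is a valid zero-record SDF
        return []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    mols: list[Molecule3D] = []
    for i, rd in enumerate(supplier, start=1):
        if rd is None:
            raise SDFParseError(f"{path}: record {i} could not be parsed")
        mols.append(_from_rdkit(rd, i))
    return mols


def write_sdf(mols: Sequence[Molecule3D], path: str | Path) -> None:
    """Write molecules as SDF V2000 (coordinates at 4 decimal places).

    An empty list produces an empty file.  Aromatic bonds are emitted with
    order 4 so the flags survive a round trip.
    """
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for mol in mols:
            writer.write(_to_rdkit(mol))
    finally:
        writer.close()


def read_score_table(path: str | Path) -> list[ScoreRecord]:
    """Read a docking score CSV with columns compound_id,target_id,binding_energy.

    Raises :class:`ScoreTableError` on a missing column, a non-numeric or
    non-finite energy, or a duplicate (compound, target) pair (the score
    would be ambiguous).
    """
    df = pd.read_csv(path, dtype={"compound_id": str, "target_id": str})
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ScoreTableError(f"{path}: missing column(s) {missing}")
    energies = pd.to_numeric(df["binding_energy"], errors="coerce")
    bad = df.loc[energies.isna() | ~np.isfinite(energies.fillna(np.inf))]
    if len(bad):
        raise ScoreTableError(
            f"{path}: non-numeric binding_energy in row(s) {list(bad.index)}"
        )
    dup = df.duplicated(subset=["compound_id", "target_id"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["compound_id", "target_id"]].drop_duplicates()
        raise ScoreTableError(
            f"{path}: duplicate (compound, target) pair(s): "
            + ", ".join(f"({r.compound_id}, {r.target_id})" for r in pairs.itertuples())
        )
    return [
        ScoreRecord(str(c), str(t), float(e))
        for c, t, e in zip(df["compound_id"], df["target_id"], energies)
    ]


def write_score_table(records: Iterable[ScoreRecord], path: str | Path) -> None:
    """Write score records as CSV (columns compound_id,target_id,binding_energy)."""
    df = pd.DataFrame(
        [(r.compound_id, r.target_id, r.binding_energy) for r in records],
        columns=list(SCORE_COLUMNS),
    )
    df.to_csv(path, index=False)
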