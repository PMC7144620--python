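"""Protein, ligand and pocket structures read from PDB files.

A *pocket* here is a set of protein residues with coordinates; its geometry
is summarised by the centroid of its Cα atoms.  The known (native) pocket of
a complex is the set of residues with any atom within a fixed radius
(default 1 nm) of any ligand atom; candidate pockets proposed by cavity
detectors such as fpocket are read from their per-pocket PDB output files.

All coordinates are stored in Å (the PDB convention); distance thresholds in
the public API are expressed in nm and converted at the boundary (1 nm = 10 Å).
"""

from __future__ import annotations

import glob
import io
import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

NM_PER_ANGSTROM = 0.1

#: residue names never counted as protein pocket residues: waters and
#: common crystallographic ions / small additives.
NON_PROTEIN_RESNAMES = frozenset(
    {
        "HOH", "WAT", "DOD",
        "NA", "CL", "K", "MG", "ZN", "CA", "MN", "FE", "CU", "NI", "CO",
        "CD", "HG", "BR", "IOD", "SO4", "PO4", "NO3", "ACT", "GOL", "EDO",
        "PEG", "DMS",
    }
)

ResidueId = tuple[str, int, str]  # (chain id, residue number, insertion code)


class StructureParseError(ValueError):
    """Raised when a PDB file or text cannot be parsed into atoms."""


class EmptyPocketError(ValueError):
    """Raised when a pocket definition yields no residues or no Cα atoms."""


@dataclass
class Atom:
    """A single atom with its residue context and position (Å)."""

    name: str
    element: str
    residue_name: str
    residue_id: ResidueId
    xyz: np.ndarray
    hetero: bool = False

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")

    @property
    def is_calpha(self) -> bool:
        return self.name == "CA" and self.residue_name not in NON_PROTEIN_RESNAMES


@dataclass
class Structure:
    """Atoms grouped by residue, in file order."""

    id: str
    atoms: list[Atom] = field(default_factory=list)

    def residues(self) -> dict[ResidueId, list[Atom]]:
        groups: dict[ResidueId, list[Atom]] = {}
        for atom in self.atoms:
            groups.setdefault(atom.residue_id, []).append(atom)
        return groups

    def protein_atoms(self) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.residue_name not in NON_PROTEIN_RESNAMES and not a.hetero
        ]

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class Pocket:
    """A candidate or known binding pocket: residues plus their atoms."""

    id: str
    residues: list[tuple[ResidueId, str]]
    atoms: list[Atom]
    source: str = "predicted"  # "known" | "predicted"

    def __post_init__(self) -> None:
        if not self.residues:
            raise EmptyPocketError(f"pocket {self.id}: empty residue set")
        listed = {rid for rid, _ in self.residues}
        for atom in self.atoms:
            if atom.residue_id not in listed:
                raise ValueError(
                    f"pocket {self.id}: atom {atom.name} belongs to unlisted "
                    f"residue {atom.residue_id}"
                )
        if not any(a.is_calpha for a in self.atoms):
            raise EmptyPocketError(f"pocket {self.id}: no Cα atom present")

    @property
    def residue_names(self) -> list[str]:
        return [name for _, name in self.residues]


@dataclass
class LigandRecord:
    """A ligand given as SMILES and/or as placed atoms.

    Exactly one of ``smiles``/``atoms`` is required at parse time; both may
    be present (SMILES for featurization, atoms for geometry).
    """

    id: str
    smiles: str | None = None
    atoms: list[Atom] | None = None
    source_format: str = "SMILES"  # SMILES | SDF | MOL2 | PDB

    def __post_init__(self) -> None:
        if self.smiles is None and not self.atoms:
            raise ValueError(f"ligand {self.id}: needs SMILES or atoms")

    @classmethod
    def from_smiles(cls, smiles: str, id: str = "ligand") -> "LigandRecord":
        from rdkit import Chem

        if Chem.MolFromSmiles(smiles) is None:
            raise ValueError(f"ligand {id}: unparseable SMILES {smiles!r}")
        return cls(id=id, smiles=smiles, source_format="SMILES")

    @classmethod
    def from_file(cls, path: str | os.PathLike, id: str | None = None) -> "LigandRecord":
        """Read a ligand from SDF, MOL2 or PDB, perceiving a SMILES string."""
        from rdkit import Chem

        path = os.fspath(path)
        ext = os.path.splitext(path)[1].lower()
        readers = {
            ".sdf": (Chem.MolFromMolFile, "SDF"),
            ".mol": (Chem.MolFromMolFile, "SDF"),
            ".mol2": (Chem.MolFromMol2File, "MOL2"),
            ".pdb": (Chem.MolFromPDBFile, "PDB"),
        }
        if ext not in readers:
            raise ValueError(f"unsupported ligand format: {path}")
        reader, fmt = readers[ext]
        mol = reader(path, sanitize=True)
        if mol is None:
            raise ValueError(f"could not parse ligand file {path}")
        lig_id = id or os.path.splitext(os.path.basename(path))[0]
        atoms = []
        if mol.GetNumConformers():
            conf = mol.GetConformer()
            for rd_atom in mol.GetAtoms():
                pos = conf.GetAtomPosition(rd_atom.GetIdx())
                atoms.append(
                    Atom(
                        name=rd_atom.GetSymbol() + str(rd_atom.GetIdx() + 1),
                        element=rd_atom.GetSymbol(),
                        residue_name="LIG",
                        residue_id=("L", 1, " "),
                        xyz=np.array([pos.x, pos.y, pos.z]),
                    )
                )
        return cls(
            id=lig_id,
            smiles=Chem.MolToSmiles(mol),
            atoms=atoms or None,
            source_format=fmt,
        )

    def coordinates(self) -> np.ndarray:
        if not self.atoms:
            raise ValueError(f"ligand {self.id}: no placed atoms available")
        return np.array([a.xyz for a in self.atoms])


def _validate_coordinate_columns(text: str) -> None:
    """Check ATOM/HETATM coordinate fields so errors can name the line."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise StructureParseError(
                        f"line {lineno}: unparseable coordinate field {line[lo:hi]!r}"
                    ) from None


def read_structure(pdb_text: str, id: str = "structure") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Alternate locations keep the first-listed conformer; hydrogens are kept.
    Raises :class:`StructureParseError` on malformed coordinates (with the
    line number) or when no atoms are found.
    """
    from Bio.PDB import PDBParser

    _validate_coordinate_columns(pdb_text)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            bio_structure = parser.get_structure(id, io.StringIO(pdb_text))
        except Exception as exc:  # Bio.PDB raises assorted exception types
            raise StructureParseError(f"{id}: {exc}") from exc

    atoms: list[Atom] = []
    model = next(bio_structure.get_models(), None)
    if model is not None:
        for chain in model:
            for residue in chain:
                het_flag, resseq, icode = residue.id
                rid: ResidueId = (chain.id, resseq, icode)
                for bio_atom in residue.get_unpacked_list():
                    atom = Atom(
                        name=bio_atom.get_name(),
                        element=bio_atom.element or bio_atom.get_name()[:1],
                        residue_name=residue.get_resname().strip(),
                        residue_id=rid,
                        xyz=bio_atom.get_coord().astype(float),
                    )
                    atom.hetero = het_flag.strip() != ""
                    atoms.append(atom)
    if not atoms:
        raise StructureParseError(f"{id}: no ATOM/HETATM records found")
    return Structure(id=id, atoms=_dedupe_altlocs(atoms))


def _dedupe_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep the first-listed alternate location per (residue, atom name)."""
    seen: set[tuple[ResidueId, str]] = set()
    out = []
    for a in atoms:
        key = (a.residue_id, a.name)
        if key in seen:
            continue
        seen.add(key)
        out.append(a)
    return out


def read_structure_file(path: str | os.PathLike) -> Structure:
    path = os.fspath(path)
    with open(path) as fh:
        text = fh.read()
    sid = os.path.splitext(os.path.basename(path))[0]
    return read_structure(text, id=sid)


def extract_ligand(structure: Structure, resname: str, smiles: str | None = None) -> LigandRecord:
    """Pull a HETATM residue out of a structure as the ligand."""
    atoms = [a for a in structure.atoms if a.residue_name == resname]
    if not atoms:
        raise ValueError(f"no residue named {resname!r} in structure {structure.id}")
    return LigandRecord(id=resname, smiles=smiles, atoms=atoms, source_format="PDB")


def known_pocket(
    structure: Structure,
    ligand: LigandRecord,
    radius_nm: float = 1.0,
) -> Pocket:
    """The known pocket: protein residues within ``radius_nm`` of the ligand.

    A residue belongs to the pocket when any of its atoms lies within
    ``radius_nm`` (converted to Å) of any ligand atom.
    """
    if radius_nm <= 0:
        raise ValueError("radius_nm must be positive")
    lig_xyz = ligand.coordinates()
    cutoff = radius_nm * 10.0  # nm -> Å

    ligand_ids = {a.residue_id for a in (ligand.atoms or [])}
    residues: list[tuple[ResidueId, str]] = []
    atoms: list[Atom] = []
    for rid, res_atoms in structure.residues().items():
        name = res_atoms[0].residue_name
        if name in NON_PROTEIN_RESNAMES or rid in ligand_ids or res_atoms[0].hetero:
            continue
        coords = np.array([a.xyz for a in res_atoms])
        d = np.linalg.norm(coords[:, None, :] - lig_xyz[None, :, :], axis=-1)
        if d.min() <= cutoff:
            residues.append((rid, name))
            atoms.extend(res_atoms)
    if not residues:
        raise EmptyPocketError(
            f"no residue within {radius_nm} nm of ligand {ligand.id}"
        )
    return Pocket(id="known", residues=residues, atoms=atoms, source="known")


def pocket_from_structure(structure: Structure, pocket_id: str, source: str = "predicted") -> Pocket:
    """Treat every residue of a (pocket) structure as one pocket."""
    residues = [
        (rid, res_atoms[0].residue_name)
        for rid, res_atoms in structure.residues().items()
        if res_atoms[0].residue_name not in NON_PROTEIN_RESNAMES
    ]
    keep = {rid for rid, _ in residues}
    atoms = [a for a in structure.atoms if a.residue_id in keep]
    return Pocket(id=pocket_id, residues=residues, atoms=atoms, source=source)


def read_pocket_dir(
    path: str | os.PathLike,
    pattern: str = "pocket*_atm.pdb",
) -> list[Pocket]:
    """Read an fpocket-style directory of per-pocket PDB files.

    Pocket ids are the rank numbers embedded in the filenames
    (``pocket<k>_atm.pdb``).  Files without any Cα atom, or that fail to
    parse, are skipped with a logged warning.
    """
    path = os.fspath(path)
    files = sorted(glob.glob(os.path.join(path, pattern)), key=_pocket_sort_key)
    if not files:
        raise FileNotFoundError(f"no files matching {pattern!r} in {path}")
    pockets = []
    for fname in files:
        pid = _pocket_rank(fname)
        try:
            structure = read_structure_file(fname)
            pockets.append(pocket_from_structure(structure, pocket_id=pid))
        except (StructureParseError, EmptyPocketError, ValueError) as exc:
            logger.warning("skipping pocket file %s: %s", fname, exc)
    return pockets


def _pocket_rank(fname: str) -> str:
    base = os.path.basename(fname)
    digits = "".join(ch for ch in base if ch.isdigit())
    return digits or os.path.splitext(base)[0]


def _pocket_sort_key(fname: str):
    rank = _pocket_rank(fname)
    return (0, int(rank)) if rank.isdigit() else (1, rank)


def calpha_center(pocket: Pocket) -> np.ndarray:
    """Arithmetic mean of the pocket's Cα coordinates (Å)."""
    coords = np.array([a.xyz for a in pocket.atoms if a.is_calpha])
    if coords.size == 0:
        raise EmptyPocketError(f"pocket {pocket.id}: no Cα atoms")
    return coords.mean(axis=0)


def center_distance(a: Pocket, b: Pocket) -> float:
    """Distance between two pockets' Cα centroids, in nm."""
    return float(np.linalg.norm(calpha_center(a) - calpha_center(b))) * NM_PER_ANGSTROM
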