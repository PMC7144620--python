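"""Shared fixtures: small embedding tables, hand-built pockets, toy complexes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from pocketrank.structures import Atom, LigandRecord, Pocket, Structure, extract_ligand, known_pocket, read_pocket_dir, read_structure_file
from pocketrank.synthetic import ToyComplex, ToyComplexSpec, make_embedding_table, make_toy_complex


def make_atom(xyz, name="CA", resname="ALA", chain="A", resnum=1, element="C", hetero=False):
    return Atom(
        name=name,
        element=element,
        residue_name=resname,
        residue_id=(chain, resnum, " "),
        xyz=np.asarray(xyz, dtype=float),
        hetero=hetero,
    )


def pocket_at(center_nm, pocket_id="p", resnames=("ALA",), chain="A"):
    """Single-ring pocket whose Cα centroid is exactly ``center_nm`` (nm)."""
    center = np.asarray(center_nm, dtype=float) * 10.0  # nm -> Å
    n = len(resnames)
    if n == 1:
        coords = [center]
    else:
        angles = 2 * np.pi * np.arange(n) / n
        coords = center + 3.0 * np.column_stack(
            [np.cos(angles), np.sin(angles), np.zeros(n)]
        )
    atoms = [
        make_atom(xyz, resname=rn, chain=chain, resnum=i + 1)
        for i, (rn, xyz) in enumerate(zip(resnames, coords))
    ]
    residues = [(a.residue_id, a.residue_name) for a in atoms]
    return Pocket(id=pocket_id, residues=residues, atoms=atoms)


@pytest.fixture(scope="session")
def table16():
    """Small-dimension embedding table covering the amino-acid vocabulary."""
    return make_embedding_table(dim=16, seed=0)


@dataclass
class ParsedComplex:
    toy: ToyComplex
    structure: Structure
    ligand: LigandRecord
    known: Pocket
    decoys: list[Pocket]


@pytest.fixture
def toy_complex_factory(tmp_path):
    counter = [0]

    def build(**kwargs) -> ParsedComplex:
        counter[0] += 1
        kwargs.setdefault("decoy_distances_nm", [0.1, 0.2, 0.5, 1.5, 2.0, 2.5])
        kwargs.setdefault("seed", counter[0])
        kwargs.setdefault("complex_id", f"toy{counter[0]}")
        spec = ToyComplexSpec(**kwargs)
        toy = make_toy_complex(spec, tmp_path / spec.complex_id)
        structure = read_structure_file(toy.protein_path)
        ligand = extract_ligand(structure, "LIG", smiles=spec.ligand_smiles)
        return ParsedComplex(
            toy=toy,
            structure=structure,
            ligand=ligand,
            known=known_pocket(structure, ligand),
            decoys=read_pocket_dir(toy.pocket_dir),
        )

    return build
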