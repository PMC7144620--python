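"""PDB parsing, known-pocket extraction and pocket geometry."""

import itertools

import numpy as np
import pytest

from pocketrank.structures import (
    EmptyPocketError,
    Pocket,
    Structure,
    StructureParseError,
    calpha_center,
    center_distance,
    known_pocket,
    read_pocket_dir,
    read_structure,
)
from pocketrank.structures import LigandRecord

from conftest import make_atom, pocket_at

ATOM_LINE = "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C"


class TestReadStructure:
    def test_single_atom_coordinates(self):
        s = read_structure(ATOM_LINE)
        assert len(s) == 1
        assert np.allclose(s.atoms[0].xyz, [1.0, 2.0, 3.0])
        assert s.atoms[0].residue_id == ("A", 1, " ")

    def test_residue_grouping(self):
        lines = []
        serial = 1
        for resnum in (1, 2):
            for name in ("N", "CA", "C"):
                lines.append(
                    f"ATOM  {serial:>5d}  {name:<3s} GLY A{resnum:>4d}    "
                    f"{serial:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           "
                    f"{name[0]:>1s}"
                )
                serial += 1
        s = read_structure("\n".join(lines))
        assert len(s) == 6
        assert len(s.residues()) == 2

    def test_malformed_coordinate_names_line(self):
        bad = ATOM_LINE[:30] + "  xx.yyy" + ATOM_LINE[38:]
        with pytest.raises(StructureParseError, match="line 1"):
            read_structure(bad)

    def test_empty_structure_rejected(self):
        with pytest.raises(StructureParseError):
            read_structure("REMARK nothing here\nEND\n")

    def test_first_altloc_kept(self):
        lines = [
            "ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.50  0.00           C",
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.50  0.00           C",
        ]
        s = read_structure("\n".join(lines))
        assert len(s) == 1
        assert s.atoms[0].xyz[0] == pytest.approx(1.0)

    def test_write_read_round_trip(self, toy_complex_factory):
        """Coordinates survive a write/parse cycle to 3 decimals."""
        cx = toy_complex_factory()
        with open(cx.toy.protein_path) as fh:
            text = fh.read()
        again = read_structure(text)
        assert len(again) == len(cx.structure)
        for a, b in zip(again.atoms, cx.structure.atoms):
            assert np.allclose(a.xyz, b.xyz, atol=5e-4)


class TestKnownPocket:
    def _structure(self, positions):
        atoms = [
            make_atom(xyz, resnum=i + 1) for i, xyz in enumerate(positions)
        ]
        return Structure(id="s", atoms=atoms)

    def _ligand(self):
        return LigandRecord(
            id="lig",
            atoms=[make_atom([0.0, 0.0, 0.0], name="C1", resname="LIG",
                             chain="L", hetero=True)],
        )

    def test_radius_threshold(self):
        s = self._structure([[5.0, 0, 0], [12.0, 0, 0]])
        p = known_pocket(s, self._ligand(), radius_nm=1.0)
        assert [rid for rid, _ in p.residues] == [("A", 1, " ")]

    def test_larger_radius_includes_both(self):
        s = self._structure([[5.0, 0, 0], [12.0, 0, 0]])
        p = known_pocket(s, self._ligand(), radius_nm=1.2)
        assert len(p.residues) == 2

    def test_no_residue_in_radius(self):
        s = self._structure([[50.0, 0, 0]])
        with pytest.raises(EmptyPocketError):
            known_pocket(s, self._ligand(), radius_nm=1.0)

    def test_matches_brute_force_scan(self, toy_complex_factory):
        """Agreement with an all-pairs O(N·M) distance scan."""
        cx = toy_complex_factory()
        pocket = known_pocket(cx.structure, cx.ligand, radius_nm=1.0)
        lig_xyz = cx.ligand.coordinates()
        expected = set()
        for rid, atoms in cx.structure.residues().items():
            if atoms[0].hetero:
                continue
            for atom, lig in itertools.product(atoms, lig_xyz):
                if np.linalg.norm(atom.xyz - lig) <= 10.0:
                    expected.add(rid)
                    break
        assert {rid for rid, _ in pocket.residues} == expected

    def test_monotone_in_radius(self, toy_complex_factory):
        cx = toy_complex_factory()
        previous: set = set()
        for r in (0.55, 0.7, 1.0, 1.5):
            res = {rid for rid, _ in known_pocket(cx.structure, cx.ligand, r).residues}
            assert previous <= res
            previous = res


class TestPocketGeometry:
    def test_single_calpha_center(self):
        p = pocket_at([0.1, 0.1, 0.1], resnames=("ALA",))
        assert np.allclose(calpha_center(p), [1.0, 1.0, 1.0])

    def test_two_calpha_mean(self):
        atoms = [
            make_atom([0, 0, 0], resnum=1),
            make_atom([2, 0, 0], resnum=2),
        ]
        p = Pocket(id="p", residues=[(a.residue_id, a.residue_name) for a in atoms], atoms=atoms)
        assert np.allclose(calpha_center(p), [1, 0, 0])

    def test_random_pocket_matches_componentwise_mean(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(-20, 20, size=(10, 3))
        atoms = [make_atom(xyz, resnum=i + 1) for i, xyz in enumerate(coords)]
        p = Pocket(id="p", residues=[(a.residue_id, a.residue_name) for a in atoms], atoms=atoms)
        assert np.allclose(calpha_center(p), coords.mean(axis=0), atol=1e-12)

    def test_pocket_without_calpha_rejected(self):
        atom = make_atom([0, 0, 0], name="CB")
        with pytest.raises(EmptyPocketError):
            Pocket(id="p", residues=[(atom.residue_id, atom.residue_name)], atoms=[atom])

    def test_center_distance_identical_zero(self):
        p = pocket_at([0.5, 0, 0])
        assert center_distance(p, p) == 0.0

    def test_center_distance_unit_conversion(self):
        a = pocket_at([0, 0, 0], pocket_id="a")
        b = pocket_at([1.0, 0, 0], pocket_id="b")  # 10 Å apart
        assert center_distance(a, b) == pytest.approx(1.0)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(11)
        pockets = [pocket_at(rng.uniform(-3, 3, 3), pocket_id=str(i)) for i in range(4)]
        for a, b, c in itertools.permutations(pockets, 3):
            assert center_distance(a, b) == pytest.approx(center_distance(b, a))
            assert center_distance(a, c) <= center_distance(a, b) + center_distance(b, c) + 1e-12


class TestPocketDir:
    def test_reads_ranked_files(self, toy_complex_factory):
        cx = toy_complex_factory(decoy_distances_nm=[0.5, 1.5])
        assert [p.id for p in cx.decoys] == ["1", "2"]
        assert all(p.source == "predicted" for p in cx.decoys)

    def test_empty_directory_errors(self, tmp_path):
        d = tmp_path / "pockets"
        d.mkdir()
        with pytest.raises(FileNotFoundError):
            read_pocket_dir(d)

    def test_file_without_calpha_skipped(self, tmp_path, caplog):
        d = tmp_path / "pockets"
        d.mkdir()
        (d / "pocket1_atm.pdb").write_text(
            "ATOM      1  CB  ALA P 101       0.000   0.000   0.000  1.00  0.00           C\n"
        )
        (d / "pocket2_atm.pdb").write_text(
            "ATOM      1  CA  ALA P 201       0.000   0.000   0.000  1.00  0.00           C\n"
        )
        pockets = read_pocket_dir(d)
        assert [p.id for p in pockets] == ["2"]

    def test_residues_match_generator_manifest(self, toy_complex_factory):
        cx = toy_complex_factory(decoy_distances_nm=[0.5, 1.5, 2.0, 2.5, 3.0])
        by_id = {entry["pocket_id"]: entry for entry in cx.toy.manifest}
        assert len(cx.decoys) == 5
        for pocket in cx.decoys:
            assert pocket.residue_names == by_id[pocket.id]["residue_names"]
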