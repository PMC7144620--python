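"""Synthetic fixtures: embedding tables, toy complexes, separable vectors.

These generators emit exactly the dialects the real pipeline consumes —
standard PDB files, fpocket-style pocket directories, word2vec-text
embedding tables — with controlled geometry and class structure, so every
stage can be exercised and checked without any external download.

A toy complex is a geometric Cα scaffold: the known pocket is a ring of
residues around a placed ligand, and each decoy pocket is a ring whose Cα
centroid sits at a requested distance from the known pocket's centroid.
Near-native decoys reuse the known pocket's residue composition (with a
small substitution), while far decoys draw their residues from a disjoint
residue alphabet.  This encodes native-likeness compositionally — the
signal that, in real data, arises because near-native pockets are built
from the native pocket's own residues.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .featurize import AMINO_ACID_SMILES, DEFAULT_RADII, EmbeddingTable, mol_to_sentence
from .structures import Atom, LigandRecord, Pocket, Structure

#: residue alphabets for native-like vs far pockets (disjoint halves of the
#: standard twenty, split roughly by hydrophobicity).
POSITIVE_ALPHABET = ("ALA", "LEU", "ILE", "VAL", "PHE", "MET", "TRP", "GLY", "PRO", "CYS")
NEGATIVE_ALPHABET = ("SER", "THR", "TYR", "ASN", "GLN", "ASP", "GLU", "LYS", "ARG", "HIS")

DEFAULT_LIGAND_SMILES = ("CCO", "CC(=O)O", "c1ccccc1", "CCN", "CC(C)O")


# --------------------------------------------------------------- embeddings

def required_vocabulary(
    ligand_smiles: Sequence[str] = DEFAULT_LIGAND_SMILES,
    radii: Sequence[int] = DEFAULT_RADII,
) -> list[str]:
    """All substructure identifiers produced by the 20 amino acids plus a
    ligand alphabet."""
    words: set[str] = set()
    for smiles in list(AMINO_ACID_SMILES.values()) + list(ligand_smiles):
        words.update(mol_to_sentence(smiles, radii=radii).words)
    return sorted(words)


def make_embedding_table(
    vocab_size: int = 0,
    dim: int = 300,
    seed: int = 0,
    ligand_smiles: Sequence[str] = DEFAULT_LIGAND_SMILES,
    cover_amino_acids: bool = True,
) -> EmbeddingTable:
    """Random embedding table with i.i.d. standard-normal vectors.

    With ``cover_amino_acids`` the vocabulary contains every identifier the
    20 amino-acid SMILES and the ligand alphabet produce (``vocab_size``
    then acts as a minimum, padded with filler words).  Without it, exactly
    ``vocab_size`` filler words ``"0"…"n-1"`` are generated.  Deterministic
    under ``seed``.
    """
    if cover_amino_acids:
        words = required_vocabulary(ligand_smiles)
        filler = 0
        while len(words) < vocab_size:
            words.append(f"filler{filler}")
            filler += 1
    else:
        if vocab_size < 1:
            raise ValueError("vocab_size must be >= 1 without amino-acid coverage")
        words = [str(i) for i in range(vocab_size)]
    rng = np.random.default_rng(seed)
    vectors = {w: rng.standard_normal(dim) for w in words}
    return EmbeddingTable(vectors)


# ------------------------------------------------------------- toy complex

@dataclass
class ToyComplexSpec:
    """Recipe for one synthetic complex and its decoy pockets."""

    decoy_distances_nm: Sequence[float]
    n_pocket_residues: int = 8
    ligand_smiles: str = "CCO"
    duplicate_decoy_distance_nm: float | None = None
    native_like_decoy: bool = False  # add a decoy at the known centroid
    seed: int = 0
    complex_id: str = "toy"

    def __post_init__(self) -> None:
        if not self.decoy_distances_nm:
            raise ValueError("decoy_distances_nm must be non-empty")
        if self.n_pocket_residues < 2:
            raise ValueError("need at least 2 pocket residues")


@dataclass
class ToyComplex:
    """Generated artifact paths plus the intended-label manifest."""

    complex_id: str
    protein_path: str
    ligand: LigandRecord
    pocket_dir: str
    manifest: list[dict]
    known_residue_names: list[str]
    seed: int


def _pdb_line(record: str, serial: int, name: str, resname: str, chain: str,
              resseq: int, xyz: np.ndarray, element: str) -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:>5d} {name_field:<4s} {resname:>3s} {chain:1s}"
        f"{resseq:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"  1.00  0.00          {element:>2s}"
    )


def _ring(center: np.ndarray, normal: np.ndarray, radius: float, n: int) -> np.ndarray:
    """n points evenly spaced on a circle; their centroid is exactly center."""
    normal = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = helper - (helper @ normal) * normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    angles = 2 * np.pi * np.arange(n) / n
    return center + radius * (np.outer(np.cos(angles), e1) + np.outer(np.sin(angles), e2))


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _intended_label(d: float, near_max: float = 0.3, neg_min: float = 1.0) -> str:
    if d < near_max:
        return "positive"
    if d > neg_min:
        return "negative_candidate"
    return "excluded"


def make_toy_complex(spec: ToyComplexSpec, out_dir: str | os.PathLike) -> ToyComplex:
    """Write a synthetic complex: protein PDB, ligand, fpocket-style decoys.

    The known pocket is a ring of ``n_pocket_residues`` Cα atoms 5 Å around
    the ligand (well inside the 1 nm shell); decoy ``k`` is a ring whose
    centroid sits exactly ``decoy_distances_nm[k]`` from the known
    centroid.  The manifest records each decoy's requested distance,
    composition source and intended label under the default thresholds.
    """
    rng = np.random.default_rng(spec.seed)
    out_dir = os.fspath(out_dir)
    pocket_dir = os.path.join(out_dir, "pockets")
    os.makedirs(pocket_dir, exist_ok=True)

    # ligand: a short carbon chain near the origin
    lig_xyz = np.array([[0.0, 0.0, 0.0], [1.4, 0.0, 0.0], [2.8, 0.0, 0.0]])
    lig_center = lig_xyz.mean(axis=0)
    ligand_atoms = [
        Atom(name=f"C{i+1}", element="C", residue_name="LIG",
             residue_id=("L", 1, " "), xyz=xyz, hetero=True)
        for i, xyz in enumerate(lig_xyz)
    ]
    ligand = LigandRecord(
        id=f"{spec.complex_id}_ligand", smiles=spec.ligand_smiles,
        atoms=ligand_atoms, source_format="PDB",
    )

    n = spec.n_pocket_residues
    known_names = [POSITIVE_ALPHABET[i] for i in rng.integers(0, len(POSITIVE_ALPHABET), n)]
    known_xyz = _ring(lig_center, np.array([0.0, 0.0, 1.0]), 5.0, n)

    lines = []
    serial = 1
    for xyz in lig_xyz:
        lines.append(_pdb_line("HETATM", serial, f"C{serial}", "LIG", "L", 1, xyz, "C"))
        serial += 1
    for i, (name, xyz) in enumerate(zip(known_names, known_xyz), start=1):
        lines.append(_pdb_line("ATOM", serial, "CA", name, "A", i, xyz, "C"))
        serial += 1
    protein_path = os.path.join(out_dir, f"{spec.complex_id}.pdb")
    with open(protein_path, "w") as fh:
        fh.write("\n".join(lines) + "\nEND\n")

    # decoys ------------------------------------------------------------
    requests: list[tuple[float, str]] = [(d, "far") for d in spec.decoy_distances_nm]
    # near-native decoys reuse the known composition (one substitution)
    requests = [
        (d, "near" if d < 0.3 else "far") for d, _ in requests
    ]
    if spec.native_like_decoy:
        requests.insert(0, (0.0, "native_like"))
    if spec.duplicate_decoy_distance_nm is not None:
        requests.append((spec.duplicate_decoy_distance_nm, "duplicate"))

    manifest: list[dict] = []
    for k, (d_nm, kind) in enumerate(requests, start=1):
        if kind in ("near", "native_like"):
            names = list(known_names)
            if kind == "near":
                pos = int(rng.integers(0, n))
                names[pos] = POSITIVE_ALPHABET[int(rng.integers(0, len(POSITIVE_ALPHABET)))]
        elif kind == "duplicate":
            names = list(known_names)
        else:
            names = [NEGATIVE_ALPHABET[i] for i in rng.integers(0, len(NEGATIVE_ALPHABET), n)]

        center = lig_center + (d_nm * 10.0) * _random_unit(rng)
        ring = _ring(center, _random_unit(rng), 4.0, n)
        plines = [
            _pdb_line("ATOM", j + 1, "CA", name, "P", 100 * k + j, xyz, "C")
            for j, (name, xyz) in enumerate(zip(names, ring), start=1)
        ]
        fname = os.path.join(pocket_dir, f"pocket{k}_atm.pdb")
        with open(fname, "w") as fh:
            fh.write("\n".join(plines) + "\nEND\n")
        manifest.append(
            {
                "pocket_id": str(k),
                "requested_distance_nm": float(d_nm),
                "kind": kind,
                "intended_label": _intended_label(d_nm),
                "residue_names": names,
            }
        )

    return ToyComplex(
        complex_id=spec.complex_id,
        protein_path=protein_path,
        ligand=ligand,
        pocket_dir=pocket_dir,
        manifest=manifest,
        known_residue_names=known_names,
        seed=spec.seed,
    )


# -------------------------------------------------------- separable vectors

def make_separable_vectors(
    n_pos: int,
    n_neg: int,
    class_separation: float,
    dim: int = 600,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two spherical Gaussian classes with mean distance ``class_separation``.

    Positives ~ N(+s/2·u, I), negatives ~ N(−s/2·u, I) for a random unit
    direction u, so the Bayes-optimal AUC has the closed form
    Φ(class_separation / √2).  Rows are shuffled; deterministic under seed.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(dim)
    u /= np.linalg.norm(u)
    offset = (class_separation / 2.0) * u
    X = np.vstack(
        [
            rng.standard_normal((n_pos, dim)) + offset,
            rng.standard_normal((n_neg, dim)) - offset,
        ]
    )
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    order = rng.permutation(n_pos + n_neg)
    return X[order], y[order]


def expected_bayes_auc(class_separation: float) -> float:
    """Closed-form AUC of the optimal linear discriminant: Φ(s/√2)."""
    return 0.5 * (1.0 + math.erf(class_separation / 2.0))
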