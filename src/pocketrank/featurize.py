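"""Substructure-embedding featurization of ligands and pockets.

A molecule is treated as a *sentence* of Morgan (circular) substructure
identifiers — one word per heavy atom per radius (radii 0 and 1 by
default) — and embedded as the element-wise sum of per-word vectors looked
up in a 300-dimensional embedding table (the word2vec-over-substructures
convention).  A pocket is embedded as the sum of its residues' vectors,
each residue mapped to the canonical SMILES of the free amino acid.  The
classifier consumes the 600-d concatenation of ligand vector (indices
0–299) and pocket vector (indices 300–599).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .structures import LigandRecord, Pocket

logger = logging.getLogger(__name__)

DEFAULT_DIM = 300
DEFAULT_RADII = (0, 1)

#: canonical SMILES of the 20 standard free amino acids, used to featurize
#: pocket residues by name.
AMINO_ACID_SMILES: dict[str, str] = {
    "ALA": "CC(N)C(=O)O",
    "ARG": "NC(CCCNC(N)=N)C(=O)O",
    "ASN": "NC(CC(N)=O)C(=O)O",
    "ASP": "NC(CC(O)=O)C(=O)O",
    "CYS": "NC(CS)C(=O)O",
    "GLN": "NC(CCC(N)=O)C(=O)O",
    "GLU": "NC(CCC(O)=O)C(=O)O",
    "GLY": "NCC(=O)O",
    "HIS": "NC(Cc1c[nH]cn1)C(=O)O",
    "ILE": "CCC(C)C(N)C(=O)O",
    "LEU": "CC(C)CC(N)C(=O)O",
    "LYS": "NCCCCC(N)C(=O)O",
    "MET": "CSCCC(N)C(=O)O",
    "PHE": "NC(Cc1ccccc1)C(=O)O",
    "PRO": "OC(=O)C1CCCN1",
    "SER": "NC(CO)C(=O)O",
    "THR": "CC(O)C(N)C(=O)O",
    "TRP": "NC(Cc1c[nH]c2ccccc12)C(=O)O",
    "TYR": "NC(Cc1ccc(O)cc1)C(=O)O",
    "VAL": "CC(C)C(N)C(=O)O",
}


class FeaturizationError(ValueError):
    """Raised when a molecule or pocket cannot be featurized."""


@dataclass
class MolecularSentence:
    """Ordered substructure identifiers: atom index ascending, then radius."""

    words: list[str]

    def __len__(self) -> int:
        return len(self.words)


class EmbeddingTable:
    """Map from substructure identifier to a fixed-dimension vector.

    Parameters
    ----------
    vectors
        Mapping identifier → vector; all vectors must share one length.
    unk_policy
        How out-of-vocabulary words contribute to a sentence sum:
        ``"zero"`` (nothing) or ``"unk_vector"`` (the vector stored under
        the ``UNK`` identifier).
    """

    UNK_WORD = "UNK"

    def __init__(self, vectors: dict[str, np.ndarray], unk_policy: str = "zero"):
        if not vectors:
            raise ValueError("embedding table must not be empty")
        if unk_policy not in ("zero", "unk_vector"):
            raise ValueError(f"unknown unk_policy {unk_policy!r}")
        self.vectors = {w: np.asarray(v, dtype=float) for w, v in vectors.items()}
        dims = {v.shape for v in self.vectors.values()}
        if len(dims) != 1 or len(next(iter(dims))) != 1:
            raise ValueError("all embedding vectors must be 1-d of equal length")
        self.dim = next(iter(dims))[0]
        if self.dim <= 0:
            raise ValueError("embedding dimension must be positive")
        self.unk_policy = unk_policy

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def lookup(self, word: str) -> np.ndarray:
        """Vector for ``word``; OOV handled per ``unk_policy``."""
        vec = self.vectors.get(word)
        if vec is not None:
            return vec
        if self.unk_policy == "unk_vector" and self.UNK_WORD in self.vectors:
            return self.vectors[self.UNK_WORD]
        return np.zeros(self.dim)

    @classmethod
    def load(cls, path: str | os.PathLike, unk_policy: str = "zero") -> "EmbeddingTable":
        """Read word2vec text format: header ``<vocab> <dim>``, then one
        ``<identifier> <f1> ... <fdim>`` line per word."""
        path = os.fspath(path)
        vectors: dict[str, np.ndarray] = {}
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError(f"{path}: malformed word2vec header {header!r}")
            vocab, dim = int(header[0]), int(header[1])
            for lineno, line in enumerate(fh, start=2):
                parts = line.split()
                if not parts:
                    continue
                word, values = parts[0], parts[1:]
                if len(values) != dim:
                    raise ValueError(
                        f"{path} line {lineno}: expected {dim} floats, got {len(values)}"
                    )
                vectors[word] = np.array(values, dtype=float)
        if len(vectors) != vocab:
            raise ValueError(
                f"{path}: header promises {vocab} words, found {len(vectors)}"
            )
        return cls(vectors, unk_policy=unk_policy)

    def save(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            fh.write(f"{len(self.vectors)} {self.dim}\n")
            for word, vec in self.vectors.items():
                fh.write(word + " " + " ".join(f"{x:.6f}" for x in vec) + "\n")


def _mol_from_record(molecule) -> "Chem.Mol":
    from rdkit import Chem

    if isinstance(molecule, str):
        mol = Chem.MolFromSmiles(molecule)
        mol_id = molecule
    elif isinstance(molecule, LigandRecord):
        if molecule.smiles is None:
            raise FeaturizationError(f"ligand {molecule.id}: no SMILES available")
        mol = Chem.MolFromSmiles(molecule.smiles)
        mol_id = molecule.id
    else:
        mol = molecule
        mol_id = "molecule"
    if mol is None:
        raise FeaturizationError(f"cannot parse molecule {mol_id!r}")
    return mol


def mol_to_sentence(molecule, radii: Sequence[int] = DEFAULT_RADII) -> MolecularSentence:
    """Morgan-substructure sentence of a molecule.

    For each heavy atom and each radius in ``radii`` (ascending) the circular
    environment identifier is emitted; atoms lacking an environment at a
    radius (e.g. an isolated atom at radius 1) contribute no word there.
    Deterministic for a fixed input.
    """
    from rdkit.Chem import rdFingerprintGenerator

    mol = _mol_from_record(molecule)
    radii = sorted(set(int(r) for r in radii))
    if not radii or radii[0] < 0:
        raise ValueError("radii must be non-negative integers")

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=max(radii))
    out = rdFingerprintGenerator.AdditionalOutput()
    out.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(mol, additionalOutput=out)

    per_atom: dict[int, dict[int, int]] = {}
    for identifier, envs in out.GetBitInfoMap().items():
        for atom_idx, radius in envs:
            per_atom.setdefault(atom_idx, {})[radius] = identifier

    words = [
        str(per_atom[atom_idx][r])
        for atom_idx in range(mol.GetNumAtoms())
        for r in radii
        if r in per_atom.get(atom_idx, {})
    ]
    return MolecularSentence(words=words)


def embed_sentence(sentence: MolecularSentence, table: EmbeddingTable) -> np.ndarray:
    """Element-wise sum of the word vectors of a sentence."""
    if not sentence.words:
        raise FeaturizationError("cannot embed an empty sentence")
    total = np.zeros(table.dim)
    for word in sentence.words:
        total += table.lookup(word)
    return total


def ligand_vector(
    ligand: LigandRecord | str,
    table: EmbeddingTable,
    radii: Sequence[int] = DEFAULT_RADII,
) -> np.ndarray:
    return embed_sentence(mol_to_sentence(ligand, radii=radii), table)


def residue_to_vector(
    residue_name: str,
    table: EmbeddingTable,
    strict: bool = False,
    extra_residues: dict[str, str] | None = None,
) -> np.ndarray:
    """Embedding of a residue via the canonical free amino-acid SMILES.

    Unknown residue names yield a zero vector with a warning (or raise in
    strict mode).  Results are cached per table instance.
    """
    cache = getattr(table, "_residue_cache", None)
    if cache is None:
        cache = table._residue_cache = {}
    key = residue_name.upper()
    if key in cache:
        return cache[key]
    smiles_map = dict(AMINO_ACID_SMILES)
    if extra_residues:
        smiles_map.update({k.upper(): v for k, v in extra_residues.items()})
    smiles = smiles_map.get(key)
    if smiles is None:
        if strict:
            raise FeaturizationError(f"unknown residue name {residue_name!r}")
        logger.warning("unknown residue %r: contributing zero vector", residue_name)
        vec = np.zeros(table.dim)
    else:
        vec = embed_sentence(mol_to_sentence(smiles), table)
    cache[key] = vec
    return vec


def pocket_vector(
    pocket: Pocket,
    table: EmbeddingTable,
    strict: bool = False,
    extra_residues: dict[str, str] | None = None,
) -> np.ndarray:
    """Sum of the pocket residues' embedding vectors."""
    if not pocket.residues:
        raise FeaturizationError(f"pocket {pocket.id}: no residues")
    total = np.zeros(table.dim)
    n_known = 0
    for name in pocket.residue_names:
        vec = residue_to_vector(name, table, strict=strict, extra_residues=extra_residues)
        if np.any(vec):
            n_known += 1
        total += vec
    if strict and n_known == 0:
        raise FeaturizationError(f"pocket {pocket.id}: no featurizable residues")
    return total


@dataclass
class PairVector:
    """The classifier input: ligand vector then pocket vector, concatenated."""

    values: np.ndarray
    meta: tuple[str, str] = ("", "")  # (complex id, pocket id)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size % 2 != 0:
            raise ValueError("pair vector must be 1-d with even length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pair vector entries must be finite")

    @property
    def dim(self) -> int:
        return self.values.size // 2

    @property
    def ligand_part(self) -> np.ndarray:
        return self.values[: self.dim]

    @property
    def pocket_part(self) -> np.ndarray:
        return self.values[self.dim :]


def pair_vector(
    ligand_vec: np.ndarray,
    pocket_vec: np.ndarray,
    meta: tuple[str, str] = ("", ""),
) -> PairVector:
    """Concatenate ligand and pocket vectors into the classifier input."""
    ligand_vec = np.asarray(ligand_vec, dtype=float)
    pocket_vec = np.asarray(pocket_vec, dtype=float)
    if ligand_vec.shape != pocket_vec.shape or ligand_vec.ndim != 1:
        raise ValueError(
            f"ligand/pocket vector length mismatch: "
            f"{ligand_vec.shape} vs {pocket_vec.shape}"
        )
    return PairVector(values=np.concatenate([ligand_vec, pocket_vec]), meta=meta)


class PairFeaturizer:
    """Transformer turning (ligand, pocket) pairs into pair-vector rows.

    A thin scikit-learn-style wrapper over :func:`ligand_vector`,
    :func:`pocket_vector` and :func:`pair_vector`; ``transform`` accepts an
    iterable of ``(LigandRecord, Pocket)`` and returns an ``(n, 2*dim)``
    array.
    """

    def __init__(self, table: EmbeddingTable, radii: Sequence[int] = DEFAULT_RADII,
                 strict: bool = False):
        self.table = table
        self.radii = tuple(radii)
        self.strict = strict

    def get_params(self, deep: bool = True) -> dict:
        return {"table": self.table, "radii": self.radii, "strict": self.strict}

    def set_params(self, **params) -> "PairFeaturizer":
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, X=None, y=None) -> "PairFeaturizer":
        return self

    def transform(self, pairs: Iterable[tuple[LigandRecord, Pocket]]) -> np.ndarray:
        rows = []
        lig_cache: dict[str, np.ndarray] = {}
        for ligand, pocket in pairs:
            key = ligand.smiles or ligand.id
            if key not in lig_cache:
                lig_cache[key] = ligand_vector(ligand, self.table, radii=self.radii)
            rows.append(
                pair_vector(
                    lig_cache[key],
                    pocket_vector(pocket, self.table, strict=self.strict),
                    meta=(ligand.id, pocket.id),
                ).values
            )
        return np.array(rows)
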