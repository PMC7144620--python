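"""Decoy labeling, negative sampling, similarity filtering and normalization.

The labeled training data for the pocket classifier is built per complex:

* the *known pocket* is the residue shell within 1 nm of the ligand;
* decoys whose Cα-centroid distance to the known pocket is below 0.3 nm are
  positives (the "near-native" strategy) — alternatively the known pocket
  itself is the positive ("native" strategy);
* decoys farther than 1 nm are negative candidates, of which three are
  drawn at random; candidates whose pocket vector has cosine similarity
  ≥ 0.995 with the known pocket's vector are removed first;
* decoys in the 0.3–1 nm band are excluded as ambiguous.

Feature matrices are normalized by a single scalar affine map
``(t - mean) / std`` — either with constants fixed from a training set or
with the matrix's own global moments.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .featurize import EmbeddingTable, PairVector, ligand_vector, pair_vector, pocket_vector
from .structures import LigandRecord, Pocket, Structure, center_distance, known_pocket

logger = logging.getLogger(__name__)

#: normalization constants published for the two positive-set strategies
#: (single scalar mean/std over all 600 components of the training matrix).
FIXED_NORMALIZATION = {
    "near_native": {"mean": -0.5696, "std": 30.8744},
    "native": {"mean": -0.9610, "std": 63.6607},
}


@dataclass(frozen=True)
class LabelingThresholds:
    """Geometric and similarity thresholds of the labeling protocol (nm)."""

    pocket_radius: float = 1.0
    near_native_max: float = 0.3
    negative_min: float = 1.0
    negatives_per_protein: int = 3
    similarity_cutoff: float = 0.995
    far_rationale_distance: float = 3.0  # informational only

    def __post_init__(self) -> None:
        if not (0 < self.near_native_max < self.negative_min):
            raise ValueError("need 0 < near_native_max < negative_min")
        if not (0 < self.similarity_cutoff <= 1):
            raise ValueError("similarity_cutoff must be in (0, 1]")


def cosine_similarity(v_i: np.ndarray, v_j: np.ndarray) -> float:
    """S_ij = (V_i · V_j) / (|V_i| |V_j|), in [-1, 1]."""
    v_i = np.asarray(v_i, dtype=float)
    v_j = np.asarray(v_j, dtype=float)
    if v_i.shape != v_j.shape:
        raise ValueError("vectors must have the same length")
    norm_i = np.linalg.norm(v_i)
    norm_j = np.linalg.norm(v_j)
    if norm_i == 0 or norm_j == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    if np.array_equal(v_i, v_j):
        return 1.0  # exact duplicates sit on the boundary; keep them there
    return float(np.clip(v_i @ v_j / (norm_i * norm_j), -1.0, 1.0))


@dataclass
class DecoyPartition:
    """Exhaustive, disjoint partition of decoys by centroid distance."""

    positives: list[tuple[Pocket, float]]
    negative_candidates: list[tuple[Pocket, float]]
    excluded_band: list[tuple[Pocket, float]]

    def __len__(self) -> int:
        return len(self.positives) + len(self.negative_candidates) + len(self.excluded_band)


def label_decoys(
    known: Pocket,
    decoys: Sequence[Pocket],
    thr: LabelingThresholds = LabelingThresholds(),
) -> DecoyPartition:
    """Partition decoys: d < 0.3 nm positive, d > 1 nm negative candidate,
    the band in between excluded."""
    if not decoys:
        raise ValueError("no decoys to label")
    part = DecoyPartition([], [], [])
    for decoy in decoys:
        d = center_distance(known, decoy)
        if d < thr.near_native_max:
            part.positives.append((decoy, d))
        elif d > thr.negative_min:
            part.negative_candidates.append((decoy, d))
        else:
            part.excluded_band.append((decoy, d))
    return part


def select_negatives(
    candidates: Sequence,
    k: int = 3,
    seed: int | np.random.Generator | None = None,
) -> list:
    """Uniform sample of min(k, n) candidates without replacement.

    When fewer than ``k`` candidates exist, all are kept.  Deterministic
    under a fixed seed; original order is preserved in the output.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    candidates = list(candidates)
    if len(candidates) <= k:
        return candidates
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = sorted(rng.choice(len(candidates), size=k, replace=False))
    return [candidates[i] for i in idx]


def similarity_filter(
    negatives: Sequence[tuple[Pocket, np.ndarray]],
    known_vec: np.ndarray,
    cutoff: float = 0.995,
) -> list[tuple[Pocket, np.ndarray]]:
    """Drop negatives whose pocket vector is highly similar to the known
    pocket's (cosine similarity ≥ cutoff); zero-norm vectors are retained
    as trivially dissimilar, with a warning."""
    kept = []
    for pocket, vec in negatives:
        try:
            s = cosine_similarity(vec, known_vec)
        except ValueError:
            logger.warning(
                "pocket %s: zero-norm vector, treated as dissimilar", pocket.id
            )
            kept.append((pocket, vec))
            continue
        if s < cutoff:
            kept.append((pocket, vec))
    return kept


class PairVectorScaler(TransformerMixin, BaseEstimator):
    """Scalar standardization ``(t - mean) / std`` over all matrix entries.

    mode="fixed" applies the supplied constants (e.g. the published
    training-set moments); mode="self" estimates a single global mean and
    std from the fitted matrix.  Unlike a per-feature standard scaler, one
    affine map is shared by every component.
    """

    def __init__(self, mode: str = "fixed", mean: float | None = None,
                 std: float | None = None):
        self.mode = mode
        self.mean = mean
        self.std = std

    def fit(self, X, y=None) -> "PairVectorScaler":
        X = np.asarray(X, dtype=float)
        if self.mode == "fixed":
            if self.mean is None or self.std is None:
                raise ValueError("fixed mode requires mean and std")
            if self.std <= 0:
                raise ValueError("std must be positive")
            self.mean_, self.std_ = float(self.mean), float(self.std)
        elif self.mode == "self":
            if X.size <= 1:
                raise ValueError("self mode needs more than one value")
            self.mean_ = float(X.mean())
            self.std_ = float(X.std())
            if self.std_ == 0:
                raise ValueError("zero standard deviation; cannot normalize")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else None
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "mean_")
        return (np.asarray(X, dtype=float) - self.mean_) / self.std_

    def inverse_transform(self, X) -> np.ndarray:
        check_is_fitted(self, "mean_")
        return np.asarray(X, dtype=float) * self.std_ + self.mean_


def normalize(
    matrix: np.ndarray,
    mode: str = "self",
    mean: float | None = None,
    std: float | None = None,
) -> np.ndarray:
    """Functional wrapper over :class:`PairVectorScaler`."""
    scaler = PairVectorScaler(mode=mode, mean=mean, std=std)
    return scaler.fit(matrix).transform(matrix)


@dataclass
class LabeledExample:
    """One classifier training example with its provenance."""

    pair: PairVector
    label: int
    positive_strategy: str  # "near_native" | "native"
    complex_id: str
    pocket_id: str
    center_distance_nm: float
    similarity_to_known: float | None = None


@dataclass
class ComplexInput:
    """One protein–ligand complex plus its candidate-pocket decoys."""

    id: str
    structure: Structure
    ligand: LigandRecord
    decoys: list[Pocket]


def build_dataset(
    complexes: Iterable[ComplexInput],
    table: EmbeddingTable,
    thr: LabelingThresholds = LabelingThresholds(),
    strategy: str = "near_native",
    seed: int | None = 0,
) -> list[LabeledExample]:
    """Assemble labeled pair vectors from a collection of complexes.

    Per complex: positives per ``strategy`` (near-native decoys, or the
    known pocket itself), negatives via distance labeling → random draw of
    ``thr.negatives_per_protein`` → similarity filter against the known
    pocket's vector.  Complexes that fail are logged and skipped; an error
    is raised only when no examples at all are produced.
    """
    if strategy not in ("near_native", "native"):
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    examples: list[LabeledExample] = []
    for cx in complexes:
        try:
            examples.extend(
                _build_one(cx, table, thr, strategy, rng)
            )
        except Exception as exc:
            logger.warning("complex %s failed, skipping: %s", cx.id, exc)
    if not examples:
        raise RuntimeError("dataset construction produced no examples")
    return examples


def _build_one(cx, table, thr, strategy, rng) -> list[LabeledExample]:
    known = known_pocket(cx.structure, cx.ligand, radius_nm=thr.pocket_radius)
    known_vec = pocket_vector(known, table)
    lig_vec = ligand_vector(cx.ligand, table)
    part = label_decoys(known, cx.decoys, thr)

    out: list[LabeledExample] = []
    if strategy == "near_native":
        positives = part.positives
        if not positives:
            logger.warning("complex %s: no near-native decoy, no positive emitted", cx.id)
        for pocket, d in positives:
            out.append(
                LabeledExample(
                    pair=pair_vector(lig_vec, pocket_vector(pocket, table), meta=(cx.id, pocket.id)),
                    label=1,
                    positive_strategy=strategy,
                    complex_id=cx.id,
                    pocket_id=pocket.id,
                    center_distance_nm=d,
                )
            )
    else:
        out.append(
            LabeledExample(
                pair=pair_vector(lig_vec, known_vec, meta=(cx.id, known.id)),
                label=1,
                positive_strategy=strategy,
                complex_id=cx.id,
                pocket_id=known.id,
                center_distance_nm=0.0,
            )
        )

    with_vecs = [
        (pocket, pocket_vector(pocket, table)) for pocket, _ in part.negative_candidates
    ]
    dist_by_id = {p.id: d for p, d in part.negative_candidates}
    filtered = similarity_filter(with_vecs, known_vec, cutoff=thr.similarity_cutoff)
    chosen = select_negatives(filtered, k=thr.negatives_per_protein, seed=rng)
    for pocket, vec in chosen:
        out.append(
            LabeledExample(
                pair=pair_vector(lig_vec, vec, meta=(cx.id, pocket.id)),
                label=0,
                positive_strategy=strategy,
                complex_id=cx.id,
                pocket_id=pocket.id,
                center_distance_nm=dist_by_id[pocket.id],
                similarity_to_known=cosine_similarity(vec, known_vec) if np.any(vec) else None,
            )
        )
    return out


def examples_to_arrays(
    examples: Sequence[LabeledExample],
    replicate_positives: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack examples into (X, y); positives may be replicated to balance
    classes (the training sets pair each positive ×3 against 3 negatives
    per complex)."""
    if replicate_positives < 1:
        raise ValueError("replicate_positives must be >= 1")
    rows, labels = [], []
    for ex in examples:
        reps = replicate_positives if ex.label == 1 else 1
        for _ in range(reps):
            rows.append(ex.pair.values)
            labels.append(ex.label)
    return np.array(rows), np.array(labels)


def write_manifest(examples: Sequence[LabeledExample], path: str | os.PathLike) -> None:
    """Tab-separated dataset manifest (one row per example)."""
    frame = pd.DataFrame(
        {
            "complex_id": [e.complex_id for e in examples],
            "pocket_id": [e.pocket_id for e in examples],
            "label": [e.label for e in examples],
            "strategy": [e.positive_strategy for e in examples],
            "center_distance_nm": [e.center_distance_nm for e in examples],
            "similarity_to_known": [e.similarity_to_known for e in examples],
        }
    )
    frame.to_csv(os.fspath(path), sep="\t", index=False)
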