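"""Scoring and ranking of candidate pockets for a given ligand."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datasets import PairVectorScaler
from .featurize import EmbeddingTable, FeaturizationError, ligand_vector, pair_vector, pocket_vector
from .model import DenseFeedForwardClassifier
from .structures import LigandRecord, Pocket, center_distance

logger = logging.getLogger(__name__)


@dataclass
class RankedPocket:
    pocket_id: str
    score: float  # native-like probability; NaN when featurization failed
    rank: int | None  # 1-based; None for failed pockets
    center_distance_nm: float | None = None


def rank_pockets(
    model: DenseFeedForwardClassifier,
    ligand: LigandRecord,
    pockets: Sequence[Pocket],
    table: EmbeddingTable,
    scaler: PairVectorScaler | None = None,
    reference: Pocket | None = None,
) -> list[RankedPocket]:
    """Score each pocket's native-like probability and rank descending.

    Each pocket is featurized as the 600-d ligand/pocket pair vector,
    normalized by ``scaler`` (typically the fixed training-set constants
    stored with the model checkpoint), and scored in inference mode.  Ties
    break by pocket id ascending.  Pockets that fail featurization are
    appended with a NaN score and no rank rather than silently dropped;
    if every pocket fails, an error is raised.
    """
    if not pockets:
        raise ValueError("no pockets to rank")
    lig_vec = ligand_vector(ligand, table)

    rows, scored, failed = [], [], []
    for pocket in pockets:
        try:
            rows.append(pair_vector(lig_vec, pocket_vector(pocket, table)).values)
            scored.append(pocket)
        except (FeaturizationError, ValueError) as exc:
            logger.warning("pocket %s failed featurization: %s", pocket.id, exc)
            failed.append(pocket)
    if not scored:
        raise RuntimeError("all pockets failed featurization")

    X = np.array(rows)
    if scaler is not None:
        X = scaler.transform(X)
    probs = model.decision_function(X)

    order = sorted(range(len(scored)), key=lambda i: (-probs[i], scored[i].id))
    ranked = [
        RankedPocket(
            pocket_id=scored[i].id,
            score=float(probs[i]),
            rank=rank,
            center_distance_nm=(
                center_distance(scored[i], reference) if reference is not None else None
            ),
        )
        for rank, i in enumerate(order, start=1)
    ]
    ranked.extend(
        RankedPocket(pocket_id=p.id, score=math.nan, rank=None) for p in failed
    )
    return ranked


def top_k(ranked: Sequence[RankedPocket], k: int = 3) -> list[RankedPocket]:
    """The first min(k, n) ranked (scored) pockets."""
    if k < 1:
        raise ValueError("k must be >= 1")
    scored = [r for r in ranked if r.rank is not None]
    return list(scored[: min(k, len(scored))])


def scaler_from_checkpoint(model: DenseFeedForwardClassifier) -> PairVectorScaler | None:
    """Rebuild the fixed normalization stored in a loaded checkpoint."""
    norm = getattr(model, "normalization_", None)
    if not norm:
        return None
    scaler = PairVectorScaler(mode="fixed", mean=norm["mean"], std=norm["std"])
    return scaler.fit(np.zeros((1, model.n_features_in_)))
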