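"""Feature importance scores, ranking and top-k subsets from a fitted W."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SelectionResult:
    """Per-feature importance scores and the induced descending ranking."""

    scores: np.ndarray
    ranking: np.ndarray
    metadata: dict = field(default_factory=dict)

    def top(self, k: int) -> np.ndarray:
        return top_k(self.ranking, k)


def feature_scores(W: np.ndarray) -> np.ndarray:
    """Importance of feature i: the row sum of W (its l1 row norm for W >= 0)."""
    W = np.asarray(W, dtype=float)
    if (W < 0).any():
        raise ValueError("weight matrix must be non-negative")
    return W.sum(axis=1)


def rank_features(scores: np.ndarray) -> np.ndarray:
    """Indices sorted by descending score; ties break by ascending index."""
    scores = np.asarray(scores, dtype=float)
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN")
    # stable sort on -scores: equal scores keep ascending index order
    return np.argsort(-scores, kind="stable")


def top_k(ranking: np.ndarray, k: int) -> np.ndarray:
    """First k entries of the ranking (prefixes are nested by construction)."""
    d = len(ranking)
    if not 1 <= k <= d:
        raise ValueError(f"k must be in 1..{d}, got {k}")
    return np.asarray(ranking[:k])


def select(W: np.ndarray, metadata: dict | None = None) -> SelectionResult:
    scores = feature_scores(W)
    return SelectionResult(
        scores=scores, ranking=rank_features(scores), metadata=metadata or {}
    )
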