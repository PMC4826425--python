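"""Extracting a one-to-one node mapping from a converged score vector.

The solver returns a simplex vector over node pairs; reshaped to an
N_a x N_b matrix X it scores every query-target correspondence.  Greedy
maximum-score matching (repeatedly take the best remaining pair and
strike its row and column) follows the practice established for
IsoRank-style scores; an argmax-per-row mode is available for
diagnostics but may be many-to-one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["AlignmentResult", "score_matrix", "greedy_match", "argmax_match", "accuracy"]


@dataclass
class AlignmentResult:
    """Node correspondence with per-pair scores, sorted by query index."""

    pairs: list[tuple[int, int, float]]
    method: str = "greedy"
    accuracy: Optional[float] = None

    def mapping(self) -> dict[int, int]:
        return {u: v for u, v, _ in self.pairs}


def score_matrix(x: np.ndarray, n_a: int, n_b: int) -> np.ndarray:
    """Reshape the pair-score vector into its N_a x N_b matrix.

    Inverse of the query-major pair order: X[u, v] = x[u * N_b + v].
    """
    x = np.asarray(x)
    if x.shape != (n_a * n_b,):
        raise ValueError(f"expected vector of length {n_a * n_b}, got shape {x.shape}")
    return x.reshape(n_a, n_b)


def greedy_match(X: np.ndarray) -> AlignmentResult:
    """One-to-one matching by repeated maximum selection.

    Ties break toward the smallest query index, then the smallest target
    index; rows and columns of selected pairs are eliminated.  Stops
    after min(N_a, N_b) pairs or when only zero scores remain.
    """
    X = np.asarray(X, dtype=np.float64)
    if np.any(X < 0):
        raise ValueError("score matrix must be non-negative")
    n_a, n_b = X.shape
    work = X.copy()
    pairs: list[tuple[int, int, float]] = []
    for _ in range(min(n_a, n_b)):
        t = int(np.argmax(work))  # first maximum in row-major order = tie rule
        u, v = divmod(t, n_b)
        if work[u, v] <= 0.0:
            break
        pairs.append((u, v, float(X[u, v])))
        work[u, :] = -1.0
        work[:, v] = -1.0
    if not pairs:
        logger.warning("all scores are zero; empty alignment")
    pairs.sort()
    return AlignmentResult(pairs=pairs, method="greedy")


def argmax_match(X: np.ndarray) -> AlignmentResult:
    """Best target per query row; may map several queries to one target."""
    X = np.asarray(X, dtype=np.float64)
    pairs = [(u, int(np.argmax(X[u])), float(X[u].max())) for u in range(X.shape[0])]
    return AlignmentResult(pairs=pairs, method="argmax")


def accuracy(result: AlignmentResult, truth: Mapping[int, int], n_query: Optional[int] = None) -> float:
    """Fraction of query nodes aligned to their true target.

    Correct pairs are counted against the total number of query nodes,
    so unmatched queries count as errors.
    """
    if n_query is None:
        n_query = len(truth)
    if n_query == 0:
        return 0.0
    correct = sum(1 for u, v, _ in result.pairs if truth.get(u) == v)
    return correct / n_query
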