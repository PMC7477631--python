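"""Neighbor recommender scoring of drug pairs.

For a candidate pair (i, j), the directed component is the similarity-weighted
mean of j's known combination labels over neighbor drugs k:

    y_ij = sum_k S_ik * a_kj / sum_k S_ik          (k != j)

and the pair score is y_ij + y_ji, symmetrized by construction. By default
k = i is excluded as well, so the queried pair's own adjacency entry never
contributes to its own score (required for honest cross-validation); set
``exclude_self=False`` for the strict textbook sum that only drops k = j.

A zero denominator (no admissible neighbor with positive similarity) yields
score 0 with a degenerate flag instead of an error, so isolated drugs rank
last rather than crash a scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data_model import CombinationNetwork, SimilarityMatrix, canonical_pair


@dataclass(frozen=True)
class PairScore:
    y_ij: float
    y_ji: float
    degenerate: bool

    @property
    def score(self) -> float:
        return self.y_ij + self.y_ji

    @property
    def probability(self) -> float:
        return self.score / 2.0


class NRMScores:
    """Scored candidate pairs; lookup is unordered: (i,j) and (j,i) agree."""

    def __init__(self, records: dict[tuple[str, str], PairScore]):
        self._records = records

    def __getitem__(self, pair: tuple[str, str]) -> PairScore:
        return self._records[canonical_pair(*pair)]

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.items())

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple(self._records)

    def probabilities(self) -> np.ndarray:
        return np.array([r.probability for r in self._records.values()])


def nrm_y(S: SimilarityMatrix, A: CombinationNetwork, i: str, j: str,
          exclude_self: bool = True) -> float:
    """Directed neighbor-recommender component y_ij for one pair."""
    if i == j:
        raise ValueError(f"i == j == {i!r}: self-pairs cannot be scored")
    ii, jj = S.drugs.index(i), S.drugs.index(j)
    if A.drugs.ids != S.drugs.ids:
        raise ValueError("similarity matrix and network use different DrugSets")
    y, _ = _y_entry(S.values, A.adjacency, ii, jj, exclude_self)
    return y


def _y_entry(S: np.ndarray, A: np.ndarray, i: int, j: int,
             exclude_self: bool) -> tuple[float, bool]:
    w = S[i].copy()
    w[j] = 0.0
    if exclude_self:
        w[i] = 0.0
    den = w.sum()
    if den <= 0.0:
        return 0.0, True
    return float(np.clip(w @ A[:, j] / den, 0.0, 1.0)), False


def _y_matrix(S: np.ndarray, A: np.ndarray, exclude_self: bool
              ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Y over all ordered pairs; returns (Y, degenerate mask)."""
    d = np.diag(S)
    num = S @ A  # Σ_k S_ik a_kj, all k
    den = S.sum(axis=1)[:, None] - S  # drop k = j
    # a_jj == 0 so the k = j term never contributes to num
    if exclude_self:
        num = num - d[:, None] * A  # drop k = i term S_ii * a_ij
        den = den - d[:, None]      # and its weight
    degenerate = den <= 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        Y = np.where(degenerate, 0.0, num / np.where(degenerate, 1.0, den))
    return np.clip(Y, 0.0, 1.0), degenerate


def score_pairs(S: SimilarityMatrix, A: CombinationNetwork,
                pairs: Iterable[tuple[str, str]],
                masked: Iterable[tuple[str, str]] = (),
                exclude_self: bool = True) -> NRMScores:
    """Score candidate pairs; ``masked`` edges are removed from A first.

    Masked edges (e.g. a held-out test fold) contribute to no pair's score,
    including pairs other than themselves.
    """
    if A.drugs.ids != S.drugs.ids:
        raise ValueError("similarity matrix and network use different DrugSets")
    masked = list(masked)
    if masked:
        A = A.without_pairs(masked)
    Y, degen = _y_matrix(S.values, A.adjacency, exclude_self)
    idx = S.drugs.index
    records: dict[tuple[str, str], PairScore] = {}
    for a, b in pairs:
        p = canonical_pair(a, b)
        if p in records:
            continue
        i, j = idx(p[0]), idx(p[1])
        records[p] = PairScore(float(Y[i, j]), float(Y[j, i]),
                               bool(degen[i, j] or degen[j, i]))
    return NRMScores(records)


def all_pairs(drugs: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered non-self pairs over a drug id sequence."""
    ids = list(drugs)
    return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]


def classify(scores: NRMScores, threshold: float = 0.5
             ) -> list[tuple[str, str, int]]:
    """Label each scored pair: 1 iff probability >= threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    return [(a, b, int(rec.probability >= threshold))
            for (a, b), rec in scores]
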