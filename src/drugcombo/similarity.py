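"""Tanimoto (Jaccard) similarity of set-valued feature profiles.

The coefficient for two annotation sets A and B is |A∩B| / (|A| + |B| − |A∩B|),
which lies in [0, 1]. The empty-vs-empty case is 0/0 and therefore undefined;
it is reported with ``defined=False`` rather than raised, and the matrix
builder resolves it by policy (default: similarity 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet

import numpy as np

from .data_model import DrugSet, FeatureProfile, SimilarityMatrix


@dataclass(frozen=True)
class TanimotoResult:
    """Similarity value plus a definedness flag for the 0/0 case."""

    value: float
    defined: bool

    def __post_init__(self) -> None:
        if self.defined and not (0.0 <= self.value <= 1.0):
            raise ValueError(f"Tanimoto value {self.value} outside [0, 1]")


def tanimoto(set_a: AbstractSet[str], set_b: AbstractSet[str]) -> TanimotoResult:
    """Tanimoto coefficient of two finite sets.

    Returns ``TanimotoResult(0.0, defined=False)`` when both sets are empty.
    """
    n_ab = len(set_a & set_b)
    denom = len(set_a) + len(set_b) - n_ab  # == |A ∪ B|
    if denom == 0:
        return TanimotoResult(0.0, defined=False)
    return TanimotoResult(n_ab / denom, defined=True)


def profile_to_matrix(profile: FeatureProfile, drugs: DrugSet,
                      undefined_policy: str = "zero") -> SimilarityMatrix:
    """Pairwise Tanimoto matrix over ``drugs`` for one feature channel.

    ``undefined_policy`` resolves pairs where both drugs have empty token
    sets: ``"zero"`` stores 0, ``"error"`` raises naming the pair. The
    diagonal is 1 by convention (a drug is identical to itself) even for
    empty-set drugs.
    """
    if undefined_policy not in ("zero", "error"):
        raise ValueError('undefined_policy must be "zero" or "error"')
    n = len(drugs)
    sets = [profile.tokens(d) for d in drugs]
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = tanimoto(sets[i], sets[j])
            if not r.defined:
                if undefined_policy == "error":
                    raise ValueError(
                        f"Tanimoto undefined for ({drugs.ids[i]}, {drugs.ids[j]}): "
                        "both token sets empty"
                    )
                v = 0.0
            else:
                v = r.value
            values[i, j] = values[j, i] = v
    return SimilarityMatrix(profile.channel, drugs, values)
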