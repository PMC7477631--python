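"""Stacked ensemble: per-channel neighbor-recommender base predictors fused
by a logistic-regression meta-classifier.

The meta-features are out-of-fold base probabilities: each pair's base vector
is computed with that pair's fold masked out of the combination network, so
no pair's own label (nor any co-fold label) leaks into its meta-features.
An in-sample mode exists for replication of pipelines that skip this
precaution; it is leaky and warned about.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression

from .data_model import CombinationNetwork, SimilarityMatrix
from .nrm import score_pairs


@dataclass
class EnsembleModel:
    """Logistic meta-classifier over ordered base channels."""

    channels: tuple[str, ...]
    coef: np.ndarray
    intercept: float
    scheme: str  # "out-of-fold" or "in-sample"

    def to_json(self, path: str | Path) -> None:
        blob = {
            "channels": list(self.channels),
            "coef": [float(c) for c in self.coef],
            "intercept": float(self.intercept),
            "scheme": self.scheme,
        }
        Path(path).write_text(json.dumps(blob, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "EnsembleModel":
        blob = json.loads(Path(path).read_text())
        return cls(tuple(blob["channels"]), np.asarray(blob["coef"], float),
                   float(blob["intercept"]), blob["scheme"])


def base_prediction_matrix(matrices: dict[str, SimilarityMatrix],
                           network: CombinationNetwork,
                           pairs: list[tuple[str, str, int]],
                           folds: np.ndarray | None,
                           exclude_self: bool = True) -> np.ndarray:
    """Per-pair base probabilities, one column per channel.

    With ``folds`` given (an int array over pairs), each fold's rows are
    scored with that fold's positive pairs masked from the network
    (out-of-fold scores). ``folds=None`` gives in-sample scores.
    """
    channels = tuple(matrices)
    base = np.zeros((len(pairs), len(channels)))
    plain = [(a, b) for a, b, _y in pairs]
    if folds is None:
        for c, channel in enumerate(channels):
            scores = score_pairs(matrices[channel], network, plain,
                                 exclude_self=exclude_self)
            base[:, c] = [scores[p].probability for p in plain]
        return base
    folds = np.asarray(folds)
    if folds.shape != (len(pairs),):
        raise ValueError("fold assignment must give one fold index per pair")
    for f in np.unique(folds):
        rows = np.flatnonzero(folds == f)
        mask = [(a, b) for a, b, y in (pairs[r] for r in rows) if y == 1]
        fold_pairs = [plain[r] for r in rows]
        for c, channel in enumerate(channels):
            scores = score_pairs(matrices[channel], network, fold_pairs,
                                 masked=mask, exclude_self=exclude_self)
            base[rows, c] = [scores[p].probability for p in fold_pairs]
    return base


def fit_ensemble(base: np.ndarray, labels: np.ndarray,
                 channels: tuple[str, ...],
                 scheme: str = "out-of-fold") -> EnsembleModel:
    """Fit the logistic meta-classifier on base probabilities.

    Unregularized logistic regression; perfectly collinear base columns are
    tolerated (warned, fit proceeds).
    """
    base = np.asarray(base, float)
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("meta-classifier training needs both classes")
    if base.shape[1] != len(channels):
        raise ValueError("base matrix width does not match channel count")
    if base.shape[1] >= 2:
        rank = np.linalg.matrix_rank(np.column_stack([base, np.ones(len(base))]))
        if rank < base.shape[1] + 1:
            warnings.warn("collinear base predictor columns; fit proceeds")
    if scheme == "in-sample":
        warnings.warn("in-sample base predictions leak training labels into "
                      "the meta-features; use out-of-fold stacking for evaluation")
    elif scheme != "out-of-fold":
        raise ValueError('scheme must be "out-of-fold" or "in-sample"')
    glm = LogisticRegression(C=np.inf, max_iter=5000)  # unregularized
    glm.fit(base, labels)
    pos = int(np.where(glm.classes_ == 1)[0][0])
    sign = 1.0 if pos == 1 else -1.0
    return EnsembleModel(tuple(channels), sign * glm.coef_[0].astype(float),
                         sign * float(glm.intercept_[0]), scheme)


def ensemble_predict(model: EnsembleModel, base: np.ndarray,
                     channels: tuple[str, ...] | None = None) -> np.ndarray:
    """Meta probabilities for a base matrix with matching channel order."""
    if channels is not None and tuple(channels) != model.channels:
        raise ValueError(
            f"channel order mismatch: model {model.channels}, input {tuple(channels)}"
        )
    base = np.asarray(base, float)
    if base.shape[1] != len(model.channels):
        raise ValueError("base matrix width does not match the model's channels")
    z = base @ model.coef + model.intercept
    return 1.0 / (1.0 + np.exp(-z))
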