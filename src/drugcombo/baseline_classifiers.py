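"""Feature-vector baselines: logistic regression (GLM), naive Bayes and SVM.

Each drug pair is represented by its per-channel similarity vector (one
Tanimoto value per channel, in declared channel order) plus a binary label;
the three classifiers are trained on that table and emit probabilities.

Features are already in [0, 1], so no rescaling is applied. The SVM uses an
RBF kernel with probability outputs; gamma and C default to the library
heuristics, with an optional small grid search. Naive Bayes defaults to a
Gaussian event model (the features are continuous), with a Bernoulli option
for binary inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.svm import SVC

from .data_model import (CombinationNetwork, DrugSet, PairDataset,
                         SimilarityMatrix, canonical_pair)

ALGORITHMS = ("glm", "nb", "svm")


@dataclass
class TrainedModel:
    """A fitted baseline classifier bound to a fixed channel order."""

    algorithm: str
    channels: tuple[str, ...]
    estimator: Any
    hyperparams: dict = field(default_factory=dict)

    def predict_proba(self, dataset: PairDataset) -> np.ndarray:
        return predict(self, dataset)


def assemble_pair_features(matrices: dict[str, SimilarityMatrix],
                           pairs: list[tuple[str, str, int]],
                           channels: tuple[str, ...] | None = None,
                           missing_policy: str = "zero") -> PairDataset:
    """Build the per-pair similarity table, one column per channel.

    ``channels`` fixes the column order (default: insertion order of
    ``matrices``). A drug absent from a channel's matrix is handled by
    ``missing_policy``: "zero" imputes similarity 0 and flags it in the
    missing mask, "drop"/"error" raise for now-unresolvable pairs.
    """
    if channels is None:
        channels = tuple(matrices)
    feats = np.zeros((len(pairs), len(channels)))
    miss = np.zeros(feats.shape, dtype=bool)
    for c, channel in enumerate(channels):
        m = matrices[channel]
        for r, (a, b, _y) in enumerate(pairs):
            if a in m.drugs and b in m.drugs:
                feats[r, c] = m.value(a, b)
            elif missing_policy == "zero":
                miss[r, c] = True
            else:
                raise KeyError(
                    f"pair ({a}, {b}) has no similarity in channel {channel!r} "
                    f"(missing_policy={missing_policy!r})"
                )
    return PairDataset(tuple(pairs), channels, feats, miss)


def labeled_pairs_from_network(network: CombinationNetwork,
                               pairs: list[tuple[str, str]] | None = None
                               ) -> list[tuple[str, str, int]]:
    """Attach adjacency labels to candidate pairs (default: all pairs)."""
    if pairs is None:
        from .nrm import all_pairs
        pairs = all_pairs(network.drugs.ids)
    edge = network.pair_set
    return [(*canonical_pair(a, b), int(canonical_pair(a, b) in edge))
            for a, b in pairs]


def _make_estimator(algorithm: str, hyperparams: dict, seed: int):
    hp = dict(hyperparams)
    if algorithm == "glm":
        return LogisticRegression(C=np.inf, max_iter=2000, **hp)  # unregularized
    if algorithm == "nb":
        event_model = hp.pop("event_model", "gaussian")
        if event_model == "gaussian":
            return GaussianNB(**hp)
        if event_model == "bernoulli":
            return BernoulliNB(**hp)
        raise ValueError(f"unknown NB event model {event_model!r}")
    if algorithm == "svm":
        grid = hp.pop("grid_search", False)
        base = SVC(kernel="rbf", probability=True, random_state=seed,
                   gamma=hp.pop("gamma", "scale"), C=hp.pop("C", 1.0), **hp)
        if grid:
            return GridSearchCV(
                base,
                {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.1, 1.0]},
                cv=3, scoring="roc_auc", n_jobs=1,
            )
        return base
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def fit(dataset: PairDataset, algorithm: str,
        hyperparams: dict | None = None, seed: int = 0) -> TrainedModel:
    """Fit one baseline classifier; deterministic given seed and settings."""
    algorithm = algorithm.lower()
    y = dataset.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    X = dataset.features
    const = np.ptp(X, axis=0) == 0
    if const.any():
        names = [c for c, flag in zip(dataset.channels, const) if flag]
        warnings.warn(f"constant feature column(s): {names}")
    est = _make_estimator(algorithm, hyperparams or {}, seed)
    with warnings.catch_warnings():
        # sklearn 1.9 deprecates SVC(probability=True); fine until 1.11
        warnings.filterwarnings("ignore", message=".*probability.*",
                                category=FutureWarning)
        est.fit(X, y)
    return TrainedModel(algorithm, dataset.channels, est, dict(hyperparams or {}))


def predict(model: TrainedModel, dataset: PairDataset) -> np.ndarray:
    """Positive-class probability per pair; channel order must match."""
    if dataset.channels != model.channels:
        raise ValueError(
            f"channel order mismatch: model {model.channels}, data {dataset.channels}"
        )
    proba = model.estimator.predict_proba(dataset.features)
    classes = getattr(model.estimator, "classes_",
                      model.estimator.best_estimator_.classes_
                      if hasattr(model.estimator, "best_estimator_") else None)
    pos_col = int(np.where(classes == 1)[0][0])
    return proba[:, pos_col]
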