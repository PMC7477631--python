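"""Screening of similarity channels before ensembling.

For each channel, the similarity values of known-combination pairs are
compared against those of non-combination pairs with a Welch two-sample
t-test and a signed two-sample Kolmogorov-Smirnov statistic, and a random
forest over the per-pair feature vectors provides a Gini importance which is
min-max normalized across channels. Channels pass the selection rule when
their t-test p-value clears the significance cutoff, with an optional
"marginal keep" cutoff for borderline channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .data_model import CombinationNetwork, PairDataset, SimilarityMatrix


@dataclass(frozen=True)
class ChannelAssessment:
    channel: str
    t_p: float
    ks_p: float
    ks_d: float
    gini: float
    gini_norm: float
    selected: bool


@dataclass(frozen=True)
class FeatureAssessment:
    """Per-channel statistics plus the resulting selection flags."""

    channels: tuple[ChannelAssessment, ...]
    alpha: float
    marginal: float

    def selected_channels(self) -> tuple[str, ...]:
        return tuple(c.channel for c in self.channels if c.selected)

    def __getitem__(self, channel: str) -> ChannelAssessment:
        for c in self.channels:
            if c.channel == channel:
                return c
        raise KeyError(channel)


def split_by_label(matrix: SimilarityMatrix, network: CombinationNetwork
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Similarity values of edges vs non-edges (upper triangle, i < j)."""
    if matrix.drugs.ids != network.drugs.ids:
        raise ValueError("matrix and network use different DrugSets")
    iu, ju = np.triu_indices(len(matrix.drugs), k=1)
    vals = matrix.values[iu, ju]
    edge = network.adjacency[iu, ju].astype(bool)
    return vals[edge], vals[~edge]


def ttest(pos: np.ndarray, neg: np.ndarray) -> float:
    """Two-sided Welch t-test p-value for positive vs negative similarities."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each sample needs at least 2 values for the t-test")
    return float(stats.ttest_ind(pos, neg, equal_var=False).pvalue)


def kstest_signed(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """Signed two-sample KS statistic and its p-value.

    d is ECDF_neg − ECDF_pos evaluated where the absolute difference is
    maximal, so d > 0 when the positive sample is stochastically larger;
    d ranges over [−1, 1]. The p-value is the standard two-sample KS
    p-value of |d|.
    """
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("KS test needs nonempty samples")
    grid = np.concatenate([pos, neg])
    ecdf_pos = np.searchsorted(np.sort(pos), grid, side="right") / len(pos)
    ecdf_neg = np.searchsorted(np.sort(neg), grid, side="right") / len(neg)
    diff = ecdf_neg - ecdf_pos
    d = float(diff[np.argmax(np.abs(diff))])
    p = float(stats.ks_2samp(pos, neg).pvalue)
    return d, p


def rf_importance(dataset: PairDataset, seed: int, n_trees: int = 500
                  ) -> dict[str, float]:
    """Raw Gini importance per channel from a random forest.

    500 trees, sqrt(C) candidate features per split, deterministic per seed.
    """
    y = dataset.labels
    if len(np.unique(y)) < 2:
        raise ValueError("random forest importance needs both classes present")
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    rf.fit(dataset.features, y)
    return dict(zip(dataset.channels, rf.feature_importances_.astype(float)))


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Affine map onto [0, 1]: min -> 0, max -> 1. All-equal input errors."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("min-max normalization needs at least 2 values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("min-max normalization undefined: all values equal")
    return (v - lo) / (hi - lo)


def assess_channels(matrices: dict[str, SimilarityMatrix],
                    network: CombinationNetwork,
                    dataset: PairDataset,
                    seed: int,
                    alpha: float = 0.05,
                    marginal: float = 0.1) -> FeatureAssessment:
    """Run the full screen: tests, RF importance, normalization, selection."""
    stats_rows = []
    for channel in dataset.channels:
        pos, neg = split_by_label(matrices[channel], network)
        t_p = ttest(pos, neg)
        ks_d, ks_p = kstest_signed(pos, neg)
        stats_rows.append((channel, t_p, ks_p, ks_d))
    gini = rf_importance(dataset, seed=seed)
    raw = np.array([gini[c] for c, *_ in stats_rows])
    norm = minmax_normalize(raw) if len(raw) >= 2 else np.ones_like(raw)
    channels = tuple(
        ChannelAssessment(
            channel=c, t_p=t_p, ks_p=ks_p, ks_d=ks_d,
            gini=float(g), gini_norm=float(gn),
            selected=_selected(t_p, alpha, marginal),
        )
        for (c, t_p, ks_p, ks_d), g, gn in zip(stats_rows, raw, norm)
    )
    return FeatureAssessment(channels, alpha=alpha, marginal=marginal)


def _selected(t_p: float, alpha: float, marginal: float) -> bool:
    return t_p < alpha or t_p <= marginal


def select_channels(assessment: FeatureAssessment,
                    alpha: float | None = None,
                    marginal: float | None = None) -> tuple[str, ...]:
    """Apply the selection rule to recorded statistics.

    A channel is kept when t_p < alpha, or t_p <= the marginal cutoff
    (borderline channels retained by judgement, e.g. a p of exactly 0.1
    with the default marginal of 0.1). An empty selection raises, advising
    a manual channel list.
    """
    alpha = assessment.alpha if alpha is None else alpha
    marginal = assessment.marginal if marginal is None else marginal
    chosen = tuple(c.channel for c in assessment.channels
                   if _selected(c.t_p, alpha, marginal))
    if not chosen:
        raise ValueError(
            "no channel passed the selection rule; pass an explicit channel list"
        )
    return chosen
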