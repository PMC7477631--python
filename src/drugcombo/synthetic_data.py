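"""Synthetic benchmark generator with planted cluster structure.

Drugs are assigned to latent clusters. Informative channels draw annotation
tokens so that same-cluster drugs overlap far more than cross-cluster drugs
(their Tanimoto similarity is high within clusters); noise channels draw
tokens independently of the clusters. Combination edges are drawn with
probability ``sigmoid(edge_base + edge_coef * same_cluster)``, encoding the
"similar drugs combine similarly" signal that the neighbor recommender
exploits — so parameter recovery on these fixtures is a meaningful check.

Everything is reproducible from the config seed, and the cluster truth is
written to a sidecar that the prediction path never reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import (CombinationNetwork, DrugSet, FeatureProfile,
                         SimilarityMatrix, write_pair_list, write_profile,
                         write_similarity_matrix)
from .similarity import profile_to_matrix

TRUTH_SIDECAR = "truth_clusters.json"  # never consumed by the prediction path


@dataclass(frozen=True)
class GeneratorConfig:
    n_drugs: int = 120
    n_clusters: int = 4
    n_channels: int = 4
    informative: tuple[bool, ...] = (True, True, False, False)
    tokens_per_cluster: int = 30
    p_within: float = 0.5       # within-cluster token-sharing probability
    p_background: float = 0.02  # background token probability
    edge_base: float = -4.5     # logit of the cross-cluster edge rate
    edge_coef: float = 4.5      # added logit for same-cluster pairs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 4:
            raise ValueError("n_drugs must be >= 4")
        if self.n_clusters < 2 or self.n_clusters > self.n_drugs:
            raise ValueError("need 2 <= n_clusters <= n_drugs")
        if len(self.informative) != self.n_channels:
            raise ValueError("informative flags must match n_channels")
        if not any(self.informative):
            raise ValueError("at least one channel must be informative")
        for p in (self.p_within, self.p_background):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(f"channel{i + 1}" for i in range(self.n_channels))


@dataclass(frozen=True)
class SyntheticBundle:
    config: GeneratorConfig
    drugs: DrugSet
    profiles: dict[str, FeatureProfile]
    network: CombinationNetwork
    clusters: dict[str, int]

    def matrices(self) -> dict[str, SimilarityMatrix]:
        return {name: profile_to_matrix(profile, self.drugs)
                for name, profile in self.profiles.items()}


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def generate(config: GeneratorConfig) -> SyntheticBundle:
    """Draw one synthetic benchmark; byte-identical per seed."""
    n, c = config.n_drugs, config.n_clusters
    p_within_edge = _sigmoid(config.edge_base + config.edge_coef)
    p_cross_edge = _sigmoid(config.edge_base)
    same = _expected_same_cluster_pairs(n, c)
    total = n * (n - 1) // 2
    expected_pos = same * p_within_edge + (total - same) * p_cross_edge
    if expected_pos < 1.0:
        raise ValueError(
            f"config implies {expected_pos:.2f} expected positive pairs; "
            "raise edge_base/edge_coef or n_drugs"
        )
    rng = np.random.default_rng(config.seed)
    width = len(str(n - 1))
    ids = tuple(f"D{i:0{width}d}" for i in range(n))
    drugs = DrugSet(ids)
    clusters = {d: int(i % c) for i, d in enumerate(ids)}

    vocab = config.tokens_per_cluster * c
    profiles: dict[str, FeatureProfile] = {}
    # density a noise channel needs to match an informative one
    p_noise = (config.p_within + (c - 1) * config.p_background) / c
    for ch, name in enumerate(config.channel_names):
        members = {}
        for d in ids:
            block = clusters[d]
            if config.informative[ch]:
                probs = np.full(vocab, config.p_background)
                lo = block * config.tokens_per_cluster
                probs[lo:lo + config.tokens_per_cluster] = config.p_within
            else:
                probs = np.full(vocab, p_noise)
            keep = rng.random(vocab) < probs
            members[d] = frozenset(f"{name}_t{t}" for t in np.flatnonzero(keep))
        profiles[name] = FeatureProfile(name, members)

    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            logit = config.edge_base
            if clusters[ids[i]] == clusters[ids[j]]:
                logit += config.edge_coef
            if rng.random() < _sigmoid(logit):
                edges.append((ids[i], ids[j]))
    network = CombinationNetwork(drugs, tuple(edges))
    return SyntheticBundle(config, drugs, profiles, network, clusters)


def _expected_same_cluster_pairs(n: int, c: int) -> int:
    sizes = [len(range(k, n, c)) for k in range(c)]
    return sum(s * (s - 1) // 2 for s in sizes)


def write_fixture(bundle: SyntheticBundle, directory: str | Path) -> None:
    """Write the bundle as plain-text files consumable by the CLI.

    Per channel: a GMT-like profile and a Tanimoto similarity matrix; plus
    the positive pair list, a truth sidecar with the cluster assignment, and
    the generator config.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stamp = f"seed={bundle.config.seed}"
    for name, profile in bundle.profiles.items():
        write_profile(profile, directory / f"profile_{name}.tsv")
    for name, matrix in bundle.matrices().items():
        write_similarity_matrix(matrix, directory / f"similarity_{name}.tsv",
                                header=stamp)
    write_pair_list(bundle.network, directory / "pairs.tsv", header=stamp)
    truth = {"clusters": bundle.clusters,
             "config": _config_dict(bundle.config)}
    (directory / TRUTH_SIDECAR).write_text(json.dumps(truth, indent=2) + "\n")


def _config_dict(config: GeneratorConfig) -> dict:
    d = {f: getattr(config, f) for f in config.__dataclass_fields__}
    d["informative"] = list(d["informative"])
    return d


def read_fixture(directory: str | Path) -> tuple[DrugSet, dict, CombinationNetwork]:
    """Read back a written fixture (profiles, matrices, pair list).

    The truth sidecar is deliberately not read here: prediction code must
    stay blind to the planted clusters.
    """
    from .data_model import read_pair_list, read_profile, read_similarity_matrix

    directory = Path(directory)
    profiles = {}
    matrices = {}
    for p in sorted(directory.glob("profile_*.tsv")):
        name = p.stem.removeprefix("profile_")
        profiles[name] = read_profile(p, name)
    for p in sorted(directory.glob("similarity_*.tsv")):
        name = p.stem.removeprefix("similarity_")
        matrices[name] = read_similarity_matrix(p, channel=name)
    some_matrix = next(iter(matrices.values()))
    network = read_pair_list(directory / "pairs.tsv", drugs=some_matrix.drugs)
    return some_matrix.drugs, {"profiles": profiles, "matrices": matrices}, network
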