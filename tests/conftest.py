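import numpy as np
import pytest

from drugcombo.data_model import (CombinationNetwork, DrugSet, FeatureProfile,
                                  SimilarityMatrix)


@pytest.fixture
def drugs4():
    return DrugSet(("A", "B", "C", "D"))


@pytest.fixture
def toy_profile():
    return FeatureProfile("target", {
        "A": frozenset({"t1", "t2"}),
        "B": frozenset({"t2", "t3"}),
        "C": frozenset({"t3"}),
        "D": frozenset(),
    })


@pytest.fixture
def toy_network(drugs4):
    return CombinationNetwork(drugs4, (("A", "B"), ("C", "D")))


def random_instance(rng, n, edge_p=0.3):
    """A random (SimilarityMatrix, CombinationNetwork) pair over n drugs."""
    ids = tuple(f"D{i:02d}" for i in range(n))
    drugs = DrugSet(ids)
    s = rng.random((n, n))
    s = (s + s.T) / 2
    np.fill_diagonal(s, 1.0)
    S = SimilarityMatrix("rand", drugs, s)
    edges = [(ids[i], ids[j]) for i in range(n) for j in range(i + 1, n)
             if rng.random() < edge_p]
    if not edges:
        edges = [(ids[0], ids[1])]
    return S, CombinationNetwork(drugs, tuple(edges))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic benchmark shared across the session."""
    from drugcombo.synthetic_data import GeneratorConfig, generate
    bundle = generate(GeneratorConfig(seed=7))
    return bundle, bundle.matrices()
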