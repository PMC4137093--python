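import random

import numpy as np
import pytest

from remort.alignments import AMINO_ACIDS, BinaryProfile, SequenceRecord, load_matrix
from remort.clustering import ResidueWeights, log_rarity_weights
from remort.network import EDGE_WEIGHTS, NodeInfo, OrthologyEdge, OrthologyNetwork


@pytest.fixture(scope="session")
def blosum62():
    return load_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def weights() -> ResidueWeights:
    return log_rarity_weights()


@pytest.fixture
def rng():
    return random.Random(0)


def random_sequence(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def random_profile_set(seed: int, n_max: int = 12, length: int = 40):
    """Random binary profiles plus a random query of matching length."""
    rng = random.Random(seed)
    n = rng.randint(2, n_max)
    profiles = [
        BinaryProfile(f"p{i:02d}",
                      np.array([rng.random() < 0.4 for _ in range(length)],
                               dtype=np.int8))
        for i in range(n)
    ]
    query = SequenceRecord("query", "sp", random_sequence(rng, length))
    return profiles, query


def random_typed_network(seed: int, n_max: int = 8) -> OrthologyNetwork:
    """Random undirected graph with edges typed from the five edge classes."""
    rng = random.Random(seed)
    n = rng.randint(2, n_max)
    net = OrthologyNetwork()
    names = [f"n{i}" for i in range(n)]
    for name in names:
        net.nodes[name] = NodeInfo("sp", rng.random())
    etypes = list(EDGE_WEIGHTS)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.45:
                net.edges.append(
                    OrthologyEdge(names[i], names[j], rng.choice(etypes)))
    return net
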