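import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from saedr.embedding_lexicon import EmbeddingSpace, build_lexicon
from saedr.lexical_network import LexicalNetwork
from saedr.synthetic_data import gen_embedding_space

import networkx as nx
import pandas as pd


@pytest.fixture
def tiny_space() -> EmbeddingSpace:
    tokens = ["headache", "abdominal", "pain", "death", "nausea"]
    rng = np.random.default_rng(7)
    vectors = rng.normal(size=(len(tokens), 4))
    return EmbeddingSpace(tokens=tokens, vectors=vectors, dim=4)


@pytest.fixture
def tiny_lexicon(tiny_space):
    table = pd.DataFrame(
        {
            "term": ["headache", "abdominal pain", "death", "nausea"],
            "tokens": ["headache", "abdominal|pain", "death", "nausea"],
            "pt_id": ["PT1", "PT2", "PT3", "PT4"],
        }
    )
    return build_lexicon(table, tiny_space)


@pytest.fixture(scope="session")
def planted_small():
    """Small planted space shared across tests (read-only)."""
    return gen_embedding_space(n_terms=120, dim=16, noise_sd=0.2, n_clones=10, rng_seed=42)


def make_weighted_network(edges) -> LexicalNetwork:
    """LexicalNetwork from explicit (u, v, weight) triples."""
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return LexicalNetwork(graph=g, k=0, pt_map={n: n for n in g.nodes})


@pytest.fixture
def triangle_network() -> LexicalNetwork:
    return make_weighted_network([("a", "b", 0.9), ("b", "c", 0.4), ("a", "c", 0.2)])
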