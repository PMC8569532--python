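"""Weighted k-nearest-neighbor lexical network over embedded ADR terms.

Each term is connected to its k nearest neighbors by cosine distance; the
neighbor relation is symmetrized by union, edges are undirected, and edge
weight is the cosine similarity of the two term vectors (floored at a small
positive epsilon so random-walk transition weights stay positive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from saedr.embedding_lexicon import Lexicon

logger = logging.getLogger(__name__)

#: floor applied to non-positive cosine similarities so every retained
#: k-NN edge carries a usable positive transition weight
WEIGHT_EPSILON = 1e-8


@dataclass
class LexicalNetwork:
    """Undirected, simple, weighted graph of ADR terms."""

    graph: nx.Graph
    k: int
    pt_map: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]


def _cosine_knn(vectors: np.ndarray, k: int, chunk: int = 2048) -> list[list[int]]:
    """Exact top-k neighbor indices per row by cosine distance.

    Rows are assumed pre-sorted in the desired tie-break order; a stable
    argsort then breaks exact distance ties by that order.
    """
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    unit = vectors / norms
    n = unit.shape[0]
    out: list[list[int]] = []
    for start in range(0, n, chunk):
        sims = unit[start : start + chunk] @ unit.T
        for i, row in enumerate(sims):
            gi = start + i
            row = row.copy()
            row[gi] = -np.inf  # exclude self from the distance ranking
            order = np.argsort(-row, kind="stable")  # self sorts last
            out.append([int(j) for j in order[:k]])
    return out


def build_knn_network(lexicon: Lexicon, k: int) -> LexicalNetwork:
    """Build the union-of-neighborhoods k-NN network over embedded terms.

    Terms without a vector are silently excluded (logged).  Distance ties
    are broken by lexicographic term order for cross-platform determinism.

    Raises ``ValueError`` if fewer than 2 embedded terms or ``k`` is not in
    ``[1, n_nodes)``.
    """
    embedded = sorted(lexicon.embedded, key=lambda r: r.term)
    n_excluded = len(lexicon.records) - len(embedded)
    if n_excluded:
        logger.info("excluding %d terms without vectors from the network", n_excluded)
    n = len(embedded)
    if n < 2:
        raise ValueError(f"need at least 2 embedded terms to build a network, got {n}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of nodes ({n})")

    terms = [r.term for r in embedded]
    vectors = np.vstack([r.vector for r in embedded])
    unit = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)

    neighbor_idx = _cosine_knn(vectors, k)

    graph = nx.Graph()
    graph.add_nodes_from(terms)
    for i, neighbors in enumerate(neighbor_idx):
        for j in neighbors:
            sim = float(unit[i] @ unit[j])
            weight = max(sim, WEIGHT_EPSILON)
            graph.add_edge(terms[i], terms[j], weight=weight)

    pt_map = {r.term: r.pt_id for r in embedded}
    logger.info("k-NN network: %d nodes, %d edges (k=%d)", n, graph.number_of_edges(), k)
    return LexicalNetwork(graph=graph, k=k, pt_map=pt_map)


def write_network(network: LexicalNetwork, edges_path: str | Path, nodes_path: str | Path | None = None) -> None:
    """Serialize the network as TSV edge list (+ optional nodes file)."""
    rows = [
        {"node_a": u, "node_b": v, "weight": d["weight"]}
        for u, v, d in network.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
        edges_path, sep="\t", index=False
    )
    if nodes_path is not None:
        nrows = [
            {"node_id": i, "term": t, "pt_id": network.pt_map.get(t, "")}
            for i, t in enumerate(network.nodes)
        ]
        pd.DataFrame(nrows, columns=["node_id", "term", "pt_id"]).to_csv(
            nodes_path, sep="\t", index=False
        )


def read_network(edges_path: str | Path, nodes_path: str | Path | None = None, k: int = 0) -> LexicalNetwork:
    """Read a network from a TSV edge list written by :func:`write_network`."""
    edges = pd.read_csv(edges_path, sep="\t", dtype={"node_a": str, "node_b": str})
    graph = nx.Graph()
    for row in edges.itertuples(index=False):
        graph.add_edge(row.node_a, row.node_b, weight=float(row.weight))
    pt_map: dict[str, str] = {}
    if nodes_path is not None:
        nodes = pd.read_csv(nodes_path, sep="\t", dtype=str).fillna("")
        pt_map = dict(zip(nodes["term"], nodes["pt_id"]))
        graph.add_nodes_from(nodes["term"])
    return LexicalNetwork(graph=graph, k=k, pt_map=pt_map)
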