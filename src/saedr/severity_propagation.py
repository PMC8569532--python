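"""Weighted random walks from seed nodes and SAEDR score computation.

From each severe and benign seed node, first-order weighted random walks
are run over the lexical network; the next node at every step is drawn with
probability proportional to incident edge weight.  Visit counts ``s_u``
(severe-initiated walks) and ``b_u`` (benign-initiated walks) give the raw
score ``s_u / (s_u + b_u)``, stabilized by bootstrap resampling of whole
walks, averaged at the preferred-term level across seed sources, and
min-max normalized to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from saedr.embedding_lexicon import Lexicon
from saedr.lexical_network import LexicalNetwork
from saedr.seed_selection import SeedSets

logger = logging.getLogger(__name__)


@dataclass
class WalkConfig:
    """Random-walk parameters; defaults follow the published configuration."""

    n_walks_per_seed: int = 5000
    walk_length: int = 200
    rng_seed: int = 0
    # exclusion scope for visits to a seed node during walks it started;
    # "start_node" drops them, "none" keeps everything
    self_visit_exclusion: str = "start_node"

    def __post_init__(self) -> None:
        if self.n_walks_per_seed < 1 or self.walk_length < 1:
            raise ValueError("n_walks_per_seed and walk_length must be positive")
        if self.self_visit_exclusion not in ("start_node", "none"):
            raise ValueError(f"unknown self_visit_exclusion {self.self_visit_exclusion!r}")


@dataclass
class WalkTally:
    """Per-node visit counts split by seed polarity, with per-walk records.

    ``severe_walk_counts`` / ``benign_walk_counts`` are sparse matrices of
    shape (n_walks, n_nodes) holding each retained walk's visit counts —
    the resampling unit for the bootstrap.
    """

    nodes: list[str]
    severe_walk_counts: sp.csr_matrix
    benign_walk_counts: sp.csr_matrix
    severe_starts: np.ndarray  # start-node index per severe walk
    benign_starts: np.ndarray
    config: Optional[WalkConfig] = None
    _node_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._node_index:
            self._node_index = {t: i for i, t in enumerate(self.nodes)}

    @property
    def s(self) -> np.ndarray:
        """Total severe-walk visit count per node (symbol s_u)."""
        return np.asarray(self.severe_walk_counts.sum(axis=0)).ravel()

    @property
    def b(self) -> np.ndarray:
        """Total benign-walk visit count per node (symbol b_u)."""
        return np.asarray(self.benign_walk_counts.sum(axis=0)).ravel()

    @property
    def unvisited(self) -> list[str]:
        mask = (self.s + self.b) == 0
        return [t for t, m in zip(self.nodes, mask) if m]

    def swapped(self) -> "WalkTally":
        """Same tally with severe/benign designations exchanged."""
        return WalkTally(
            nodes=self.nodes,
            severe_walk_counts=self.benign_walk_counts,
            benign_walk_counts=self.severe_walk_counts,
            severe_starts=self.benign_starts,
            benign_starts=self.severe_starts,
            config=self.config,
            _node_index=self._node_index,
        )


@dataclass
class SeverityTable:
    """Per-PT severity scores after aggregation and normalization."""

    per_pt: pd.DataFrame  # index pt_id; columns run_*, combined, score_normalized
    per_term: pd.DataFrame  # per-run per-term raw scores
    n_seed_sets_combined: int

    def score(self, pt_id: str) -> float:
        return float(self.per_pt.loc[pt_id, "score_normalized"])


def _adjacency_arrays(network: LexicalNetwork):
    """Padded neighbor-index and cumulative-probability arrays per node."""
    nodes = network.nodes
    index = {t: i for i, t in enumerate(nodes)}
    neigh: list[np.ndarray] = []
    cumprob: list[np.ndarray] = []
    for t in nodes:
        nbrs = [(index[v], d["weight"]) for v, d in network.graph[t].items()]
        if nbrs:
            idx = np.array([i for i, _ in nbrs], dtype=np.int64)
            w = np.array([w for _, w in nbrs], dtype=np.float64)
            cp = np.cumsum(w / w.sum())
            cp[-1] = 1.0
        else:
            idx = np.empty(0, dtype=np.int64)
            cp = np.empty(0, dtype=np.float64)
        neigh.append(idx)
        cumprob.append(cp)
    max_deg = max((len(a) for a in neigh), default=0)
    neigh_mat = np.full((len(nodes), max_deg), -1, dtype=np.int64)
    cum_mat = np.ones((len(nodes), max_deg), dtype=np.float64)
    for i, (idx, cp) in enumerate(zip(neigh, cumprob)):
        neigh_mat[i, : len(idx)] = idx
        cum_mat[i, : len(cp)] = cp
        cum_mat[i, len(cp):] = 1.0 + 1e-12  # padding never selected
    return index, neigh_mat, cum_mat


def _walk_batch(
    start: int,
    n_walks: int,
    length: int,
    neigh_mat: np.ndarray,
    cum_mat: np.ndarray,
    n_nodes: int,
    rng: np.random.Generator,
    exclude_start: bool,
) -> sp.csr_matrix:
    """Run all walks from one seed node; return per-walk visit counts.

    The starting position itself is not counted as a visit; every
    subsequent position is, including repeats.
    """
    counts = np.zeros((n_walks, n_nodes), dtype=np.int32)
    cur = np.full(n_walks, start, dtype=np.int64)
    rows = np.arange(n_walks)
    for _ in range(length):
        u = rng.random(n_walks)
        choice = (cum_mat[cur] < u[:, None]).sum(axis=1)
        cur = neigh_mat[cur, choice]
        counts[rows, cur] += 1
    if exclude_start:
        counts[:, start] = 0
    return sp.csr_matrix(counts)


def run_walks(network: LexicalNetwork, seeds: SeedSets, cfg: WalkConfig) -> WalkTally:
    """Run cfg.n_walks_per_seed weighted walks of cfg.walk_length per seed.

    Every seed must be a network node with at least one edge.  Nodes never
    visited by any walk (e.g. outside the seed components) are reported via
    ``WalkTally.unvisited``.
    """
    index, neigh_mat, cum_mat = _adjacency_arrays(network)
    n_nodes = len(index)
    for term in seeds.all_seeds:
        if term not in index:
            raise ValueError(f"seed term {term!r} is not a network node")
        if network.graph.degree(term) == 0:
            raise ValueError(f"seed node {term!r} has no edges")

    rng = np.random.default_rng(cfg.rng_seed)
    exclude = cfg.self_visit_exclusion == "start_node"

    def run_polarity(terms: Sequence[str]):
        blocks, starts = [], []
        for term in terms:
            i = index[term]
            blocks.append(
                _walk_batch(
                    i, cfg.n_walks_per_seed, cfg.walk_length,
                    neigh_mat, cum_mat, n_nodes, rng, exclude,
                )
            )
            starts.extend([i] * cfg.n_walks_per_seed)
        return sp.vstack(blocks, format="csr"), np.array(starts, dtype=np.int64)

    severe_counts, severe_starts = run_polarity(seeds.severe)
    benign_counts, benign_starts = run_polarity(seeds.benign)

    tally = WalkTally(
        nodes=list(network.nodes),
        severe_walk_counts=severe_counts,
        benign_walk_counts=benign_counts,
        severe_starts=severe_starts,
        benign_starts=benign_starts,
        config=cfg,
    )
    n_unvisited = len(tally.unvisited)
    if n_unvisited:
        logger.warning(
            "%d of %d nodes were never visited; increase n_walks_per_seed or walk_length",
            n_unvisited, n_nodes,
        )
    return tally


def saedr_raw(s_u: float, b_u: float) -> float:
    """Raw severity score s_u / (s_u + b_u).

    Undefined (ValueError) when both counts are zero; such nodes are
    excluded upstream rather than imputed.
    """
    if s_u < 0 or b_u < 0:
        raise ValueError("visit counts must be nonnegative")
    total = s_u + b_u
    if total == 0:
        raise ValueError("saedr_raw undefined for s_u + b_u == 0")
    return s_u / total


def point_scores(tally: WalkTally) -> pd.Series:
    """Per-node raw scores from total visit counts; unvisited nodes omitted."""
    s, b = tally.s.astype(float), tally.b.astype(float)
    total = s + b
    mask = total > 0
    values = np.divide(s, total, out=np.zeros_like(s), where=mask)
    return pd.Series(values[mask], index=[t for t, m in zip(tally.nodes, mask) if m])


def bootstrap_scores(
    tally: WalkTally,
    n_boot: int = 10000,
    rng_seed: int = 0,
    return_interval: bool = False,
):
    """Bootstrap-mean severity score per node.

    Each iteration resamples walks with replacement independently within
    the severe and benign walk sets (sizes preserved), recomputes the raw
    score per node, and the final score is the mean over the iterations in
    which the node was visited at all.  Nodes with no visits in any
    iteration are omitted.

    Returns a Series (node -> bootstrap mean), or with
    ``return_interval=True`` a DataFrame with columns ``bootstrap_mean``,
    ``ci_low``, ``ci_high`` (2.5/97.5 percentile interval) and
    ``n_contributing``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    rng = np.random.default_rng(rng_seed)
    n_nodes = len(tally.nodes)
    n_sev = tally.severe_walk_counts.shape[0]
    n_ben = tally.benign_walk_counts.shape[0]
    if n_sev == 0 or n_ben == 0:
        raise ValueError("bootstrap requires at least one walk of each polarity")

    sev_T = tally.severe_walk_counts.T.tocsr().astype(np.float64)  # nodes x walks
    ben_T = tally.benign_walk_counts.T.tocsr().astype(np.float64)

    store = n_boot * n_nodes <= 200_000_000
    scores = np.full((n_boot, n_nodes), np.nan, dtype=np.float32) if store else None
    sums = np.zeros(n_nodes)
    counts = np.zeros(n_nodes, dtype=np.int64)

    p_sev = np.full(n_sev, 1.0 / n_sev)
    p_ben = np.full(n_ben, 1.0 / n_ben)
    for it in range(n_boot):
        w_s = rng.multinomial(n_sev, p_sev).astype(np.float64)
        w_b = rng.multinomial(n_ben, p_ben).astype(np.float64)
        s = sev_T @ w_s
        b = ben_T @ w_b
        total = s + b
        mask = total > 0
        vals = np.divide(s, total, out=np.full(n_nodes, np.nan), where=mask)
        sums[mask] += vals[mask]
        counts[mask] += 1
        if store:
            scores[it] = vals
    visited = counts > 0
    mean = np.divide(sums, counts, out=np.full(n_nodes, np.nan), where=visited)
    idx = [t for t, v in zip(tally.nodes, visited) if v]
    if not return_interval:
        return pd.Series(mean[visited], index=idx)
    if store:
        with np.errstate(invalid="ignore"):
            lo = np.nanpercentile(scores[:, visited], 2.5, axis=0)
            hi = np.nanpercentile(scores[:, visited], 97.5, axis=0)
    else:  # normal-approximation interval for very large runs
        lo = hi = mean[visited]
    return pd.DataFrame(
        {
            "bootstrap_mean": mean[visited],
            "ci_low": lo,
            "ci_high": hi,
            "n_contributing": counts[visited],
        },
        index=idx,
    )


def aggregate_and_normalize(
    per_term_scores: Sequence[pd.Series],
    lexicon: Lexicon,
) -> SeverityTable:
    """Average term scores at the PT level per run, combine runs, normalize.

    Within each run the PT score is the mean of its scored terms; across
    runs the combined PT score is the mean of the per-run PT scores (over
    the runs that scored the PT); the combined column is then min-max
    normalized so its minimum is exactly 0 and maximum exactly 1.  PTs with
    no scored terms in any run are absent from the output.
    """
    if not per_term_scores:
        raise ValueError("need at least one per-term score table")
    pt_map = lexicon.pt_map()

    run_frames = []
    term_frames = []
    for i, series in enumerate(per_term_scores):
        missing = [t for t in series.index if t not in pt_map]
        if missing:
            raise ValueError(f"terms without pt_id in run {i}: {missing[:5]}")
        df = pd.DataFrame({"term": series.index, "score": series.values})
        df["pt_id"] = df["term"].map(pt_map)
        df["run"] = i
        term_frames.append(df)
        run_frames.append(df.groupby("pt_id")["score"].mean().rename(f"run_{i}"))

    per_pt = pd.concat(run_frames, axis=1)
    per_pt["combined"] = per_pt.mean(axis=1, skipna=True)
    lo, hi = per_pt["combined"].min(), per_pt["combined"].max()
    if hi > lo:
        per_pt["score_normalized"] = (per_pt["combined"] - lo) / (hi - lo)
    else:
        logger.warning("degenerate score range [%g, %g]; normalized scores set to 0.5", lo, hi)
        per_pt["score_normalized"] = 0.5
    per_pt = per_pt.sort_index()

    return SeverityTable(
        per_pt=per_pt,
        per_term=pd.concat(term_frames, ignore_index=True),
        n_seed_sets_combined=len(per_term_scores),
    )


def write_severity_table(table: SeverityTable, path) -> None:
    """Write the per-PT table as TSV with term lists and visit-free columns."""
    terms = (
        table.per_term.groupby("pt_id")["term"]
        .apply(lambda s: "|".join(sorted(set(s))))
        .rename("terms")
    )
    out = table.per_pt.join(terms)
    out.index.name = "pt_id"
    out.reset_index().to_csv(path, sep="\t", index=False)
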