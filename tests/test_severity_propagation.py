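from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, strategies as st

from conftest import make_weighted_network
from oracles import (
    binomial_visit_se,
    exact_bootstrap_mean,
    expected_visits,
    transition_matrix,
)
from saedr.embedding_lexicon import EmbeddingSpace, build_lexicon
from saedr.seed_selection import SeedSets
from saedr.severity_propagation import (
    WalkConfig,
    WalkTally,
    aggregate_and_normalize,
    bootstrap_scores,
    point_scores,
    run_walks,
    saedr_raw,
)


def make_tally(nodes, severe_rows, benign_rows, severe_starts=None, benign_starts=None):
    return WalkTally(
        nodes=list(nodes),
        severe_walk_counts=sp.csr_matrix(np.asarray(severe_rows)),
        benign_walk_counts=sp.csr_matrix(np.asarray(benign_rows)),
        severe_starts=np.asarray(severe_starts if severe_starts is not None else [0] * len(severe_rows)),
        benign_starts=np.asarray(benign_starts if benign_starts is not None else [0] * len(benign_rows)),
    )


class TestRunWalks:
    def path_network(self):
        return make_weighted_network([("a", "b", 1.0)])

    def test_forced_walk_on_path_graph_no_exclusion(self):
        net = self.path_network()
        seeds = SeedSets(severe=["a"], benign=["b"])
        cfg = WalkConfig(n_walks_per_seed=1, walk_length=3, rng_seed=0,
                         self_visit_exclusion="none")
        tally = run_walks(net, seeds, cfg)
        s = dict(zip(tally.nodes, tally.s))
        b = dict(zip(tally.nodes, tally.b))
        # severe walk a->b->a->b: 2 visits to b, 1 self-return to a
        assert s == {"a": 1, "b": 2}
        assert b == {"a": 2, "b": 1}

    def test_forced_walk_self_visits_excluded_by_default(self):
        net = self.path_network()
        seeds = SeedSets(severe=["a"], benign=["b"])
        cfg = WalkConfig(n_walks_per_seed=1, walk_length=3, rng_seed=0)
        tally = run_walks(net, seeds, cfg)
        s = dict(zip(tally.nodes, tally.s))
        b = dict(zip(tally.nodes, tally.b))
        assert s == {"a": 0, "b": 2}
        assert b == {"a": 2, "b": 0}

    def test_markov_oracle_triangle(self, triangle_network):
        n_walks, length = 2000, 50
        seeds = SeedSets(severe=["a"], benign=["b"])
        cfg = WalkConfig(n_walks_per_seed=n_walks, walk_length=length, rng_seed=123,
                         self_visit_exclusion="none")
        tally = run_walks(triangle_network, seeds, cfg)
        nodes = tally.nodes
        P = transition_matrix(triangle_network.graph, nodes)
        for polarity, counts in (("severe", tally.s), ("benign", tally.b)):
            seed = {"severe": "a", "benign": "b"}[polarity]
            si = nodes.index(seed)
            exp = n_walks * expected_visits(P, si, length)
            se = binomial_visit_se(P, si, length, n_walks)
            assert np.all(np.abs(counts - exp) <= 3 * se), (polarity, counts, exp, 3 * se)

    def test_unvisited_nodes_reported(self):
        net = make_weighted_network([("a", "b", 1.0), ("c", "d", 1.0)])
        seeds = SeedSets(severe=["a"], benign=["b"])
        cfg = WalkConfig(n_walks_per_seed=5, walk_length=4, rng_seed=0)
        tally = run_walks(net, seeds, cfg)
        assert set(tally.unvisited) == {"c", "d"}

    def test_seed_not_in_network_is_error(self, triangle_network):
        seeds = SeedSets(severe=["zzz"], benign=["b"])
        with pytest.raises(ValueError, match="zzz"):
            run_walks(triangle_network, seeds, WalkConfig(1, 1, 0))

    def test_isolated_seed_is_error(self, triangle_network):
        triangle_network.graph.add_node("lonely")
        seeds = SeedSets(severe=["lonely"], benign=["b"])
        with pytest.raises(ValueError, match="lonely"):
            run_walks(triangle_network, seeds, WalkConfig(1, 1, 0))

    def test_reproducible(self, triangle_network):
        seeds = SeedSets(severe=["a"], benign=["c"])
        cfg = WalkConfig(n_walks_per_seed=50, walk_length=20, rng_seed=7)
        t1 = run_walks(triangle_network, seeds, cfg)
        t2 = run_walks(triangle_network, seeds, cfg)
        assert (t1.severe_walk_counts != t2.severe_walk_counts).nnz == 0
        assert (t1.benign_walk_counts != t2.benign_walk_counts).nnz == 0


class TestSaedrRaw:
    @pytest.mark.parametrize(
        "s,b,expected",
        [(100, 100, 0.5), (0, 7, 0.0), (7, 0, 1.0), (3, 1, 0.75)],
    )
    def test_examples(self, s, b, expected):
        assert saedr_raw(s, b) == expected

    def test_undefined_when_unvisited(self):
        with pytest.raises(ValueError):
            saedr_raw(0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            saedr_raw(-1, 2)

    @given(st.integers(1, 1000), st.integers(0, 1000), st.integers(1, 100))
    def test_monotone_decreasing_in_b(self, s, b, db):
        assert saedr_raw(s, b + db) < saedr_raw(s, b)

    @given(st.integers(0, 500), st.integers(0, 500))
    def test_matches_formula_grid(self, s, b):
        if s + b == 0:
            return
        assert saedr_raw(s, b) == s / (s + b)


class TestBootstrap:
    def test_identical_walks_degenerate(self):
        tally = make_tally("xyz", [[1, 2, 0]] * 4, [[0, 1, 3]] * 4)
        out = bootstrap_scores(tally, n_boot=50, rng_seed=1, return_interval=True)
        point = point_scores(tally)
        for node in point.index:
            assert out.loc[node, "bootstrap_mean"] == pytest.approx(point[node])
            assert out.loc[node, "ci_high"] - out.loc[node, "ci_low"] == 0.0

    def test_single_walk_each(self):
        tally = make_tally("xyz", [[2, 1, 0]], [[1, 0, 4]])
        boot = bootstrap_scores(tally, n_boot=25, rng_seed=0)
        point = point_scores(tally)
        for node in point.index:
            # every resample reproduces the single original walk pair
            assert boot[node] == pytest.approx(point[node], abs=1e-12)

    def test_exhaustive_enumeration_oracle(self):
        severe_rows = [[2, 0, 1], [0, 1, 0]]
        benign_rows = [[1, 1, 0], [0, 0, 2]]
        tally = make_tally("xyz", severe_rows, benign_rows)
        exact = exact_bootstrap_mean(severe_rows, benign_rows)
        n_boot = 4000
        boot = bootstrap_scores(tally, n_boot=n_boot, rng_seed=5, return_interval=True)
        for i, node in enumerate("xyz"):
            # bootstrap SE of the mean over iterations
            se = max(1e-6, float(boot.loc[node, "ci_high"] - boot.loc[node, "ci_low"]) / 4 / np.sqrt(n_boot))
            assert abs(boot.loc[node, "bootstrap_mean"] - exact[i]) <= 3 * se + 1e-9

    def test_nodes_missing_from_resamples_tracked(self):
        # node z visited only by one severe walk: sometimes absent
        tally = make_tally("xyz", [[1, 0, 1], [1, 1, 0]], [[1, 1, 0], [1, 0, 0]])
        out = bootstrap_scores(tally, n_boot=200, rng_seed=3, return_interval=True)
        assert out.loc["z", "n_contributing"] < 200
        assert out.loc["x", "n_contributing"] == 200

    def test_label_swap_antisymmetry_exact(self):
        rng = np.random.default_rng(8)
        nodes = [f"n{i}" for i in range(6)]
        severe = rng.integers(0, 5, size=(10, 6))
        benign = rng.integers(0, 5, size=(10, 6))
        tally = make_tally(nodes, severe, benign)
        swapped = tally.swapped()
        s, b = tally.s, tally.b
        for u in range(6):
            if s[u] + b[u] == 0:
                continue
            orig = Fraction(int(s[u]), int(s[u] + b[u]))
            swap = Fraction(int(swapped.s[u]), int(swapped.s[u] + swapped.b[u]))
            assert swap == 1 - orig  # exact, in rational arithmetic
        p, q = point_scores(tally), point_scores(swapped)
        for node in p.index:
            assert q[node] == pytest.approx(1 - p[node], abs=1e-15)


class TestAggregateAndNormalize:
    def lexicon(self, mapping):
        # lexicon whose records carry only term -> pt_id (vectors irrelevant)
        space = EmbeddingSpace(tokens=["tok"], vectors=np.ones((1, 2)), dim=2)
        table = pd.DataFrame(
            {"term": list(mapping), "tokens": ["tok"] * len(mapping), "pt_id": list(mapping.values())}
        )
        return build_lexicon(table, space)

    def test_minmax_on_two_points(self):
        lex = self.lexicon({"t1": "P1", "t2": "P2"})
        table = aggregate_and_normalize([pd.Series({"t1": 0.2, "t2": 0.6})], lex)
        assert table.per_pt.loc["P1", "score_normalized"] == 0.0
        assert table.per_pt.loc["P2", "score_normalized"] == 1.0

    def test_two_identical_runs_idempotent(self):
        lex = self.lexicon({"t1": "P1", "t2": "P2", "t3": "P3"})
        run = pd.Series({"t1": 0.1, "t2": 0.5, "t3": 0.9})
        table = aggregate_and_normalize([run, run.copy()], lex)
        np.testing.assert_allclose(table.per_pt["combined"], table.per_pt["run_0"])

    def test_cross_run_pt_mean_hand_computed(self):
        lex = self.lexicon({"t1": "P1", "t2": "P1", "t3": "P1"})
        run1 = pd.Series({"t1": 0.4, "t2": 0.8})
        run2 = pd.Series({"t3": 0.6})
        table = aggregate_and_normalize([run1, run2], lex)
        # run1 PT mean = 0.6, run2 PT mean = 0.6 -> combined 0.6
        assert table.per_pt.loc["P1", "combined"] == pytest.approx(0.6)

    def test_unscored_pt_absent(self):
        lex = self.lexicon({"t1": "P1", "t2": "P2"})
        table = aggregate_and_normalize([pd.Series({"t1": 0.3})], lex)
        assert "P2" not in table.per_pt.index

    def test_scores_within_unit_interval_and_extremes(self):
        rng = np.random.default_rng(4)
        mapping = {f"t{i}": f"P{i // 2}" for i in range(20)}
        lex = self.lexicon(mapping)
        run = pd.Series(rng.uniform(0.2, 0.9, size=20), index=list(mapping))
        table = aggregate_and_normalize([run], lex)
        col = table.per_pt["score_normalized"]
        assert col.min() == 0.0 and col.max() == 1.0
        assert ((col >= 0) & (col <= 1)).all()
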