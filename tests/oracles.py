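"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: enumeration, all-pairs computation,
matrix powers, rank transforms by hand.  Nothing imports the code paths it
checks.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def lcs_length(a: str, b: str) -> int:
    """Longest-common-subsequence length by full-table DP."""
    table = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                table[i][j] = table[i - 1][j - 1] + 1
            else:
                table[i][j] = max(table[i - 1][j], table[i][j - 1])
    return table[len(a)][len(b)]


def ratio_via_lcs(a: str, b: str) -> float:
    """Similarity ratio through the LCS identity: 2*LCS / (|a|+|b|).

    With substitution cost 2 the weighted edit distance equals
    |a|+|b| - 2*LCS, so (|a|+|b|-D)/(|a|+|b|) == 2*LCS/(|a|+|b|).
    """
    total = len(a) + len(b)
    if total == 0:
        return 1.0
    return 2 * lcs_length(a, b) / total


def brute_force_knn_edges(terms, vectors, k):
    """Union-of-neighborhoods k-NN edge dict {(u, v): cosine} by all pairs.

    Distance ties broken by lexicographic term order; non-positive
    similarities floored at 1e-8 to mirror the positivity rule.
    """
    n = len(terms)
    unit = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    sims = unit @ unit.T
    edges = {}
    for i in range(n):
        order = sorted(
            (j for j in range(n) if j != i),
            key=lambda j: (-sims[i, j], terms[j]),
        )
        for j in order[:k]:
            key = tuple(sorted((terms[i], terms[j])))
            edges[key] = max(float(sims[i, j]), 1e-8)
    return edges


def transition_matrix(graph, nodes):
    """Row-stochastic transition matrix from edge weights."""
    n = len(nodes)
    idx = {t: i for i, t in enumerate(nodes)}
    P = np.zeros((n, n))
    for u in nodes:
        total = sum(d["weight"] for d in graph[u].values())
        for v, d in graph[u].items():
            P[idx[u], idx[v]] = d["weight"] / total
    return P


def expected_visits(P: np.ndarray, seed_idx: int, length: int) -> np.ndarray:
    """Expected visits per node over one walk: sum_{t=1..L} (P^t)[seed, :]."""
    out = np.zeros(P.shape[0])
    row = np.zeros(P.shape[0])
    row[seed_idx] = 1.0
    for _ in range(length):
        row = row @ P
        out += row
    return out


def visit_step_probabilities(P: np.ndarray, seed_idx: int, length: int) -> np.ndarray:
    """(L, n) matrix of per-step occupation probabilities p_t."""
    probs = np.zeros((length, P.shape[0]))
    row = np.zeros(P.shape[0])
    row[seed_idx] = 1.0
    for t in range(length):
        row = row @ P
        probs[t] = row
    return probs


def binomial_visit_se(P: np.ndarray, seed_idx: int, length: int, n_walks: int) -> np.ndarray:
    """sqrt(n * sum_t p_t (1 - p_t)) per node."""
    probs = visit_step_probabilities(P, seed_idx, length)
    return np.sqrt(n_walks * (probs * (1 - probs)).sum(axis=0))


def exact_bootstrap_mean(severe_rows, benign_rows):
    """Expected bootstrap-mean score per node by exhaustive enumeration.

    Rows are per-walk visit-count vectors.  Enumerates every multinomial
    resample-count outcome within each polarity (sizes preserved), weights
    by its probability, scores s/(s+b) in exact rational arithmetic, and
    averages over outcomes where the node is visited (mean over
    contributing outcomes, matching the documented bootstrap convention).
    """
    from itertools import product
    from math import comb, factorial

    severe_rows = [np.asarray(r, dtype=int) for r in severe_rows]
    benign_rows = [np.asarray(r, dtype=int) for r in benign_rows]
    n_nodes = len(severe_rows[0])

    def outcomes(rows):
        n = len(rows)
        # all count vectors (c_1..c_n) with sum n
        def rec(i, remaining):
            if i == n - 1:
                yield (remaining,)
                return
            for c in range(remaining + 1):
                for rest in rec(i + 1, remaining - c):
                    yield (c, *rest)
        result = []
        for counts in rec(0, n):
            w = factorial(n)
            for c in counts:
                w //= factorial(c)
            prob = Fraction(w, n**n)
            tot = np.zeros(n_nodes, dtype=int)
            for c, row in zip(counts, rows):
                tot += c * row
            result.append((prob, tot))
        return result

    sev_out = outcomes(severe_rows)
    ben_out = outcomes(benign_rows)
    num = [Fraction(0)] * n_nodes
    den = [Fraction(0)] * n_nodes
    for ps, s in sev_out:
        for pb, b in ben_out:
            p = ps * pb
            for u in range(n_nodes):
                tot = int(s[u]) + int(b[u])
                if tot > 0:
                    num[u] += p * Fraction(int(s[u]), tot)
                    den[u] += p
    return np.array([float(n / d) if d > 0 else np.nan for n, d in zip(num, den)])


def spearman_by_hand(x, y):
    """Spearman rho as Pearson correlation of average ranks."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def permutation_pvalue_greater(a, b, n_perm=20000, seed=0):
    """One-sided permutation test p-value for mean(a) > mean(b)."""
    rng = np.random.default_rng(seed)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    observed = a.mean() - b.mean()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if perm[: len(a)].mean() - perm[len(a):].mean() >= observed:
            count += 1
    return (count + 1) / (n_perm + 1)


def tabulate_outcomes_brute(cases):
    """Per-ADR outcome tabulation by direct per-case enumeration.

    ``cases`` are (case_id, reactions, outcomes) triples already
    normalized; returns {adr: {category: count, 'n_cases': int}} using the
    published code->category schema, restated here independently.
    """
    schema = {
        "death": "Death",
        "life-threatening": "Serious Outcome",
        "hospitalization": "Serious Outcome",
        "other serious": "Serious Outcome",
        "required intervention": "Serious Outcome",
        "congenital anomaly": "Disability",
        "disability": "Disability",
    }
    table: dict[str, dict[str, int]] = {}
    for _cid, reactions, outcomes in cases:
        if outcomes:
            cats = {schema[o.lower()] for o in outcomes if o.lower() in schema}
        else:
            cats = {"No Outcome"}
        for adr in set(reactions):
            row = table.setdefault(adr, {"n_cases": 0, "Death": 0, "Serious Outcome": 0,
                                         "Disability": 0, "No Outcome": 0})
            row["n_cases"] += 1
            for c in cats:
                row[c] += 1
    return table
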