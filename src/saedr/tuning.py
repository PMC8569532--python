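"""Hyperparameter grid search and validation statistics.

Grid search spans the network neighbor count k and the seed percentage;
each cell builds the network, seeds from the extremes of a training
ranking, propagates, and scores the result by Spearman correlation with
the training ranks.  Also houses the train/test split and the thin
rank-correlation / one-sided t-test utilities used for validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from saedr.embedding_lexicon import Lexicon
from saedr.lexical_network import build_knn_network
from saedr.seed_selection import RankedTerms, make_seed_sets
from saedr.severity_propagation import WalkConfig, point_scores, run_walks

logger = logging.getLogger(__name__)

#: published grid
DEFAULT_K_VALUES = (2, 5, 10, 15, 20, 25, 30)
DEFAULT_PCT_VALUES = (2.0, 5.0, 10.0, 15.0, 20.0, 25.0)
DEFAULT_SPLIT = 0.75


@dataclass
class TuningGrid:
    k_values: tuple[int, ...] = DEFAULT_K_VALUES
    pct_values: tuple[float, ...] = DEFAULT_PCT_VALUES
    split_fraction: float = DEFAULT_SPLIT

    def __post_init__(self) -> None:
        if not self.k_values or not self.pct_values:
            raise ValueError("grid value sets must be non-empty")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")

    def cells(self) -> list[tuple[int, float]]:
        """Cartesian product of k and pct values, in deterministic order."""
        return [(k, pct) for k in self.k_values for pct in self.pct_values]


@dataclass
class TuningResult:
    table: pd.DataFrame  # columns k, pct, rho, p, n_terms, status
    best_config: Optional[tuple[int, float]]

    def best_row(self) -> pd.Series:
        k, pct = self.best_config
        mask = (self.table["k"] == k) & (self.table["pct"] == pct)
        return self.table.loc[mask].iloc[0]


def split_ranking(
    ranking: RankedTerms,
    fraction: float,
    rng_seed: int,
    mappable: Optional[Sequence[str]] = None,
) -> tuple[RankedTerms, RankedTerms, int]:
    """Random train/test partition of a ranked list, preserving rank scores.

    Terms not mappable to the network (when ``mappable`` is given) are
    dropped first and counted; returns (train, test, n_dropped).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    base = ranking if mappable is None else ranking.restrict(mappable)
    n_dropped = len(ranking) - len(base)
    if n_dropped:
        logger.info("split_ranking: %d unmappable terms dropped", n_dropped)
    n = len(base)
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    n_train = int(round(n * fraction))
    train_pos = np.sort(perm[:n_train])
    test_pos = np.sort(perm[n_train:])

    def take(pos: np.ndarray) -> RankedTerms:
        return RankedTerms(
            terms=[base.terms[i] for i in pos],
            scores=[base.scores[i] for i in pos] if base.scores is not None else None,
            source_id=base.source_id,
        )

    return take(train_pos), take(test_pos), n_dropped


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("rank_correlation needs equal-length inputs of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank_correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def compare_groups(
    scores_a: Sequence[float], scores_b: Sequence[float], direction: str = "a_greater"
) -> tuple[float, float, tuple[float, float]]:
    """One-sided two-sample t-test (Welch); returns (t, p, medians).

    ``direction="a_greater"`` tests the alternative mean(a) > mean(b).
    Zero-variance inputs yield t=+/-inf (p 0 or 1) per scipy convention;
    identical zero-variance groups yield t=nan with p reported as 0.5.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("compare_groups needs at least 2 values per group")
    if direction != "a_greater":
        raise ValueError("direction must be 'a_greater' (swap arguments otherwise)")
    t, p = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    if np.isnan(t):  # both groups constant and equal
        t, p = 0.0, 0.5
    return float(t), float(p), (float(np.median(a)), float(np.median(b)))


def _train_scores_for_correlation(train: RankedTerms) -> dict[str, float]:
    """Severity value per train term: supplied score, else reversed rank."""
    if train.scores is not None:
        return dict(zip(train.terms, train.scores))
    n = len(train.terms)
    return {t: float(n - i) for i, t in enumerate(train.terms)}


def evaluate_config(
    lexicon: Lexicon,
    train: RankedTerms,
    k: int,
    pct: float,
    cfg: WalkConfig,
) -> tuple[float, float, int]:
    """Propagate with one (k, pct) configuration and score against train.

    Returns (rho, p, n_terms_correlated).
    """
    network = build_knn_network(lexicon, k=k)
    seeds = make_seed_sets(train, train.reversed(), pct, network.nodes)
    tally = run_walks(network, seeds, cfg)
    scores = point_scores(tally)
    ref = _train_scores_for_correlation(train)
    common = [t for t in scores.index if t in ref]
    if len(common) < 3:
        raise ValueError("fewer than 3 train terms received scores")
    rho, p = rank_correlation([scores[t] for t in common], [ref[t] for t in common])
    return rho, p, len(common)


def grid_search(
    lexicon: Lexicon,
    train: RankedTerms,
    grid: TuningGrid,
    cfg: WalkConfig,
) -> TuningResult:
    """Exhaustive search over the (k, pct) grid.

    Each cell uses a fresh rng substream derived from (rng_seed, k, pct)
    so cells are independent of enumeration order.  Infeasible cells are
    recorded as failed and excluded from the argmax; ties are broken by
    smaller k then smaller pct.
    """
    if not train.terms:
        raise ValueError("empty training ranking")
    rows = []
    for k, pct in grid.cells():
        sub = np.random.SeedSequence([cfg.rng_seed, int(k), int(round(pct * 1000))])
        cell_cfg = WalkConfig(
            n_walks_per_seed=cfg.n_walks_per_seed,
            walk_length=cfg.walk_length,
            rng_seed=int(sub.generate_state(1)[0]),
            self_visit_exclusion=cfg.self_visit_exclusion,
        )
        try:
            rho, p, n_terms = evaluate_config(lexicon, train, k, pct, cell_cfg)
            rows.append({"k": k, "pct": pct, "rho": rho, "p": p, "n_terms": n_terms, "status": "ok"})
        except ValueError as exc:
            logger.warning("grid cell (k=%d, pct=%g) failed: %s", k, pct, exc)
            rows.append({"k": k, "pct": pct, "rho": np.nan, "p": np.nan, "n_terms": 0, "status": f"failed: {exc}"})
    table = pd.DataFrame(rows, columns=["k", "pct", "rho", "p", "n_terms", "status"])
    ok = table.loc[table["status"] == "ok"]
    if ok.empty:
        return TuningResult(table=table, best_config=None)
    # argmax rho; ties -> smaller k, then smaller pct
    best = ok.sort_values(["rho", "k", "pct"], ascending=[False, True, True]).iloc[0]
    return TuningResult(table=table, best_config=(int(best["k"]), float(best["pct"])))
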