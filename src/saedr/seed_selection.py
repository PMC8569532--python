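"""Severe/benign seed list construction from a ranked severity source.

Ranked term lists (crowdworker-style or outcome-derived) are filtered for
lexical near-duplicates with an indel similarity ratio, restricted to
network nodes, and truncated to equal length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class RankedTerms:
    """Terms ordered most-extreme first, with optional aligned scores."""

    terms: list[str]
    scores: Optional[list[float]] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("ranked term list contains duplicates")
        if self.scores is not None and len(self.scores) != len(self.terms):
            raise ValueError("scores must align with terms")

    def __len__(self) -> int:
        return len(self.terms)

    def head(self, n: int) -> "RankedTerms":
        return RankedTerms(
            terms=self.terms[:n],
            scores=self.scores[:n] if self.scores is not None else None,
            source_id=self.source_id,
        )

    def restrict(self, allowed: Iterable[str]) -> "RankedTerms":
        allowed = set(allowed)
        keep = [i for i, t in enumerate(self.terms) if t in allowed]
        return RankedTerms(
            terms=[self.terms[i] for i in keep],
            scores=[self.scores[i] for i in keep] if self.scores is not None else None,
            source_id=self.source_id,
        )

    def reversed(self) -> "RankedTerms":
        return RankedTerms(
            terms=list(reversed(self.terms)),
            scores=list(reversed(self.scores)) if self.scores is not None else None,
            source_id=self.source_id,
        )


@dataclass
class SeedSets:
    """Equal-length severe and benign seed lists after lexical filtering."""

    severe: list[str]
    benign: list[str]
    source_id: str = ""
    pct: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.severe) != len(self.benign):
            raise ValueError("severe and benign seed lists must have equal length")
        if set(self.severe) & set(self.benign):
            raise ValueError("severe and benign seed lists overlap")

    @property
    def all_seeds(self) -> list[str]:
        return self.severe + self.benign


def indel_similarity(a: str, b: str) -> float:
    """Similarity ratio (|a|+|b| - D(a,b)) / (|a|+|b|).

    D is edit distance with insert/delete cost 1 and substitution cost 2,
    so the value matches the classic Levenshtein ``ratio`` function.
    Returns 1.0 for two empty strings by convention.
    """
    total = len(a) + len(b)
    if total == 0:
        return 1.0
    return (total - _weighted_edit_distance(a, b)) / total


def _weighted_edit_distance(a: str, b: str) -> int:
    """Edit distance with indel cost 1 and substitution cost 2 (two-row DP)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    # with substitution cost 2 the distance equals |a|+|b| - 2*LCS, but the
    # DP is kept explicit so it stays the definition, not a derived identity
    for i in range(1, len(a) + 1):
        cur = [i] + [0] * len(b)
        for j in range(1, len(b) + 1):
            sub = prev[j - 1] + (0 if a[i - 1] == b[j - 1] else 2)
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, sub)
        prev = cur
    return prev[len(b)]


def filter_lexically_distinct(ranked: RankedTerms, threshold: float = 0.5) -> RankedTerms:
    """Drop terms lexically close to any higher-ranking kept term.

    Greedy scan in rank order: a term is kept iff its indel similarity to
    every previously kept term is <= threshold.  Output preserves order and
    is a subsequence of the input.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    kept_idx: list[int] = []
    kept_terms: list[str] = []
    for i, term in enumerate(ranked.terms):
        if all(indel_similarity(term, prev) <= threshold for prev in kept_terms):
            kept_idx.append(i)
            kept_terms.append(term)
        else:
            logger.debug("seed filter dropped near-duplicate term %r", term)
    return RankedTerms(
        terms=kept_terms,
        scores=[ranked.scores[i] for i in kept_idx] if ranked.scores is not None else None,
        source_id=ranked.source_id,
    )


def rank_from_outcomes(outcomes, use_proportions: bool = False) -> RankedTerms:
    """Rank ADRs by their marginal association with death-or-serious outcomes.

    The per-ADR statistic is the number of death-or-serious cases containing
    the ADR divided by the number of death-or-serious cases not containing
    it (raw counts; set ``use_proportions`` to divide each count by the
    respective group size instead).  A zero denominator yields +inf and the
    term is placed first.

    Parameters
    ----------
    outcomes : OutcomeTable
        Per-ADR outcome tallies from :mod:`saedr.faers_outcomes`.
    """
    stats: dict[str, float] = {}
    total_ds = outcomes.n_death_or_serious_total
    total_cases = outcomes.n_cases_total
    for adr, row in outcomes.per_adr.items():
        with_adr = row["n_death_or_serious"]
        without_adr = total_ds - with_adr
        if use_proportions:
            n_with = row["n_cases"]
            n_without = total_cases - n_with
            num = with_adr / n_with if n_with else 0.0
            den = without_adr / n_without if n_without else 0.0
        else:
            num, den = float(with_adr), float(without_adr)
        if den == 0:
            stat = math.inf if num > 0 else 0.0
            if num > 0:
                logger.warning("ADR %r: zero denominator, statistic set to +inf", adr)
        else:
            stat = num / den
        stats[adr] = stat

    # descending statistic = most severe first; ties broken alphabetically
    ordered = sorted(stats, key=lambda t: (-stats[t], t))
    return RankedTerms(
        terms=ordered,
        scores=[stats[t] for t in ordered],
        source_id="outcome-ranking",
    )


def make_seed_sets(
    severe_ranked: RankedTerms,
    benign_ranked: RankedTerms,
    pct: float,
    network_nodes: Iterable[str],
    threshold: float = 0.5,
    pct_basis: str = "ranked_list",
) -> SeedSets:
    """Build equal-length severe/benign seed sets from ranked extremes.

    Takes the top ``pct`` percent of each ranked list (restricted to terms
    present as network nodes), filters lexical near-duplicates, then
    truncates both lists to the shorter length.
    """
    if not 0 < pct < 50:
        raise ValueError(f"pct must be in (0, 50), got {pct}")
    if pct_basis not in ("ranked_list", "network_nodes"):
        raise ValueError(f"unknown pct_basis {pct_basis!r}")
    nodes = set(network_nodes)

    def prepare(ranked: RankedTerms, label: str) -> RankedTerms:
        mapped = ranked.restrict(nodes)
        dropped = len(ranked) - len(mapped)
        if dropped:
            logger.info("%s seeds: %d ranked terms absent from the network, dropped", label, dropped)
        basis = len(mapped) if pct_basis == "ranked_list" else len(nodes)
        n_take = max(1, int(round(basis * pct / 100.0)))
        return filter_lexically_distinct(mapped.head(n_take), threshold=threshold)

    severe = prepare(severe_ranked, "severe")
    benign = prepare(benign_ranked, "benign")
    if not severe.terms or not benign.terms:
        raise ValueError("a post-filter seed list is empty; increase pct or check inputs")

    # exclude any term claimed by both extremes (kept on the severe side
    # would bias; drop from both for symmetry)
    overlap = set(severe.terms) & set(benign.terms)
    if overlap:
        logger.warning("%d terms in both seed extremes, dropped from both", len(overlap))
        severe = RankedTerms([t for t in severe.terms if t not in overlap], source_id=severe.source_id)
        benign = RankedTerms([t for t in benign.terms if t not in overlap], source_id=benign.source_id)

    n = min(len(severe.terms), len(benign.terms))
    if n == 0:
        raise ValueError("seed lists empty after overlap removal")
    source_id = severe_ranked.source_id or benign_ranked.source_id
    return SeedSets(severe=severe.terms[:n], benign=benign.terms[:n], source_id=source_id, pct=pct)


def read_ranked_terms(path: str | Path, source_id: str = "") -> RankedTerms:
    """Read a ranked severity list TSV with columns term[, score].

    If a ``score`` column is present the rows are sorted descending by
    score (most severe first); otherwise file order is taken as the rank.
    """
    df = pd.read_csv(path, sep="\t", dtype={"term": str})
    if "term" not in df.columns:
        raise ValueError("ranked term file needs a 'term' column")
    df["term"] = df["term"].str.lower().str.strip()
    if "score" in df.columns:
        df = df.sort_values("score", ascending=False, kind="stable")
        return RankedTerms(
            terms=df["term"].tolist(),
            scores=[float(x) for x in df["score"]],
            source_id=source_id or str(path),
        )
    return RankedTerms(terms=df["term"].tolist(), source_id=source_id or str(path))


def write_seed_sets(seeds: SeedSets, path: str | Path) -> None:
    rows = []
    for rank, term in enumerate(seeds.severe, start=1):
        rows.append({"term": term, "polarity": "severe", "rank": rank, "source_id": seeds.source_id})
    for rank, term in enumerate(seeds.benign, start=1):
        rows.append({"term": term, "polarity": "benign", "rank": rank, "source_id": seeds.source_id})
    pd.DataFrame(rows, columns=["term", "polarity", "rank", "source_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_seed_sets(path: str | Path) -> SeedSets:
    df = pd.read_csv(path, sep="\t", dtype={"term": str, "polarity": str})
    severe = df.loc[df["polarity"] == "severe"].sort_values("rank")["term"].tolist()
    benign = df.loc[df["polarity"] == "benign"].sort_values("rank")["term"].tolist()
    source = str(df["source_id"].iloc[0]) if "source_id" in df.columns and len(df) else ""
    return SeedSets(severe=severe, benign=benign, source_id=source)
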