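"""Word embeddings, phrase vectors, and the ADR term lexicon.

The embedding input is word2vec-style text: an optional ``<count> <dim>``
header line followed by one ``token v1 ... vd`` row per token.  ADR terms
(lowest-level-term granularity) arrive as a TSV with a precomputed
tokenization and a preferred-term group id; a multi-token phrase is
represented by the arithmetic mean of its in-vocabulary token vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TERM_TABLE_COLUMNS = ("term", "tokens", "pt_id")


@dataclass
class EmbeddingSpace:
    """Token -> dense vector map of fixed dimensionality."""

    tokens: list[str]
    vectors: np.ndarray  # shape (n_tokens, dim)
    dim: int
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {t: i for i, t in enumerate(self.tokens)}

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __len__(self) -> int:
        return len(self.tokens)

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self._index[token]]


@dataclass
class TermRecord:
    """One ADR term: surface string, tokenization, PT group, optional vector.

    ``vector`` is present iff at least one token is in-vocabulary.
    """

    term: str
    tokens: list[str]
    pt_id: str
    vector: Optional[np.ndarray] = None

    @property
    def has_vector(self) -> bool:
        return self.vector is not None


@dataclass
class Lexicon:
    """All ADR term records plus vocabulary-coverage bookkeeping.

    ``coverage`` is the fraction of input terms that received a vector;
    0.0 by convention for an empty term table.
    """

    records: list[TermRecord]
    coverage: float

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def embedded(self) -> list[TermRecord]:
        return [r for r in self.records if r.has_vector]

    @property
    def terms(self) -> list[str]:
        return [r.term for r in self.records]

    def pt_map(self) -> dict[str, str]:
        return {r.term: r.pt_id for r in self.records}

    def record(self, term: str) -> TermRecord:
        for r in self.records:
            if r.term == term:
                return r
        raise KeyError(term)


def load_embeddings(path: str | Path, format_id: str = "word2vec-text") -> EmbeddingSpace:
    """Load a word2vec-style text embedding file.

    Rows with the wrong field count raise ``ValueError`` naming the line;
    duplicate tokens keep the first occurrence with a warning; all-zero
    vectors are rejected with a warning.  Tokens are lowercased.
    """
    if format_id != "word2vec-text":
        raise ValueError(f"unsupported embedding format: {format_id!r}")
    path = Path(path)
    tokens: list[str] = []
    rows: list[np.ndarray] = []
    index: dict[str, int] = {}
    dim: Optional[int] = None
    declared_dim: Optional[int] = None

    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2:
                # optional "<count> <dim>" header
                try:
                    int(parts[0])
                    declared_dim = int(parts[1])
                    continue
                except ValueError:
                    pass
            token = parts[0].lower()
            try:
                vec = np.asarray([float(x) for x in parts[1:]], dtype=np.float64)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
            if dim is None:
                dim = declared_dim if declared_dim is not None else vec.size
            if vec.size != dim:
                raise ValueError(
                    f"{path}: malformed row at line {lineno}: expected {dim} values, got {vec.size}"
                )
            if token in index:
                logger.warning("duplicate token %r at line %d: keeping first", token, lineno)
                continue
            if not np.any(vec):
                logger.warning("all-zero vector for token %r at line %d: rejected", token, lineno)
                continue
            index[token] = len(tokens)
            tokens.append(token)
            rows.append(vec)

    if dim is None:
        raise ValueError(f"{path}: no embedding rows found")
    vectors = np.vstack(rows) if rows else np.empty((0, dim))
    return EmbeddingSpace(tokens=tokens, vectors=vectors, dim=dim, _index=index)


def phrase_vector(tokens: Sequence[str], space: EmbeddingSpace) -> Optional[np.ndarray]:
    """Mean vector of the in-vocabulary tokens of a phrase; None if all OOV.

    Out-of-vocabulary tokens are skipped so partially covered phrases still
    get a representation.
    """
    if not tokens:
        raise ValueError("phrase_vector requires a non-empty token list")
    present = [t for t in tokens if t in space]
    if not present:
        return None
    if len(present) == 1:
        # bit-identical to the stored vector for single-token phrases
        return space.vector(present[0]).copy()
    return np.mean([space.vector(t) for t in present], axis=0)


def read_term_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV term table with columns term, tokens (pipe-separated), pt_id."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(TERM_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"term table missing required column(s): {sorted(missing)}")
    return df


def build_lexicon(term_table: pd.DataFrame, space: EmbeddingSpace) -> Lexicon:
    """Resolve every term-table row into a TermRecord with an optional vector.

    Terms without any in-vocabulary token are retained but flagged absent
    (they are excluded from the network downstream).  Terms and tokens are
    lowercased; ``tokens`` column is pipe-separated.
    """
    missing = set(TERM_TABLE_COLUMNS) - set(term_table.columns)
    if missing:
        raise ValueError(f"term table missing required column(s): {sorted(missing)}")

    records: list[TermRecord] = []
    n_embedded = 0
    for row in term_table.itertuples(index=False):
        term = str(row.term).lower().strip()
        toks = [t for t in str(row.tokens).lower().split("|") if t]
        if not toks:
            toks = term.split()
        pt_id = str(row.pt_id).strip()
        if not pt_id:
            raise ValueError(f"term {term!r} has empty pt_id")
        vec = phrase_vector(toks, space) if toks else None
        if vec is not None:
            n_embedded += 1
        records.append(TermRecord(term=term, tokens=toks, pt_id=pt_id, vector=vec))

    coverage = n_embedded / len(records) if records else 0.0
    logger.info(
        "lexicon: %d terms, %d with vectors (coverage %.2f%%)",
        len(records), n_embedded, 100 * coverage,
    )
    return Lexicon(records=records, coverage=coverage)


def write_embeddings(path: str | Path, space: EmbeddingSpace) -> None:
    """Write an EmbeddingSpace in word2vec text format (with header)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(space.tokens)} {space.dim}\n")
        for tok, vec in zip(space.tokens, space.vectors):
            fh.write(tok + " " + " ".join(f"{v:.8g}" for v in vec) + "\n")
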