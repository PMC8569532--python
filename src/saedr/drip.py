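"""Per-drug risk (DRIP) scores from severities and label ADR frequencies.

A drug's DRIP score is the sum over its label ADRs of severity times
frequency.  Frequencies reported as a range are sampled uniformly within
the range; missing frequencies are sampled uniformly on [0.001, 0.01];
the score is averaged over repeated joint draws (default 1000).
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_FREQ_LOW = 0.001
MISSING_FREQ_HIGH = 0.01


@dataclass
class LabelFrequencyRecord:
    """One drug-label ADR frequency annotation."""

    drug_id: str
    adr_pt: str
    freq_kind: str  # point | range | missing
    freq_point: Optional[float] = None
    freq_min: Optional[float] = None
    freq_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.freq_kind not in ("point", "range", "missing"):
            raise ValueError(f"unknown freq_kind {self.freq_kind!r}")
        if self.freq_kind == "point":
            if self.freq_point is None or not 0 <= self.freq_point <= 1:
                raise ValueError(f"point record needs freq_point in [0,1]: {self}")
        if self.freq_kind == "range":
            if (
                self.freq_min is None or self.freq_max is None
                or not 0 <= self.freq_min <= self.freq_max <= 1
            ):
                raise ValueError(f"range record needs 0 <= freq_min <= freq_max <= 1: {self}")


@dataclass
class DripTable:
    """Per-drug DRIP means with sampling spread."""

    table: pd.DataFrame  # index drug_id; drip_mean, drip_q05, drip_q95, n_adrs_scored, n_adrs_skipped
    n_samples: int

    def score(self, drug_id: str) -> float:
        return float(self.table.loc[drug_id, "drip_mean"])


def sample_frequency(rec: LabelFrequencyRecord, rng: np.random.Generator) -> float:
    """Draw one frequency estimate for a label record."""
    if rec.freq_kind == "point":
        return float(rec.freq_point)
    if rec.freq_kind == "range":
        return float(rng.uniform(rec.freq_min, rec.freq_max))
    return float(rng.uniform(MISSING_FREQ_LOW, MISSING_FREQ_HIGH))


def _sample_matrix(recs: Sequence[LabelFrequencyRecord], n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """(n_samples, n_recs) independent frequency draws, one column per ADR."""
    cols = []
    for rec in recs:
        if rec.freq_kind == "point":
            cols.append(np.full(n_samples, rec.freq_point))
        elif rec.freq_kind == "range":
            cols.append(rng.uniform(rec.freq_min, rec.freq_max, size=n_samples))
        else:
            cols.append(rng.uniform(MISSING_FREQ_LOW, MISSING_FREQ_HIGH, size=n_samples))
    return np.column_stack(cols)


def drip_score(
    records: Sequence[LabelFrequencyRecord],
    severities: Mapping[str, float],
    n_samples: int = 1000,
    rng_seed: int = 0,
) -> Optional[dict]:
    """DRIP row for one drug: mean over joint frequency draws.

    ADRs whose preferred term has no severity score are skipped and
    counted.  Returns None (logged) when nothing is scoreable.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    scored = [r for r in records if r.adr_pt in severities]
    skipped = len(records) - len(scored)
    if skipped:
        logger.debug("%d label ADRs without severity scores skipped", skipped)
    if not scored:
        if records:
            logger.warning("drug %r: no scoreable ADRs", records[0].drug_id)
        return None
    rng = np.random.default_rng(rng_seed)
    sev = np.array([severities[r.adr_pt] for r in scored])
    freqs = _sample_matrix(scored, n_samples, rng)
    samples = freqs @ sev  # per-draw sum of severity * frequency
    return {
        "drip_mean": float(samples.mean()),
        "drip_q05": float(np.quantile(samples, 0.05)),
        "drip_q95": float(np.quantile(samples, 0.95)),
        "n_adrs_scored": len(scored),
        "n_adrs_skipped": skipped,
    }


def drip_table(
    records: Iterable[LabelFrequencyRecord],
    severities: Mapping[str, float],
    n_samples: int = 1000,
    rng_seed: int = 0,
) -> DripTable:
    """Compute DRIP rows for every drug in a label-frequency record set.

    Each drug gets its own rng substream derived from (rng_seed, drug_id)
    so results do not depend on table ordering.
    """
    by_drug: dict[str, list[LabelFrequencyRecord]] = {}
    for rec in records:
        by_drug.setdefault(rec.drug_id, []).append(rec)
    rows = {}
    for drug_id in sorted(by_drug):
        digest = hashlib.blake2s(drug_id.encode("utf-8"), digest_size=8).digest()
        ss = np.random.SeedSequence([rng_seed, int.from_bytes(digest, "big")])
        row = drip_score(
            by_drug[drug_id], severities, n_samples=n_samples,
            rng_seed=int(ss.generate_state(1)[0]),
        )
        if row is not None:
            rows[drug_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "drug_id"
    return DripTable(table=df.sort_index(), n_samples=n_samples)


def group_drip(drip: DripTable, grouping: Mapping[str, str]) -> pd.DataFrame:
    """Per-group median/quartile summaries of DRIP scores.

    ``grouping`` maps drug_id -> group label; drugs without a group are
    summarized under "__ungrouped__".
    """
    df = drip.table.copy()
    if df.empty:
        raise ValueError("empty DRIP table")
    df["group"] = [grouping.get(d, "__ungrouped__") for d in df.index]
    if not set(grouping) & set(df.index):
        raise ValueError("grouping covers no scored drug")
    out = df.groupby("group")["drip_mean"].agg(
        n="count", median="median",
        q25=lambda s: s.quantile(0.25),
        q75=lambda s: s.quantile(0.75),
    )
    out.index.name = "group"
    return out


def read_label_frequencies(path: str | Path) -> list[LabelFrequencyRecord]:
    """Read a frequency TSV: drug_id, adr_pt, freq_point, freq_min, freq_max.

    Blank frequency fields mean "missing"; a row with only freq_point is a
    point record; a row with freq_min/freq_max is a range record.
    """
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "adr_pt": str})
    required = {"drug_id", "adr_pt"}
    if missing := required - set(df.columns):
        raise ValueError(f"frequency table missing column(s): {sorted(missing)}")
    records: list[LabelFrequencyRecord] = []
    for row in df.itertuples(index=False):
        point = getattr(row, "freq_point", None)
        fmin = getattr(row, "freq_min", None)
        fmax = getattr(row, "freq_max", None)
        point = None if point is None or (isinstance(point, float) and math.isnan(point)) else float(point)
        fmin = None if fmin is None or (isinstance(fmin, float) and math.isnan(fmin)) else float(fmin)
        fmax = None if fmax is None or (isinstance(fmax, float) and math.isnan(fmax)) else float(fmax)
        if point is not None:
            kind = "point"
        elif fmin is not None and fmax is not None:
            kind = "range"
        else:
            kind = "missing"
        records.append(
            LabelFrequencyRecord(
                drug_id=str(row.drug_id), adr_pt=str(row.adr_pt), freq_kind=kind,
                freq_point=point, freq_min=fmin, freq_max=fmax,
            )
        )
    return records


def write_drip_table(drip: DripTable, path: str | Path) -> None:
    drip.table.reset_index().to_csv(path, sep="\t", index=False)
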