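"""Adverse-event case normalization and per-ADR outcome proportions.

Cases arrive as JSON-lines (one case per line) with fields case_id,
is_duplicate, country, reactions, outcomes.  Normalization removes
duplicate case IDs and cases outside the configured country; raw outcome
codes map onto the categories Death, Serious Outcome, Disability and
No Outcome (empty outcome list).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: raw outcome code -> normalized category
OUTCOME_SCHEMA: dict[str, str] = {
    "Death": "Death",
    "Life-Threatening": "Serious Outcome",
    "Hospitalization": "Serious Outcome",
    "Other Serious": "Serious Outcome",
    "Required Intervention": "Serious Outcome",
    "Congenital Anomaly": "Disability",
    "Disability": "Disability",
}

CATEGORIES = ("Death", "Serious Outcome", "Disability", "No Outcome")

_SCHEMA_LOWER = {k.lower(): v for k, v in OUTCOME_SCHEMA.items()}


@dataclass
class CaseRecord:
    """One adverse-event case report."""

    case_id: str
    is_duplicate: bool
    country: str
    reactions: list[str]
    outcomes: list[str]


@dataclass
class OutcomeTable:
    """Per-ADR outcome tallies over a normalized case set.

    ``per_adr`` maps each ADR term to a dict with keys n_cases, n_death,
    n_serious, n_disability, n_none, n_death_or_serious and the matching
    p_* proportions (category count / cases reporting the ADR).  A case
    with several raw outcomes contributes once to each mapped category, so
    proportions can sum above 1.
    """

    per_adr: dict[str, dict]
    n_cases_total: int
    n_death_or_serious_total: int
    min_reports: int = 0

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "n_cases",
            "n_death", "p_death",
            "n_serious", "p_serious",
            "n_disability", "p_disability",
            "n_none", "p_none",
            "n_death_or_serious",
        ]
        df = pd.DataFrame.from_dict(self.per_adr, orient="index")[cols]
        df.index.name = "adr_term"
        return df.sort_index()

    def filtered(self, min_reports: Optional[int] = None) -> pd.DataFrame:
        n = self.min_reports if min_reports is None else min_reports
        df = self.to_frame()
        return df.loc[df["n_cases"] >= n]


def map_outcome(raw_code: str) -> str:
    """Normalize a raw outcome code to its category.

    Unknown codes return "Unmapped" (logged); they are excluded from
    proportions.
    """
    cat = _SCHEMA_LOWER.get(raw_code.strip().lower())
    if cat is None:
        logger.warning("unknown outcome code %r mapped to 'Unmapped'", raw_code)
        return "Unmapped"
    return cat


def case_categories(outcomes: Sequence[str]) -> set[str]:
    """Set of normalized categories for one case's raw outcome list."""
    if not outcomes:
        return {"No Outcome"}
    cats = {map_outcome(code) for code in outcomes}
    cats.discard("Unmapped")
    if not cats:
        return set()  # only unmappable codes: excluded from proportions
    return cats


def normalize_cases(
    raw: Iterable[CaseRecord],
    country_filter: str = "US",
    lexicon_terms: Optional[Iterable[str]] = None,
) -> list[CaseRecord]:
    """Deduplicate and geography-filter case records.

    Records flagged duplicate or sharing an already-seen case_id are
    dropped (first occurrence kept); cases whose country differs from
    ``country_filter`` are dropped.  Reaction terms are lowercased; if a
    lexicon term set is supplied, unmapped reactions are logged but kept.
    """
    known = set(t.lower() for t in lexicon_terms) if lexicon_terms is not None else None
    seen: set[str] = set()
    kept: list[CaseRecord] = []
    n_dup = n_geo = n_bad = n_unmapped = 0
    for rec in raw:
        if not rec.case_id:
            logger.warning("record without case_id rejected")
            n_bad += 1
            continue
        if rec.is_duplicate or rec.case_id in seen:
            n_dup += 1
            continue
        seen.add(rec.case_id)
        if rec.country != country_filter:
            n_geo += 1
            continue
        reactions = [r.lower().strip() for r in rec.reactions if r.strip()]
        if not reactions:
            n_bad += 1
            continue
        if known is not None:
            n_unmapped += sum(1 for r in reactions if r not in known)
        kept.append(
            CaseRecord(
                case_id=rec.case_id,
                is_duplicate=False,
                country=rec.country,
                reactions=reactions,
                outcomes=list(rec.outcomes),
            )
        )
    logger.info(
        "normalize_cases: kept %d, removed %d duplicates, %d non-%s, %d invalid; %d unmapped reaction mentions",
        len(kept), n_dup, n_geo, country_filter, n_bad, n_unmapped,
    )
    return kept


def outcome_proportions(cases: Sequence[CaseRecord], min_reports: int = 0) -> OutcomeTable:
    """Tally per-ADR outcome-category counts and proportions."""
    per_adr: dict[str, dict] = {}
    total_ds = 0
    for case in cases:
        cats = case_categories(case.outcomes)
        is_ds = bool(cats & {"Death", "Serious Outcome"})
        total_ds += is_ds
        for adr in set(case.reactions):
            row = per_adr.setdefault(
                adr,
                {
                    "n_cases": 0, "n_death": 0, "n_serious": 0,
                    "n_disability": 0, "n_none": 0, "n_death_or_serious": 0,
                },
            )
            row["n_cases"] += 1
            row["n_death"] += "Death" in cats
            row["n_serious"] += "Serious Outcome" in cats
            row["n_disability"] += "Disability" in cats
            row["n_none"] += "No Outcome" in cats
            row["n_death_or_serious"] += is_ds
    for row in per_adr.values():
        n = row["n_cases"]
        row["p_death"] = row["n_death"] / n
        row["p_serious"] = row["n_serious"] / n
        row["p_disability"] = row["n_disability"] / n
        row["p_none"] = row["n_none"] / n
    return OutcomeTable(
        per_adr=per_adr,
        n_cases_total=len(cases),
        n_death_or_serious_total=total_ds,
        min_reports=min_reports,
    )


def read_cases(path: str | Path) -> list[CaseRecord]:
    """Read JSON-lines case records (one JSON object per line)."""
    records: list[CaseRecord] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: invalid JSON at line {lineno}: {exc}") from exc
            records.append(
                CaseRecord(
                    case_id=str(obj.get("case_id", "")),
                    is_duplicate=bool(obj.get("is_duplicate", False)),
                    country=str(obj.get("country", "")),
                    reactions=[str(r) for r in obj.get("reactions", [])],
                    outcomes=[str(o) for o in obj.get("outcomes", [])],
                )
            )
    return records


def write_outcome_table(table: OutcomeTable, path: str | Path) -> None:
    table.to_frame().reset_index().to_csv(path, sep="\t", index=False)
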