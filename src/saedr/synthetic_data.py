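"""Synthetic fixtures with planted structure for every pipeline input.

Generates (1) an embedding space whose vectors carry a one-dimensional
latent severity axis plus isotropic Gaussian noise, with lexical
near-duplicate "clone" terms; (2) adverse-event case reports whose
death/serious outcome probability is a logistic function of case severity;
(3) drug-label ADR frequency tables with point/range/missing annotations.
All generators are pure functions of their parameters and rng seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from saedr.embedding_lexicon import EmbeddingSpace

logger = logging.getLogger(__name__)

_SYLLABLES = [
    "ab", "al", "ar", "car", "derm", "dys", "em", "gast", "hep", "itis",
    "my", "neur", "osis", "path", "phag", "plas", "ren", "sten", "tox", "vas",
]

_SERIOUS_CODES = ["Life-Threatening", "Hospitalization", "Other Serious", "Required Intervention"]
_DISABILITY_CODES = ["Congenital Anomaly", "Disability"]


@dataclass
class PlantedSpace:
    """Ground truth for a synthetic embedding space.

    ``latent_severity`` maps each term to its planted severity in [0, 1];
    clones share their parent's latent value.
    """

    latent_severity: dict[str, float]
    direction: np.ndarray
    noise_sd: float
    embeddings: EmbeddingSpace
    clone_map: dict[str, list[str]]
    term_table: pd.DataFrame  # columns term, tokens, pt_id

    @property
    def terms(self) -> list[str]:
        return list(self.latent_severity)

    def severity_series(self) -> pd.Series:
        return pd.Series(self.latent_severity)

    def pt_severity(self) -> pd.Series:
        """Latent severity aggregated at the PT level (mean over members)."""
        df = self.term_table.copy()
        df["latent"] = df["term"].map(self.latent_severity)
        return df.groupby("pt_id")["latent"].mean()


def _term_name(i: int, rng: np.random.Generator) -> str:
    parts = rng.choice(len(_SYLLABLES), size=3, replace=True)
    return "".join(_SYLLABLES[p] for p in parts) + f"{i:03d}"


def gen_embedding_space(
    n_terms: int = 500,
    dim: int = 32,
    noise_sd: float = 0.3,
    n_clones: int = 0,
    rng_seed: int = 0,
) -> PlantedSpace:
    """Plant a severity axis in an embedding space.

    Latent severities are uniform on [0, 1].  The severity axis is a
    unit-norm arc between two orthonormal directions: a term with latent
    ``s`` has mean vector ``cos(s*pi/2) * u_benign + sin(s*pi/2) * u_severe``
    plus isotropic Gaussian noise of total expected norm ``noise_sd``
    (per-coordinate sd ``noise_sd / sqrt(dim)``).  On the arc the cosine
    similarity of two noiseless terms is ``cos((s_i - s_j) * pi / 2)`` — a
    deterministic, monotone-decreasing function of their severity gap, so
    cosine nearest neighbors are severity-adjacent.  (A straight ray
    ``s * direction`` would leave all means mutually parallel and hence
    invisible to cosine similarity.)

    Clones are string variants (suffix edits) of randomly chosen parents
    sharing the parent's latent severity, with vectors re-noised around the
    same mean.  Terms belonging to the same parent share a pt_id.
    """
    if n_terms < 10:
        raise ValueError("n_terms must be >= 10")
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.default_rng(rng_seed)

    basis = np.linalg.qr(rng.normal(size=(dim, 2)))[0].T  # two orthonormal dirs
    u_benign, u_severe = basis[0], basis[1]
    direction = u_severe
    per_coord_sd = noise_sd / np.sqrt(dim)

    names = []
    seen: set[str] = set()
    for i in range(n_terms):
        name = _term_name(i, rng)
        while name in seen:
            name = _term_name(i, rng)
        seen.add(name)
        names.append(name)

    latents = rng.uniform(0.0, 1.0, size=n_terms)
    angles = latents * np.pi / 2
    means = np.cos(angles)[:, None] * u_benign[None, :] + np.sin(angles)[:, None] * u_severe[None, :]
    vectors = means + rng.normal(scale=per_coord_sd, size=(n_terms, dim))

    latent_severity = dict(zip(names, latents))
    clone_map: dict[str, list[str]] = {}
    rows = [
        {"term": t, "tokens": t, "pt_id": f"PT{i:05d}"}
        for i, t in enumerate(names)
    ]
    all_names = list(names)
    all_vectors = [vectors]

    if n_clones > 0:
        parents = rng.choice(n_terms, size=n_clones, replace=n_clones > n_terms)
        clone_rows = []
        clone_vecs = np.empty((n_clones, dim))
        for ci, pi in enumerate(parents):
            parent = names[int(pi)]
            suffix = ["acute", "nos", "severe", "chronic"][ci % 4]
            clone = f"{parent} {suffix}"
            if clone in seen:
                clone = f"{clone} {ci}"
            seen.add(clone)
            clone_map.setdefault(parent, []).append(clone)
            latent_severity[clone] = latents[int(pi)]
            clone_vecs[ci] = means[int(pi)] + rng.normal(scale=per_coord_sd, size=dim)
            clone_rows.append(
                {"term": clone, "tokens": clone.replace(" ", "|"), "pt_id": f"PT{int(pi):05d}"}
            )
            all_names.append(clone)
        rows.extend(clone_rows)
        all_vectors.append(clone_vecs)

    # token-level embedding space: each single-word term is its own token;
    # clone phrases reuse the parent token plus a shared suffix token whose
    # vector is the clone vector's residual, so the phrase mean lands on
    # the intended clone vector only approximately -- instead we emit each
    # full term as a dedicated token to keep phrase vectors exact
    token_names: list[str] = []
    token_vecs: list[np.ndarray] = []
    stacked = np.vstack(all_vectors)
    for term, vec in zip(all_names, stacked):
        if " " in term:
            continue
        token_names.append(term)
        token_vecs.append(vec)
    # clone phrases: represent via two tokens (parent-clone token pair) whose
    # mean equals the clone vector exactly
    for i, term in enumerate(all_names):
        if " " not in term:
            continue
        vec = stacked[i]
        joined = term.replace(" ", "_")
        token_names.append(joined)
        token_vecs.append(vec)
        rows_idx = next(j for j, r in enumerate(rows) if r["term"] == term)
        rows[rows_idx]["tokens"] = joined

    space = EmbeddingSpace(
        tokens=token_names,
        vectors=np.vstack(token_vecs),
        dim=dim,
    )
    term_table = pd.DataFrame(rows, columns=["term", "tokens", "pt_id"])
    return PlantedSpace(
        latent_severity=latent_severity,
        direction=direction,
        noise_sd=noise_sd,
        embeddings=space,
        clone_map=clone_map,
        term_table=term_table,
    )


def planted_ranking(space: PlantedSpace, source_id: str = "planted"):
    """RankedTerms over the planted latent severities, most severe first."""
    from saedr.seed_selection import RankedTerms

    items = sorted(space.latent_severity.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankedTerms(
        terms=[t for t, _ in items],
        scores=[v for _, v in items],
        source_id=source_id,
    )


def gen_case_reports(
    space: PlantedSpace,
    n_cases: int = 1000,
    outcome_slope: float = 6.0,
    rng_seed: int = 0,
    duplicate_fraction: float = 0.0,
    foreign_fraction: float = 0.0,
) -> list[dict]:
    """Simulate adverse-event case reports as JSON-ready dicts.

    Each case carries 1-5 ADR terms; the probability of a death-or-serious
    outcome is ``sigmoid(outcome_slope * (max latent severity - 0.5))``.
    Given a severe outcome, "Death" is chosen with probability equal to the
    case's maximum latent severity, otherwise a serious code uniformly.
    Non-severe cases report a disability code with probability 0.05 and no
    outcome otherwise.  ``duplicate_fraction`` of cases are re-emitted with
    the duplicate flag set; ``foreign_fraction`` get a non-US country.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(rng_seed)
    terms = space.terms
    latents = np.array([space.latent_severity[t] for t in terms])

    cases: list[dict] = []
    for i in range(n_cases):
        n_adrs = int(rng.integers(1, 6))
        idx = rng.choice(len(terms), size=min(n_adrs, len(terms)), replace=False)
        reactions = [terms[j] for j in idx]
        max_sev = float(latents[idx].max())
        p_severe = 1.0 / (1.0 + np.exp(-outcome_slope * (max_sev - 0.5)))
        outcomes: list[str] = []
        if rng.random() < p_severe:
            if rng.random() < max_sev:
                outcomes = ["Death"]
            else:
                outcomes = [_SERIOUS_CODES[int(rng.integers(len(_SERIOUS_CODES)))]]
        elif rng.random() < 0.05:
            outcomes = [_DISABILITY_CODES[int(rng.integers(len(_DISABILITY_CODES)))]]
        country = "US"
        if foreign_fraction > 0 and rng.random() < foreign_fraction:
            country = str(rng.choice(["FR", "JP", "DE", "GB"]))
        cases.append(
            {
                "case_id": f"C{i:07d}",
                "is_duplicate": False,
                "country": country,
                "reactions": reactions,
                "outcomes": outcomes,
            }
        )
    if duplicate_fraction > 0:
        n_dup = int(round(n_cases * duplicate_fraction))
        dup_idx = rng.choice(n_cases, size=n_dup, replace=False)
        for j in dup_idx:
            dup = dict(cases[int(j)])
            dup["is_duplicate"] = True
            cases.append(dup)
        order = rng.permutation(len(cases))
        # originals must precede their duplicates so "keep first" keeps the
        # unflagged record; the duplicate flag makes order irrelevant anyway
        cases = [cases[int(o)] for o in order]
    return cases


def write_case_reports(cases: list[dict], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for case in cases:
            fh.write(json.dumps(case) + "\n")


def gen_label_frequencies(
    space: PlantedSpace,
    n_drugs: int = 20,
    missing_fraction: float = 0.3,
    rng_seed: int = 0,
    adrs_per_drug: tuple[int, int] = (3, 12),
    point_fraction: float = 0.5,
) -> pd.DataFrame:
    """Simulate a drug-label ADR frequency table (SIDER-style TSV rows).

    Each drug receives a random PT subset; each (drug, ADR) is annotated
    as missing with probability ``missing_fraction``, else as a point
    frequency with probability ``point_fraction``, else as a range.
    Columns: drug_id, adr_pt, freq_point, freq_min, freq_max.
    """
    if n_drugs < 1:
        raise ValueError("n_drugs must be >= 1")
    rng = np.random.default_rng(rng_seed)
    pts = sorted(space.term_table["pt_id"].unique())
    rows = []
    for d in range(n_drugs):
        drug = f"DRUG{d:04d}"
        lo, hi = adrs_per_drug
        n_adrs = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(pts), size=min(n_adrs, len(pts)), replace=False)
        for j in chosen:
            pt = pts[int(j)]
            u = rng.random()
            if u < missing_fraction:
                rows.append({"drug_id": drug, "adr_pt": pt, "freq_point": None, "freq_min": None, "freq_max": None})
            elif u < missing_fraction + (1 - missing_fraction) * point_fraction:
                rows.append({
                    "drug_id": drug, "adr_pt": pt,
                    "freq_point": round(float(rng.uniform(0.001, 0.5)), 6),
                    "freq_min": None, "freq_max": None,
                })
            else:
                a, b = sorted(rng.uniform(0.001, 0.5, size=2))
                rows.append({
                    "drug_id": drug, "adr_pt": pt, "freq_point": None,
                    "freq_min": round(float(a), 6), "freq_max": round(float(b), 6),
                })
    return pd.DataFrame(rows, columns=["drug_id", "adr_pt", "freq_point", "freq_min", "freq_max"])
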