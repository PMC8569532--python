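"""End-to-end pipeline: build network -> seeds -> propagate -> score -> DRIP.

Configuration is a flat key/value file with stage-scoped sections (INI
syntax).  Every run writes its intermediate TSV artifacts plus a JSON run
manifest carrying the config snapshot, rng seeds, input digests and
per-stage row counts, sufficient to reproduce the run.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

import saedr
from saedr.drip import drip_table, read_label_frequencies, write_drip_table
from saedr.embedding_lexicon import build_lexicon, load_embeddings, read_term_table
from saedr.faers_outcomes import normalize_cases, outcome_proportions, read_cases
from saedr.lexical_network import build_knn_network, write_network
from saedr.seed_selection import (
    make_seed_sets,
    rank_from_outcomes,
    read_ranked_terms,
    write_seed_sets,
)
from saedr.severity_propagation import (
    SeverityTable,
    WalkConfig,
    aggregate_and_normalize,
    bootstrap_scores,
    point_scores,
    run_walks,
    write_severity_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config: dict
    rng_seed: int
    input_digests: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    version: str = saedr.__version__
    status: str = "RUNNING"

    def record_stage(self, name: str, t0: float, **counts) -> None:
        self.stages[name] = {"seconds": round(time.time() - t0, 3), **counts}

    def write(self, path: str | Path) -> None:
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(self.__dict__, indent=2, default=str))
        tmp.replace(path)  # atomic on POSIX


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def read_config(path: str | Path) -> dict:
    """Read an INI-style config into a flat {section: {key: value}} dict."""
    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)
    return {s: dict(parser.items(s)) for s in parser.sections()}


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    config: dict,
    out_dir: str | Path,
    rng_seed: Optional[int] = None,
) -> tuple[SeverityTable, Optional[object], RunManifest]:
    """Execute the full stage sequence described by ``config``.

    Required sections/keys::

        [inputs]  embeddings, term_table, and at least one of
                  ranking (TSV term[,score]) or cases (JSON-lines)
        [network] k
        [seeds]   pct
        [walks]   n_walks, walk_length, n_boot (0 = point scores), rng_seed
        [drip]    frequencies (optional), n_samples

    Returns (SeverityTable, DripTable or None, RunManifest); any stage
    error raises :class:`StageFailure` naming the stage, after writing a
    manifest with status FAILED.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = config.get("inputs", {})
    seed = int(rng_seed if rng_seed is not None else config.get("walks", {}).get("rng_seed", 0))
    manifest = RunManifest(config=config, rng_seed=seed)
    manifest_path = out_dir / "manifest.json"

    def fail(stage: str, exc: Exception):
        manifest.status = f"FAILED at {stage}"
        manifest.write(manifest_path)
        (out_dir / "FAILED").write_text(f"{stage}: {exc}\n")
        raise StageFailure(stage, exc)

    stage = "load"
    try:
        t0 = time.time()
        for key in ("embeddings", "term_table", "ranking", "cases", "frequencies"):
            for section in config.values():
                if key in section and Path(section[key]).exists():
                    manifest.input_digests[key] = _digest(section[key])
        space = load_embeddings(inputs["embeddings"])
        term_table = read_term_table(inputs["term_table"])
        lexicon = build_lexicon(term_table, space)
        manifest.record_stage(stage, t0, n_tokens=len(space), n_terms=len(lexicon),
                              coverage=lexicon.coverage)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail(stage, exc)

    stage = "build-net"
    try:
        t0 = time.time()
        k = int(config.get("network", {}).get("k", 10))
        network = build_knn_network(lexicon, k=k)
        write_network(network, out_dir / "edges.tsv", out_dir / "nodes.tsv")
        manifest.record_stage(stage, t0, n_nodes=network.n_nodes, n_edges=network.n_edges, k=k)
    except Exception as exc:
        fail(stage, exc)

    stage = "seeds"
    seed_sources = []
    try:
        t0 = time.time()
        pct = float(config.get("seeds", {}).get("pct", 10))
        if "ranking" in inputs:
            ranking = read_ranked_terms(inputs["ranking"], source_id="ranking")
            seed_sources.append(("ranking", ranking))
        if "cases" in inputs:
            cases = normalize_cases(
                read_cases(inputs["cases"]),
                country_filter=config.get("cases", {}).get("country", "US"),
            )
            outcomes = outcome_proportions(cases)
            seed_sources.append(("outcomes", rank_from_outcomes(outcomes)))
        if not seed_sources:
            raise ValueError("config must provide inputs.ranking and/or inputs.cases")
        seed_sets = []
        for name, ranking in seed_sources:
            seeds = make_seed_sets(ranking, ranking.reversed(), pct, network.nodes)
            write_seed_sets(seeds, out_dir / f"seeds_{name}.tsv")
            seed_sets.append((name, seeds))
        manifest.record_stage(
            stage, t0, pct=pct,
            **{f"n_seeds_{name}": len(s.severe) for name, s in seed_sets},
        )
    except Exception as exc:
        fail(stage, exc)

    stage = "propagate"
    try:
        t0 = time.time()
        walks_cfg = config.get("walks", {})
        n_boot = int(walks_cfg.get("n_boot", 0))
        per_run_scores = []
        n_unvisited = {}
        for i, (name, seeds) in enumerate(seed_sets):
            cfg = WalkConfig(
                n_walks_per_seed=int(walks_cfg.get("n_walks", 5000)),
                walk_length=int(walks_cfg.get("walk_length", 200)),
                rng_seed=seed + i,
            )
            tally = run_walks(network, seeds, cfg)
            n_unvisited[name] = len(tally.unvisited)
            if n_boot > 0:
                scores = bootstrap_scores(tally, n_boot=n_boot, rng_seed=seed + 100 + i)
            else:
                scores = point_scores(tally)
            per_run_scores.append(scores)
        severity = aggregate_and_normalize(per_run_scores, lexicon)
        write_severity_table(severity, out_dir / "scores.tsv")
        manifest.record_stage(
            stage, t0, n_pts_scored=len(severity.per_pt), n_boot=n_boot,
            unvisited=n_unvisited,
        )
    except Exception as exc:
        fail(stage, exc)

    drip = None
    if "frequencies" in inputs:
        stage = "drip"
        try:
            t0 = time.time()
            records = read_label_frequencies(inputs["frequencies"])
            severities = severity.per_pt["score_normalized"].to_dict()
            n_samples = int(config.get("drip", {}).get("n_samples", 1000))
            drip = drip_table(records, severities, n_samples=n_samples, rng_seed=seed)
            write_drip_table(drip, out_dir / "drip.tsv")
            manifest.record_stage(stage, t0, n_drugs=len(drip.table), n_samples=n_samples)
        except Exception as exc:
            fail(stage, exc)

    manifest.status = "OK"
    manifest.write(manifest_path)
    return severity, drip, manifest
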