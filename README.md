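# saedr

Severity scoring of adverse-drug-reaction (ADR) terms by label propagation
over a k-nearest-neighbor lexical network built from word embeddings, plus
per-drug risk (DRIP) profiling.

The method: per-term vectors are derived from a word2vec-style embedding
model (phrase terms use the mean of their token vectors); terms are
connected to their k nearest neighbors by cosine distance with edge weight
equal to cosine similarity; small severe and benign seed sets are selected
from the extremes of a ranked severity source after filtering lexical
near-duplicates (indel similarity ratio > 0.5); weighted random walks from
every seed tally per-node visit counts `s_u` (severe-initiated) and `b_u`
(benign-initiated); the severity score of node `u` is `s_u / (s_u + b_u)`,
stabilized by bootstrap resampling of whole walks, averaged at the
preferred-term (PT) level across seed sources, and min-max normalized to
[0, 1]. A drug's DRIP score is the sum over its label ADRs of severity
times frequency, averaged over repeated uniform frequency draws (ranges
sampled within their bounds; missing frequencies sampled on [0.001, 0.01]).

## Layout

| module | contents |
| --- | --- |
| `saedr.embedding_lexicon` | word2vec-text loader, phrase vectors, ADR term lexicon (LLT → PT mapping, coverage) |
| `saedr.lexical_network` | exact cosine k-NN graph, union symmetrization, TSV (de)serialization |
| `saedr.seed_selection` | indel similarity, near-duplicate filtering, outcome-based ranking, seed-set assembly |
| `saedr.severity_propagation` | weighted random-walk engine, visit tallies, bootstrap, PT aggregation + normalization |
| `saedr.tuning` | train/test split, (k, pct) grid search, Spearman / one-sided t utilities |
| `saedr.faers_outcomes` | case normalization (dedup, geography), outcome schema, per-ADR proportions |
| `saedr.drip` | frequency sampling, per-drug DRIP scores, group summaries |
| `saedr.synthetic_data` | planted-severity embedding spaces, simulated case reports and label frequencies |
| `saedr.pipeline` / `saedr.cli` | end-to-end orchestration, run manifest, `saedr` command |

## CLI

Everything is reachable through the `saedr` command (all tables are TSV
with headers; case reports are JSON-lines). A typical synthetic run:

```sh
# generate inputs with a planted severity axis
saedr simulate embeddings --n-terms 500 --dim 32 --noise-sd 0.3 --rng-seed 1 --out-prefix syn
saedr simulate cases  --truth syn.truth.tsv --n-cases 2000 --rng-seed 2 --out cases.jsonl
saedr simulate labels --terms syn.terms.tsv --truth syn.truth.tsv --n-drugs 20 --rng-seed 3 --out freq.tsv

# stage by stage
saedr build-net --embeddings syn.vec --term-table syn.terms.tsv -k 10 \
    --edges-out edges.tsv --nodes-out nodes.tsv
saedr seeds --ranking syn.truth.tsv --nodes nodes.tsv --pct 10 --out seeds.tsv
saedr propagate --network edges.tsv --nodes nodes.tsv --seeds seeds.tsv \
    --n-walks 5000 --walk-length 200 --n-boot 10000 --rng-seed 1 --out scores.tsv
saedr validate --scores scores.tsv --ranking syn.truth.tsv
saedr drip --frequencies freq.tsv --severities scores.tsv --out drip.tsv

# hyperparameter grid search
saedr tune --embeddings syn.vec --term-table syn.terms.tsv --ranking syn.truth.tsv \
    --grid-k 2,5,10 --grid-pct 5,10 --rng-seed 1 --out tuning.tsv
```

`saedr run --config run.ini --out-dir out/` executes the whole sequence
from an INI config (sections `[inputs]`, `[network]`, `[seeds]`,
`[walks]`, `[drip]`; see `saedr.pipeline.run_pipeline` for keys) and
writes a `manifest.json` with seeds, input digests and per-stage counts.
Supplying both a ranking file and a case file yields two propagation runs
whose scores are averaged at the PT level before normalization.

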