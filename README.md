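# kbmatch

A self-contained SDK for working with a clinical variant knowledgebase
snapshot offline: a linked record model with local caching, a
high-throughput genomic coordinate-matching engine with four match modes,
VCF 4.2 export with structured clinical annotations, and cohort-level
match summarization. A synthetic-knowledgebase generator with known ground
truth makes every component testable without network access.

## Library overview

| Module | What it does |
|---|---|
| `kbmatch.records` | Entity types (genes, variants, evidence, assertions, sources), snapshot JSON parsing (plain or gzip), link materialization into shared object graphs, status filtering. Dangling links resolve to partial records, never exceptions. |
| `kbmatch.store` | Cache envelopes with session-scoped identity keys (recomputed per process), save/load to a human-readable JSON cache, strict 7-day (configurable) expiration, atomic refresh from a file/URL source. |
| `kbmatch.search` | Sorted variant coordinate index (compound variants split into two rows; coordinate-less variants excluded) and a two-pointer bulk search with pointer restore. Modes: `exact`, `query_encompassing`, `record_encompassing`, `any`. Closed 1-based intervals; alt alleles participate in `exact` only (`None`/`"*"` = wildcard). Results are instrumented with predicate-evaluation counts. |
| `kbmatch.vcf` | `VcfWriter` with per-variant validity rules (fusions and coordinate-incomplete variants are skipped with warnings), reversible CSQ value escaping (spaces→underscores, everything else percent-hex), one CSQ entry per status-passing evidence item/assertion. Indels use a documented `N`-padding dialect since no reference FASTA is assumed. |
| `kbmatch.cohort` | MAF-like TSV reader, barcode-tagged query construction, per-sample classification (`exact` / `any_only` / `none` / `no_variants` — always a partition), highest-evidence-level summarization (A>B>C>D>E over exact matches), cohort report tables. |
| `kbmatch.synth` | Seed-deterministic snapshot + cohort generator with per-row ground-truth labels consistent with the search predicates by construction. |

The snapshot JSON dialect is documented in
`src/kbmatch/data/snapshot.schema.json`.

## Quick start

```python
from kbmatch import (GeneratorConfig, generate_knowledgebase, generate_cohort,
                     parse_snapshot, resolve_links, build_index,
                     CoordinateQuery, bulk_search)
from kbmatch.synth import snapshot_bytes

cfg = GeneratorConfig(seed=1, n_variants=200, n_evidence=400)
snapshot, truth = generate_knowledgebase(cfg)
kb = resolve_links(parse_snapshot(snapshot_bytes(snapshot)))

index = build_index(kb.variants)
hits = bulk_search(index, [CoordinateQuery(chromosome="1", start=500, stop=600)], "any")
for variant in hits.matches[0]:
    print(variant.name, [e.evidence_level for e in variant.evidence])
```

## Command line

```bash
# synthesize a knowledgebase + cohort with ground truth
kbmatch generate --seed 1 --n-variants 200 --cohort-size 100 \
    --out-snapshot snap.json --out-maf cohort.maf --out-truth truth.tsv

# build/refresh the local cache (add --hard to force)
kbmatch update --source snap.json --cache-path cache.json

# coordinate matching: TSV of (key, chrom, start, stop, alt), no header
kbmatch bulk-search --mode exact --queries queries.tsv --cache-path cache.json

# status-filtered VCF export (-i is required and repeatable)
kbmatch create-vcf -i accepted -i submitted -o kb.vcf --cache-path cache.json

# per-tumor match summary for a MAF-like table
kbmatch cohort-report --maf cohort.maf --statuses accepted --statuses submitted \
    --cache-path cache.json -o report.tsv
```

## Tests and acceptance

```bash
python -m pytest -q tests/            # full suite (~15 s)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds the binding acceptance criteria: search
results are checked against an independent all-pairs brute-force oracle on
thousands of randomized instances (including an adversarial long-interval
fixture), mode nesting (`exact ⊆ QE ∩ RE ⊆ any`), a linear-scaling bound on
instrumented comparison counts, planted-fraction recovery on synthetic
cohorts, VCF round-trips through `pysam`, escape-encoding reversibility,
cache save/load/expiry semantics, and cohort partition invariants.

`scripts/acceptance.py` runs an end-to-end pipeline self-check and writes
the (empty) numeric-target report; there are no offline-reproducible
headline numbers for this artifact, so all acceptance is property-based.
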