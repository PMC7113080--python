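"""Independent brute-force oracle and random-instance helpers for search tests.

The oracle evaluates every (query, entry) pair with its own inline interval
arithmetic (numpy, closed intervals) — it shares no code path with the
two-pointer engine it checks.
"""

from __future__ import annotations

import numpy as np

from kbmatch.records import Coordinates, RecordIdentifier, VariantRecord
from kbmatch.search import CoordinateQuery, build_index

CHROMS = ["1", "2", "3", "X"]
ALTS = [None, "A", "C", "G", "T"]


def brute_force_match_sets(entries, queries, mode: str) -> list[set[int]]:
    """All-pairs evaluation; returns the set of matched variant ids per query."""
    chrom_codes = {c: i for i, c in enumerate(sorted({e.chromosome for e in entries}))}
    e_chrom = np.array([chrom_codes[e.chromosome] for e in entries], dtype=np.int64)
    e_start = np.array([e.start for e in entries], dtype=np.int64)
    e_stop = np.array([e.stop for e in entries], dtype=np.int64)
    e_alt = [e.alt for e in entries]
    e_vid = [e.variant_id for e in entries]

    out = []
    for q in queries:
        if q.chromosome not in chrom_codes:
            out.append(set())
            continue
        same = e_chrom == chrom_codes[q.chromosome]
        if mode == "any":
            mask = same & (q.start <= e_stop) & (e_start <= q.stop)
        elif mode == "query_encompassing":
            mask = same & (e_start >= q.start) & (e_stop <= q.stop)
        elif mode == "record_encompassing":
            mask = same & (q.start >= e_start) & (q.stop <= e_stop)
        elif mode == "exact":
            mask = same & (e_start == q.start) & (e_stop == q.stop)
            if q.alt not in (None, "*"):
                idx = np.nonzero(mask)[0]
                mask = np.zeros_like(mask)
                mask[[i for i in idx if e_alt[i] == q.alt]] = True
        else:  # pragma: no cover
            raise ValueError(mode)
        out.append({e_vid[i] for i in np.nonzero(mask)[0]})
    return out


def make_variant(vid: int, chrom, start, stop, alt=None, chrom2=None, start2=None,
                 stop2=None) -> VariantRecord:
    return VariantRecord(
        identifier=RecordIdentifier("variant", vid),
        name=f"V{vid}",
        coordinates=Coordinates(
            chromosome=chrom,
            start=start,
            stop=stop,
            variant_bases=alt,
            chromosome2=chrom2,
            start2=start2,
            stop2=stop2,
        ),
    )


def random_instance(rng: np.random.Generator, n: int, m: int, span: int = 2000,
                    max_len: int = 30):
    """Random variants (some compound) and queries over a small genome."""
    variants = []
    for vid in range(1, n + 1):
        chrom = CHROMS[rng.integers(len(CHROMS))]
        start = int(rng.integers(1, span))
        stop = start + int(rng.integers(0, max_len))
        alt = ALTS[rng.integers(len(ALTS))]
        if rng.random() < 0.1:  # compound
            c2 = CHROMS[rng.integers(len(CHROMS))]
            s2 = int(rng.integers(1, span))
            variants.append(
                make_variant(vid, chrom, start, stop, None, c2, s2,
                             s2 + int(rng.integers(0, max_len)))
            )
        else:
            variants.append(make_variant(vid, chrom, start, stop, alt))
    queries = []
    for _ in range(m):
        chrom = CHROMS[rng.integers(len(CHROMS))]
        start = int(rng.integers(1, span))
        stop = start + int(rng.integers(0, max_len))
        alt = ALTS[rng.integers(len(ALTS))] if rng.random() < 0.7 else "*"
        queries.append(CoordinateQuery(chromosome=chrom, start=start, stop=stop, alt=alt))
    return build_index(variants), queries


def result_id_sets(result) -> list[set[int]]:
    return [{v.id for v in matched} for matched in result.matches]
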