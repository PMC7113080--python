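"""Sorted variant coordinate index and two-pointer bulk coordinate search.

The index holds one row per usable coordinate set — compound variants (e.g.
fusions) contribute two rows sharing one variant reference, variants missing
coordinates contribute none — sorted by (chromosome, start, stop, alternate
sequence).  Bulk search walks sorted queries and the index together,
advancing whichever pointer lags; the index pointer only moves permanently
past rows that can no longer match any later query, and a per-query forward
scan (the "restore" pointer) collects every overlapping row.

Intervals are 1-based and fully closed on both sides.  Four match modes are
supported:

========================  ====================================================
``exact``                 identical start/stop and compatible alternate allele
``query_encompassing``    index row lies entirely inside the query interval
``record_encompassing``   query lies entirely inside the index row
``any``                   any overlap of the closed intervals
========================  ====================================================

Alternate alleles participate in sorting and in ``exact`` matching only; a
query alt of ``None`` or ``"*"`` is a wildcard.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .genome import DEFAULT_BUILD, chromosome_sort_key, normalize_chromosome
from .records import VariantRecord
from .store import record_key


class BuildMismatchError(ValueError):
    """Query genome build differs from the index build."""


class MatchMode(str, enum.Enum):
    EXACT = "exact"
    QUERY_ENCOMPASSING = "query_encompassing"
    RECORD_ENCOMPASSING = "record_encompassing"
    ANY = "any"

    @classmethod
    def coerce(cls, value: "MatchMode | str") -> "MatchMode":
        if isinstance(value, cls):
            return value
        aliases = {"qe": cls.QUERY_ENCOMPASSING, "re": cls.RECORD_ENCOMPASSING}
        v = str(value).lower()
        return aliases.get(v) or cls(v)


@dataclass(frozen=True)
class CoordinateQuery:
    """A caller-supplied closed interval, optionally allele- and sample-tagged.

    ``key`` is an opaque user tag (e.g. a tumor sample barcode) carried
    through search results untouched.
    """

    chromosome: str
    start: int
    stop: int
    alt: str | None = None
    build: str = DEFAULT_BUILD
    key: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.alt is not None and self.alt != "*":
            object.__setattr__(self, "alt", self.alt.upper())
        if self.start > self.stop:
            raise ValueError(f"query start > stop: {self.start} > {self.stop}")


@dataclass(frozen=True)
class CoordinateIndexEntry:
    """One sorted index row pointing back (via the session cache key) to the
    variant it came from."""

    chromosome: str
    start: int
    stop: int
    alt: str | None
    variant_key: int
    variant_id: int  # public id, used for deterministic tie-breaking

    def sort_key(self) -> tuple:
        return (
            chromosome_sort_key(self.chromosome),
            self.start,
            self.stop,
            self.alt or "",
            self.variant_id,
        )


def query_sort_key(query: CoordinateQuery) -> tuple:
    """Queries sort by the same procedure as the index (wildcard alt first)."""
    alt = "" if query.alt in (None, "*") else query.alt
    return (chromosome_sort_key(query.chromosome), query.start, query.stop, alt)


@dataclass
class IndexBuildReport:
    n_variants: int = 0
    n_entries: int = 0
    n_compound: int = 0
    n_skipped_missing_coordinates: int = 0


class VariantCoordinateIndex:
    """Sorted list of :class:`CoordinateIndexEntry` plus the variant lookup."""

    def __init__(
        self,
        entries: Sequence[CoordinateIndexEntry],
        variants_by_key: Mapping[int, VariantRecord],
        build: str = DEFAULT_BUILD,
        report: IndexBuildReport | None = None,
    ) -> None:
        self.entries = sorted(entries, key=CoordinateIndexEntry.sort_key)
        self.variants_by_key = dict(variants_by_key)
        self.build = build
        self.report = report or IndexBuildReport(
            n_variants=len(variants_by_key), n_entries=len(self.entries)
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[CoordinateIndexEntry]:
        return iter(self.entries)

    def variant_for(self, entry: CoordinateIndexEntry) -> VariantRecord:
        return self.variants_by_key[entry.variant_key]


def build_index(
    variants: Iterable[VariantRecord], build: str = DEFAULT_BUILD
) -> VariantCoordinateIndex:
    """Extract all usable coordinates from ``variants`` into a sorted index.

    Variants missing chromosome/start/stop are excluded (and counted in the
    build report); compound variants are split into two entries sharing one
    variant key.  Deterministic: rebuilding from the same variants yields an
    identically ordered index.
    """
    report = IndexBuildReport()
    entries: list[CoordinateIndexEntry] = []
    by_key: dict[int, VariantRecord] = {}
    for variant in variants:
        report.n_variants += 1
        coords = variant.coordinates
        if not coords.has_primary:
            report.n_skipped_missing_coordinates += 1
            continue
        key = record_key(variant.type, variant.id)
        by_key[key] = variant
        entries.append(
            CoordinateIndexEntry(
                chromosome=coords.chromosome,
                start=coords.start,
                stop=coords.stop,
                alt=coords.variant_bases,
                variant_key=key,
                variant_id=variant.id,
            )
        )
        if coords.is_compound:
            report.n_compound += 1
            entries.append(
                CoordinateIndexEntry(
                    chromosome=coords.chromosome2,
                    start=coords.start2,
                    stop=coords.stop2,
                    alt=None,
                    variant_key=key,
                    variant_id=variant.id,
                )
            )
    report.n_entries = len(entries)
    return VariantCoordinateIndex(entries, by_key, build=build, report=report)


# ---------------------------------------------------------------------------
# Match predicate


def _alt_compatible(query_alt: str | None, entry_alt: str | None) -> bool:
    if query_alt in (None, "*"):
        return True
    return query_alt == entry_alt


def match(
    query: CoordinateQuery, entry: CoordinateIndexEntry, mode: MatchMode | str
) -> bool:
    """Pure predicate deciding whether ``entry`` matches ``query`` in ``mode``.

    Closed-interval semantics; different chromosomes never match.
    """
    mode = MatchMode.coerce(mode)
    if normalize_chromosome(query.chromosome) != entry.chromosome:
        return False
    if mode is MatchMode.ANY:
        return query.start <= entry.stop and entry.start <= query.stop
    if mode is MatchMode.QUERY_ENCOMPASSING:
        return entry.start >= query.start and entry.stop <= query.stop
    if mode is MatchMode.RECORD_ENCOMPASSING:
        return query.start >= entry.start and query.stop <= entry.stop
    return (
        query.start == entry.start
        and query.stop == entry.stop
        and _alt_compatible(query.alt, entry.alt)
    )


# ---------------------------------------------------------------------------
# Bulk search


@dataclass
class BulkSearchResult(Mapping):
    """Per-query match lists, in the original query order.

    Mapping access is by query value (equal queries share a match set);
    ``matches`` is positionally aligned with the input query list.
    ``n_predicate_evaluations`` counts mode-predicate calls during the scan
    phase and ``n_pointer_steps`` counts permanent index-pointer advances —
    together they instrument the linear-scaling contract.
    """

    queries: tuple[CoordinateQuery, ...]
    matches: tuple[tuple[VariantRecord, ...], ...]
    mode: MatchMode
    n_predicate_evaluations: int = 0
    n_pointer_steps: int = 0
    _by_query: dict[CoordinateQuery, tuple[VariantRecord, ...]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        if not self._by_query:
            self._by_query = dict(zip(self.queries, self.matches))

    def __getitem__(self, query: CoordinateQuery) -> tuple[VariantRecord, ...]:
        return self._by_query[query]

    def __iter__(self) -> Iterator[CoordinateQuery]:
        return iter(self._by_query)

    def __len__(self) -> int:
        return len(self._by_query)


def bulk_search(
    index: VariantCoordinateIndex,
    queries: Sequence[CoordinateQuery],
    mode: MatchMode | str,
) -> BulkSearchResult:
    """Match every query against the index with a sorted two-pointer merge.

    Queries may arrive in any order; they are sorted internally by the index
    ordering and results are reported in the original order.  Matched
    variants are deduplicated per query (a compound variant matching on both
    split entries reports once) and sorted by variant id.

    Total predicate evaluations are O(|index| + |queries| + scanned overlap
    pairs): the index pointer permanently advances past an entry only when
    its stop precedes the current query start (so it can never match a
    later, >=-start query); everything else is covered by the bounded
    per-query forward scan.
    """
    mode = MatchMode.coerce(mode)
    for q in queries:
        if q.build != index.build:
            raise BuildMismatchError(
                f"query build {q.build!r} does not match index build {index.build!r}"
            )

    order = sorted(range(len(queries)), key=lambda i: query_sort_key(queries[i]))
    entries = index.entries
    n = len(entries)
    results: list[tuple[VariantRecord, ...]] = [()] * len(queries)

    vci_ptr = 0
    n_pred = 0
    n_steps = 0
    for qi in order:
        q = queries[qi]
        q_chrom = chromosome_sort_key(q.chromosome)
        # permanent advance: drop entries that precede this (and thus every
        # later) query — earlier chromosome, or same chromosome with
        # stop < query.start
        while vci_ptr < n:
            e = entries[vci_ptr]
            e_chrom = chromosome_sort_key(e.chromosome)
            if e_chrom < q_chrom or (e_chrom == q_chrom and e.stop < q.start):
                vci_ptr += 1
                n_steps += 1
            else:
                break
        # bounded forward scan from the restored pointer: entries on this
        # chromosome with start <= query.stop are the only candidates
        matched: dict[int, VariantRecord] = {}
        scan = vci_ptr
        while scan < n:
            e = entries[scan]
            e_chrom = chromosome_sort_key(e.chromosome)
            if e_chrom > q_chrom or (e_chrom == q_chrom and e.start > q.stop):
                break
            n_pred += 1
            if match(q, e, mode) and e.variant_key not in matched:
                matched[e.variant_key] = index.variants_by_key[e.variant_key]
            scan += 1
        results[qi] = tuple(sorted(matched.values(), key=lambda v: v.id))

    return BulkSearchResult(
        queries=tuple(queries),
        matches=tuple(results),
        mode=mode,
        n_predicate_evaluations=n_pred,
        n_pointer_steps=n_steps,
    )


def search_single(
    index: VariantCoordinateIndex, query: CoordinateQuery, mode: MatchMode | str
) -> tuple[VariantRecord, ...]:
    """Convenience wrapper: ``bulk_search`` on a singleton query list."""
    return bulk_search(index, [query], mode).matches[0]
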