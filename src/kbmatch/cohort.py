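"""Cohort-level matching: MAF-like tables in, per-sample match summaries out.

A tumor cohort arrives as a MAF-like TSV (one somatic variant per row,
tagged with a tumor sample barcode).  Rows become sample-tagged coordinate
queries, an exact and an ``any``-overlap bulk search are run against the
variant coordinate index, and each sample is classified:

``exact``        at least one variant matched exactly
``any_only``     no exact match, but at least one overlap match
``none``         variants reported, none matched
``no_variants``  no variants reported for the sample

The four classes partition the cohort.  The highest evidence level per
sample (A > B > C > D > E) is summarized over exact-matched variants only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Sequence, Union

import pandas as pd

from .genome import DEFAULT_BUILD, normalize_chromosome
from .records import DEFAULT_STATUSES, ReviewStatus, VariantRecord
from .search import (
    BulkSearchResult,
    CoordinateQuery,
    MatchMode,
    VariantCoordinateIndex,
    bulk_search,
    query_sort_key,
)

#: Required columns of the MAF-like input table.
MAF_COLUMNS = (
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "End_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
)

LEVEL_ORDER = ("A", "B", "C", "D", "E")  # A ranks highest
_LEVEL_RANK = {level: i for i, level in enumerate(LEVEL_ORDER)}

MATCH_CLASSES = ("exact", "any_only", "none", "no_variants")


class CohortFormatError(ValueError):
    """The MAF-like table is missing a required column."""


class CohortConsistencyError(ValueError):
    """Search results reference a barcode absent from the sample list."""


@dataclass(frozen=True)
class SampleVariant:
    """One row of the cohort table: a sample-tagged somatic variant."""

    sample_barcode: str
    chromosome: str
    start: int
    stop: int
    ref: str | None
    alt: str | None

    def __post_init__(self) -> None:
        if not self.sample_barcode:
            raise ValueError("sample_barcode must be non-empty")
        if self.start > self.stop:
            raise ValueError(f"start > stop: {self.start} > {self.stop}")


@dataclass
class CohortTable:
    variants: list[SampleVariant]
    n_dropped: int = 0


def _normalize_allele(raw: object) -> str | None:
    """MAF convention: '-' (and blanks) mean no allele on that side."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    s = str(raw).strip().upper()
    if s in ("", "-", "NAN"):
        return None
    return s


def read_cohort_table(source: Union[str, IO[str], IO[bytes]]) -> CohortTable:
    """Read a MAF-like TSV into sample variants.

    Rows with unparseable coordinates are dropped and counted; a missing
    required column raises :class:`CohortFormatError` naming the column.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, comment="#")
    for col in MAF_COLUMNS:
        if col not in df.columns:
            raise CohortFormatError(f"required column {col!r} missing from cohort table")

    variants: list[SampleVariant] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        try:
            start = int(getattr(row, "Start_Position"))
            stop = int(getattr(row, "End_Position"))
            variants.append(
                SampleVariant(
                    sample_barcode=str(getattr(row, "Tumor_Sample_Barcode")),
                    chromosome=normalize_chromosome(getattr(row, "Chromosome")),
                    start=start,
                    stop=stop,
                    ref=_normalize_allele(getattr(row, "Reference_Allele")),
                    alt=_normalize_allele(getattr(row, "Tumor_Seq_Allele2")),
                )
            )
        except (TypeError, ValueError):
            n_dropped += 1
    return CohortTable(variants=variants, n_dropped=n_dropped)


def queries_from_cohort(
    variants: Sequence[SampleVariant], build: str = DEFAULT_BUILD
) -> list[CoordinateQuery]:
    """One barcode-keyed query per sample variant, sorted by the index
    ordering (row identity is recoverable through the barcode key plus
    coordinates; duplicates are preserved)."""
    queries = [
        CoordinateQuery(
            chromosome=v.chromosome,
            start=v.start,
            stop=v.stop,
            alt=v.alt,
            build=build,
            key=v.sample_barcode,
        )
        for v in variants
    ]
    queries.sort(key=lambda q: (query_sort_key(q), q.key or ""))
    return queries


@dataclass
class SampleSummary:
    """Per-sample match classification and evidence-level summary."""

    sample_barcode: str
    n_variants: int
    n_exact: int
    n_any_only: int
    match_class: str
    highest_level: str | None = None

    def __post_init__(self) -> None:
        if self.match_class not in MATCH_CLASSES:
            raise ValueError(f"unknown match class {self.match_class!r}")
        if self.n_exact + self.n_any_only > self.n_variants:
            raise ValueError("match counts exceed variant count")


def highest_evidence_level(
    matched_variants: Iterable[VariantRecord],
    allowed_statuses: Iterable[ReviewStatus | str] = DEFAULT_STATUSES,
) -> str | None:
    """Maximum evidence level (A > B > C > D > E) over all status-passing
    evidence of the given variants; None when there is none."""
    statuses = frozenset(ReviewStatus(s) for s in allowed_statuses)
    best: str | None = None
    for variant in matched_variants:
        for ev in variant.evidence:
            if ev.status not in statuses:
                continue
            if best is None or _LEVEL_RANK[ev.evidence_level] < _LEVEL_RANK[best]:
                best = ev.evidence_level
    return best


def _pairs(result: Union[BulkSearchResult, Iterable]) -> list[tuple[CoordinateQuery, tuple]]:
    if isinstance(result, BulkSearchResult):
        return list(zip(result.queries, result.matches))
    return [(q, tuple(m)) for q, m in result]


def classify_samples(
    exact_results: Union[BulkSearchResult, Iterable],
    any_results: Union[BulkSearchResult, Iterable],
    all_samples: Iterable[str] | None = None,
    allowed_statuses: Iterable[ReviewStatus | str] = DEFAULT_STATUSES,
) -> list[SampleSummary]:
    """Group query results by sample barcode and classify each sample.

    ``exact_results`` and ``any_results`` must come from the same query list
    (the ``any`` result set is a superset per the mode-nesting property).
    ``all_samples`` may include barcodes with zero reported variants, which
    classify as ``no_variants``.
    """
    exact_pairs = _pairs(exact_results)
    any_pairs = _pairs(any_results)
    if len(exact_pairs) != len(any_pairs):
        raise CohortConsistencyError(
            "exact and any results cover different numbers of queries"
        )

    barcodes: dict[str, dict] = {}
    if all_samples is not None:
        for bc in all_samples:
            barcodes[bc] = {"n": 0, "exact": 0, "any_only": 0, "matched": []}
    known = set(barcodes) if all_samples is not None else None

    for (q_exact, m_exact), (q_any, m_any) in zip(exact_pairs, any_pairs):
        if q_exact != q_any:
            raise CohortConsistencyError("exact/any results are not query-aligned")
        bc = q_exact.key or ""
        if known is not None and bc not in known:
            raise CohortConsistencyError(f"result barcode {bc!r} not in sample list")
        agg = barcodes.setdefault(bc, {"n": 0, "exact": 0, "any_only": 0, "matched": []})
        agg["n"] += 1
        if m_exact:
            agg["exact"] += 1
            agg["matched"].extend(m_exact)
        elif m_any:
            agg["any_only"] += 1

    summaries = []
    for bc in sorted(barcodes):
        agg = barcodes[bc]
        if agg["n"] == 0:
            cls = "no_variants"
        elif agg["exact"]:
            cls = "exact"
        elif agg["any_only"]:
            cls = "any_only"
        else:
            cls = "none"
        level = (
            highest_evidence_level(agg["matched"], allowed_statuses)
            if agg["exact"]
            else None
        )
        summaries.append(
            SampleSummary(
                sample_barcode=bc,
                n_variants=agg["n"],
                n_exact=agg["exact"],
                n_any_only=agg["any_only"],
                match_class=cls,
                highest_level=level,
            )
        )
    return summaries


@dataclass
class CohortReport:
    """Cohort-level aggregation of sample summaries."""

    n_samples: int
    class_counts: dict[str, int]
    class_fractions: dict[str, float]
    level_counts: dict[str, int]
    level_fractions: dict[str, float]  # among exact-matched samples
    exact_count_distribution: dict[int, int]  # samples by number of exact matches
    n_queries: int = 0
    n_exact_queries: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("class", cls, self.class_counts.get(cls, 0), self.class_fractions.get(cls, 0.0))
            for cls in MATCH_CLASSES
        ]
        rows += [
            ("highest_level", lv, self.level_counts.get(lv, 0), self.level_fractions.get(lv, 0.0))
            for lv in LEVEL_ORDER
            if lv in self.level_counts
        ]
        rows += [
            ("n_exact_variants", str(k), v, v / self.n_samples if self.n_samples else 0.0)
            for k, v in sorted(self.exact_count_distribution.items())
        ]
        return pd.DataFrame(rows, columns=["breakdown", "group", "count", "fraction"])

    def to_tsv(self, stream: Union[str, IO[str]]) -> None:
        self.to_frame().to_csv(stream, sep="\t", index=False)


def cohort_report(summaries: Sequence[SampleSummary]) -> CohortReport:
    """Aggregate class fractions, highest-level fractions among exact-matched
    samples, and the distribution of samples by exact-match count."""
    n = len(summaries)
    class_counts = {cls: 0 for cls in MATCH_CLASSES}
    level_counts: dict[str, int] = {}
    exact_dist: dict[int, int] = {}
    n_queries = 0
    n_exact_queries = 0
    for s in summaries:
        class_counts[s.match_class] += 1
        exact_dist[s.n_exact] = exact_dist.get(s.n_exact, 0) + 1
        n_queries += s.n_variants
        n_exact_queries += s.n_exact
        if s.match_class == "exact" and s.highest_level is not None:
            level_counts[s.highest_level] = level_counts.get(s.highest_level, 0) + 1

    n_exact_samples = class_counts["exact"]
    return CohortReport(
        n_samples=n,
        class_counts=class_counts,
        class_fractions={c: (k / n if n else 0.0) for c, k in class_counts.items()},
        level_counts=level_counts,
        level_fractions={
            lv: (k / n_exact_samples if n_exact_samples else 0.0)
            for lv, k in level_counts.items()
        },
        exact_count_distribution=exact_dist,
        n_queries=n_queries,
        n_exact_queries=n_exact_queries,
    )


def annotate_cohort(
    table: CohortTable,
    index: VariantCoordinateIndex,
    all_samples: Iterable[str] | None = None,
    allowed_statuses: Iterable[ReviewStatus | str] = DEFAULT_STATUSES,
) -> tuple[list[SampleSummary], CohortReport]:
    """Full pipeline: queries, exact + any bulk searches, classification."""
    queries = queries_from_cohort(table.variants)
    exact = bulk_search(index, queries, MatchMode.EXACT)
    any_ = bulk_search(index, queries, MatchMode.ANY)
    summaries = classify_samples(exact, any_, all_samples, allowed_statuses)
    return summaries, cohort_report(summaries)
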