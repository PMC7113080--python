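"""Knowledgebase record model: entity types, snapshot parsing, link resolution.

A *snapshot* is a single JSON document with one top-level array per entity
type (``genes``, ``variants``, ``evidence_items``, ``assertions``,
``sources``, ...).  Parsing yields a :class:`RecordCollection` whose link
fields hold :class:`RecordIdentifier` values; :func:`resolve_links`
materializes those into shared object references so nested records can be
traversed with plain attribute access.  Links that point outside the
snapshot resolve to :class:`PartialRecord` stubs, never to exceptions.

The JSON dialect is described by ``data/snapshot.schema.json`` shipped with
the package; readers accept plain or gzip-compressed files.
"""

from __future__ import annotations

import copy
import enum
import gzip
import io
import json
import os
from dataclasses import dataclass, field
from typing import Any, BinaryIO, Iterable, Iterator, Mapping

from .genome import DEFAULT_BUILD, is_valid_base_string, normalize_chromosome

RECORD_TYPES = frozenset(
    {
        "gene",
        "variant",
        "variant_group",
        "evidence",
        "assertion",
        "source",
        "user",
        "organization",
    }
)

EVIDENCE_LEVELS = ("A", "B", "C", "D", "E")

SNAPSHOT_FORMAT = "kb-snapshot"
SNAPSHOT_VERSION = 1

# top-level snapshot array name -> record_type of its elements
_SECTION_TYPES = {
    "genes": "gene",
    "variants": "variant",
    "variant_groups": "variant_group",
    "evidence_items": "evidence",
    "assertions": "assertion",
    "sources": "source",
    "users": "user",
    "organizations": "organization",
}
_TYPE_SECTIONS = {v: k for k, v in _SECTION_TYPES.items()}


class SnapshotParseError(ValueError):
    """Raised when a snapshot stream is not well-formed JSON."""


class SnapshotSchemaError(ValueError):
    """Raised when snapshot JSON does not match the documented schema."""


class ReviewStatus(str, enum.Enum):
    """Lifecycle state of evidence items and assertions."""

    ACCEPTED = "accepted"
    SUBMITTED = "submitted"
    REJECTED = "rejected"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.value


#: Default status filter: most downstream workflows want curated or pending
#: content and exclude rejected records.
DEFAULT_STATUSES = frozenset({ReviewStatus.ACCEPTED, ReviewStatus.SUBMITTED})


@dataclass(frozen=True, order=True)
class RecordIdentifier:
    """Stable public identifier of a first-class knowledgebase record."""

    record_type: str
    record_id: int

    def __post_init__(self) -> None:
        if self.record_type not in RECORD_TYPES:
            raise SnapshotSchemaError(
                f"unknown record_type {self.record_type!r} (id={self.record_id})"
            )
        if not isinstance(self.record_id, int) or self.record_id < 1:
            raise SnapshotSchemaError(
                f"record_id must be a positive integer, got {self.record_id!r}"
            )


@dataclass(frozen=True)
class AttributeBlob:
    """Composite data entity (disease, drug, ...) that is never independently
    addressable: it carries no identifier and is never cached standalone."""

    name: str
    payload: tuple[tuple[str, Any], ...]

    @classmethod
    def from_dict(cls, name: str, payload: Mapping[str, Any]) -> "AttributeBlob":
        return cls(name=name, payload=tuple(sorted(payload.items())))

    def to_dict(self) -> dict[str, Any]:
        return dict(self.payload)

    def get(self, key: str, default: Any = None) -> Any:
        return self.to_dict().get(key, default)


@dataclass
class Coordinates:
    """Genomic coordinates of a variant; compound variants (e.g. fusions)
    carry a second chromosome/start/stop set."""

    reference_build: str = DEFAULT_BUILD
    chromosome: str | None = None
    start: int | None = None
    stop: int | None = None
    reference_bases: str | None = None
    variant_bases: str | None = None
    chromosome2: str | None = None
    start2: int | None = None
    stop2: int | None = None
    representative_transcript: str | None = None

    def __post_init__(self) -> None:
        if self.chromosome is not None:
            self.chromosome = normalize_chromosome(self.chromosome)
        if self.chromosome2 is not None:
            self.chromosome2 = normalize_chromosome(self.chromosome2)
        for attr in ("reference_bases", "variant_bases"):
            val = getattr(self, attr)
            if val is not None:
                val = val.upper()
                if not is_valid_base_string(val):
                    raise SnapshotSchemaError(
                        f"{attr} contains non-nucleotide characters: {val!r}"
                    )
                setattr(self, attr, val)
        if self.start is not None and self.stop is not None and self.start > self.stop:
            raise SnapshotSchemaError(f"start > stop: {self.start} > {self.stop}")
        if self.chromosome2 is not None:
            if self.start2 is None or self.stop2 is None:
                raise SnapshotSchemaError("chromosome2 present without start2/stop2")
            if self.start2 > self.stop2:
                raise SnapshotSchemaError(f"start2 > stop2: {self.start2} > {self.stop2}")

    @property
    def has_primary(self) -> bool:
        return (
            self.chromosome is not None
            and self.start is not None
            and self.stop is not None
        )

    @property
    def is_compound(self) -> bool:
        return self.chromosome2 is not None


class KbRecord:
    """Base class for first-class records.

    Equality and hashing are by ``(record_type, record_id)`` only, so a
    :class:`PartialRecord` stub compares equal to the fully populated record
    it stands in for.
    """

    identifier: RecordIdentifier

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KbRecord):
            return NotImplemented
        return self.identifier == other.identifier

    def __hash__(self) -> int:
        return hash(self.identifier)

    @property
    def id(self) -> int:
        return self.identifier.record_id

    @property
    def type(self) -> str:
        return self.identifier.record_type


@dataclass(eq=False)
class PartialRecord(KbRecord):
    """Stub standing in for a record not present in the snapshot: it carries
    only the identifier and compares equal to its full counterpart."""

    identifier: RecordIdentifier

    def __repr__(self) -> str:
        return f"PartialRecord({self.identifier.record_type}, {self.identifier.record_id})"


@dataclass(eq=False)
class Gene(KbRecord):
    identifier: RecordIdentifier
    name: str = ""
    aliases: list[str] = field(default_factory=list)
    description: str = ""
    variants: list["VariantRecord"] = field(default_factory=list, repr=False)


@dataclass(eq=False)
class Source(KbRecord):
    identifier: RecordIdentifier
    citation: str = ""
    source_type: str = ""
    evidence: list["EvidenceItem"] = field(default_factory=list, repr=False)


@dataclass(eq=False)
class EvidenceItem(KbRecord):
    identifier: RecordIdentifier
    variant_id: RecordIdentifier | None = None
    status: ReviewStatus = ReviewStatus.SUBMITTED
    evidence_level: str = "E"
    evidence_direction: str = ""
    clinical_significance: str = ""
    disease: AttributeBlob | None = None
    drugs: list[AttributeBlob] = field(default_factory=list)
    source_id: RecordIdentifier | None = None
    rating: int | None = None
    # materialized by resolve_links
    variant: KbRecord | None = field(default=None, repr=False)
    source: KbRecord | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.evidence_level not in EVIDENCE_LEVELS:
            raise SnapshotSchemaError(
                f"evidence_level must be one of {EVIDENCE_LEVELS}, "
                f"got {self.evidence_level!r} (evidence {self.identifier.record_id})"
            )
        if self.rating is not None and not 1 <= self.rating <= 5:
            raise SnapshotSchemaError(f"rating out of range 1-5: {self.rating}")


@dataclass(eq=False)
class Assertion(KbRecord):
    identifier: RecordIdentifier
    variant_id: RecordIdentifier | None = None
    status: ReviewStatus = ReviewStatus.SUBMITTED
    amp_category: str | None = None
    evidence_ids: list[RecordIdentifier] = field(default_factory=list)
    disease: AttributeBlob | None = None
    drugs: list[AttributeBlob] = field(default_factory=list)
    # materialized by resolve_links
    variant: KbRecord | None = field(default=None, repr=False)
    evidence: list[KbRecord] = field(default_factory=list, repr=False)


@dataclass(eq=False)
class VariantRecord(KbRecord):
    identifier: RecordIdentifier
    gene_id: RecordIdentifier | None = None
    name: str = ""
    aliases: list[str] = field(default_factory=list)
    coordinates: Coordinates = field(default_factory=Coordinates)
    variant_types: list[str] = field(default_factory=list)
    # materialized by resolve_links
    gene: KbRecord | None = field(default=None, repr=False)
    evidence: list[EvidenceItem] = field(default_factory=list, repr=False)
    assertions: list[Assertion] = field(default_factory=list, repr=False)


class RecordCollection:
    """All records of one snapshot keyed by :class:`RecordIdentifier`.

    ``dangling`` lists ``(owner, field_name, missing_identifier)`` triples for
    link fields that do not resolve within the snapshot.
    """

    def __init__(self, reference_build: str = DEFAULT_BUILD) -> None:
        self._records: dict[RecordIdentifier, KbRecord] = {}
        self.reference_build = reference_build
        self.dangling: list[tuple[RecordIdentifier, str, RecordIdentifier]] = []
        self.resolved = False

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[KbRecord]:
        return iter(self._records.values())

    def __contains__(self, identifier: RecordIdentifier) -> bool:
        return identifier in self._records

    def get(self, identifier: RecordIdentifier) -> KbRecord | None:
        return self._records.get(identifier)

    def add(self, record: KbRecord) -> None:
        if record.identifier in self._records:
            raise SnapshotSchemaError(f"duplicate record {record.identifier}")
        self._records[record.identifier] = record

    def _of_type(self, record_type: str) -> list[KbRecord]:
        return sorted(
            (r for r in self._records.values() if r.type == record_type),
            key=lambda r: r.id,
        )

    @property
    def genes(self) -> list[Gene]:
        return self._of_type("gene")  # type: ignore[return-value]

    @property
    def variants(self) -> list[VariantRecord]:
        return self._of_type("variant")  # type: ignore[return-value]

    @property
    def evidence_items(self) -> list[EvidenceItem]:
        return self._of_type("evidence")  # type: ignore[return-value]

    @property
    def assertions(self) -> list[Assertion]:
        return self._of_type("assertion")  # type: ignore[return-value]

    @property
    def sources(self) -> list[Source]:
        return self._of_type("source")  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Parsing


def _ident(record_type: str, raw: Any, context: str) -> RecordIdentifier:
    if not isinstance(raw, int) or isinstance(raw, bool) or raw < 1:
        raise SnapshotSchemaError(f"{context}: id must be a positive integer, got {raw!r}")
    return RecordIdentifier(record_type, raw)


def _blob(name: str, raw: Any, context: str) -> AttributeBlob | None:
    if raw is None:
        return None
    if not isinstance(raw, dict):
        raise SnapshotSchemaError(f"{context}: {name} must be an object")
    return AttributeBlob.from_dict(name, raw)


def _coordinates(raw: Any, build: str) -> Coordinates:
    if raw is None:
        return Coordinates(reference_build=build)
    if not isinstance(raw, dict):
        raise SnapshotSchemaError("coordinates must be an object")
    allowed = {
        "chromosome",
        "start",
        "stop",
        "reference_bases",
        "variant_bases",
        "chromosome2",
        "start2",
        "stop2",
        "representative_transcript",
        "reference_build",
    }
    unknown = set(raw) - allowed
    if unknown:
        raise SnapshotSchemaError(f"unknown coordinate fields: {sorted(unknown)}")
    return Coordinates(reference_build=raw.get("reference_build", build), **{
        k: raw[k] for k in allowed - {"reference_build"} if k in raw
    })


def _read_stream(source: str | os.PathLike | bytes | BinaryIO | io.IOBase) -> bytes:
    if isinstance(source, bytes):
        data = source
    elif isinstance(source, (str, os.PathLike)):
        with open(source, "rb") as fh:
            data = fh.read()
    else:
        data = source.read()
        if isinstance(data, str):
            data = data.encode("utf-8")
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    return data


def parse_snapshot(source: str | os.PathLike | bytes | BinaryIO) -> RecordCollection:
    """Parse a snapshot JSON document (path, bytes, or binary stream; plain or
    gzip) into a :class:`RecordCollection` with unresolved link identifiers.

    Raises :class:`SnapshotParseError` (naming the byte offset) for malformed
    JSON and :class:`SnapshotSchemaError` for schema violations.
    """
    data = _read_stream(source)
    try:
        doc = json.loads(data)
    except json.JSONDecodeError as exc:
        raise SnapshotParseError(
            f"malformed snapshot JSON at byte offset {exc.pos}: {exc.msg}"
        ) from exc
    return snapshot_from_dict(doc)


def snapshot_from_dict(doc: Any) -> RecordCollection:
    if not isinstance(doc, dict):
        raise SnapshotSchemaError("snapshot must be a JSON object")
    unknown = set(doc) - set(_SECTION_TYPES) - {"format", "version", "reference_build"}
    if unknown:
        raise SnapshotSchemaError(f"unknown snapshot sections: {sorted(unknown)}")
    if doc.get("format", SNAPSHOT_FORMAT) != SNAPSHOT_FORMAT:
        raise SnapshotSchemaError(f"unknown snapshot format {doc.get('format')!r}")

    build = doc.get("reference_build", DEFAULT_BUILD)
    collection = RecordCollection(reference_build=build)

    for section, record_type in _SECTION_TYPES.items():
        entries = doc.get(section, [])
        if not isinstance(entries, list):
            raise SnapshotSchemaError(f"section {section!r} must be an array")
        for raw in entries:
            if not isinstance(raw, dict):
                raise SnapshotSchemaError(f"entries of {section!r} must be objects")
            collection.add(_parse_entity(record_type, raw, build))

    _flag_dangling(collection)
    return collection


def _parse_entity(record_type: str, raw: Mapping[str, Any], build: str) -> KbRecord:
    ident = _ident(record_type, raw.get("id"), record_type)
    ctx = f"{record_type} {ident.record_id}"
    if record_type == "gene":
        return Gene(
            identifier=ident,
            name=raw.get("name", ""),
            aliases=list(raw.get("aliases", [])),
            description=raw.get("description", ""),
        )
    if record_type == "variant":
        return VariantRecord(
            identifier=ident,
            gene_id=_ident("gene", raw["gene_id"], ctx) if raw.get("gene_id") else None,
            name=raw.get("name", ""),
            aliases=list(raw.get("aliases", [])),
            coordinates=_coordinates(raw.get("coordinates"), build),
            variant_types=list(raw.get("variant_types", [])),
        )
    if record_type == "evidence":
        return EvidenceItem(
            identifier=ident,
            variant_id=_ident("variant", raw["variant_id"], ctx)
            if raw.get("variant_id")
            else None,
            status=ReviewStatus(raw.get("status", "submitted")),
            evidence_level=raw.get("evidence_level", "E"),
            evidence_direction=raw.get("evidence_direction", ""),
            clinical_significance=raw.get("clinical_significance", ""),
            disease=_blob("disease", raw.get("disease"), ctx),
            drugs=[
                b
                for d in raw.get("drugs", [])
                if (b := _blob("drug", d, ctx)) is not None
            ],
            source_id=_ident("source", raw["source_id"], ctx)
            if raw.get("source_id")
            else None,
            rating=raw.get("rating"),
        )
    if record_type == "assertion":
        return Assertion(
            identifier=ident,
            variant_id=_ident("variant", raw["variant_id"], ctx)
            if raw.get("variant_id")
            else None,
            status=ReviewStatus(raw.get("status", "submitted")),
            amp_category=raw.get("amp_category"),
            evidence_ids=[
                _ident("evidence", e, ctx) for e in raw.get("evidence_ids", [])
            ],
            disease=_blob("disease", raw.get("disease"), ctx),
            drugs=[
                b
                for d in raw.get("drugs", [])
                if (b := _blob("drug", d, ctx)) is not None
            ],
        )
    if record_type == "source":
        return Source(
            identifier=ident,
            citation=raw.get("citation", ""),
            source_type=raw.get("source_type", ""),
        )
    # variant_group / user / organization: identity-only records for now
    return PartialRecord(identifier=ident)


def _link_fields(record: KbRecord) -> list[tuple[str, RecordIdentifier]]:
    links: list[tuple[str, RecordIdentifier]] = []
    if isinstance(record, VariantRecord) and record.gene_id is not None:
        links.append(("gene_id", record.gene_id))
    elif isinstance(record, EvidenceItem):
        if record.variant_id is not None:
            links.append(("variant_id", record.variant_id))
        if record.source_id is not None:
            links.append(("source_id", record.source_id))
    elif isinstance(record, Assertion):
        if record.variant_id is not None:
            links.append(("variant_id", record.variant_id))
        links.extend(("evidence_ids", e) for e in record.evidence_ids)
    return links


def _flag_dangling(collection: RecordCollection) -> None:
    collection.dangling = [
        (record.identifier, field_name, target)
        for record in collection
        for field_name, target in _link_fields(record)
        if target not in collection
    ]


# ---------------------------------------------------------------------------
# Link resolution


def resolve_links(collection: RecordCollection) -> RecordCollection:
    """Materialize link identifiers into shared object references, in place.

    Dangling identifiers resolve to :class:`PartialRecord` stubs; traversal
    never raises.  Returns the same collection for chaining.
    """
    partials: dict[RecordIdentifier, PartialRecord] = {}

    def lookup(ident: RecordIdentifier) -> KbRecord:
        record = collection.get(ident)
        if record is not None:
            return record
        return partials.setdefault(ident, PartialRecord(identifier=ident))

    for variant in collection.variants:
        variant.evidence = []
        variant.assertions = []
        variant.gene = lookup(variant.gene_id) if variant.gene_id else None
    for gene in collection.genes:
        gene.variants = []
    for source in collection.sources:
        source.evidence = []

    for ev in collection.evidence_items:
        if ev.variant_id is not None:
            ev.variant = lookup(ev.variant_id)
            if isinstance(ev.variant, VariantRecord):
                ev.variant.evidence.append(ev)
        if ev.source_id is not None:
            ev.source = lookup(ev.source_id)
            if isinstance(ev.source, Source):
                ev.source.evidence.append(ev)

    for assertion in collection.assertions:
        if assertion.variant_id is not None:
            assertion.variant = lookup(assertion.variant_id)
            if isinstance(assertion.variant, VariantRecord):
                assertion.variant.assertions.append(assertion)
        assertion.evidence = [lookup(e) for e in assertion.evidence_ids]

    for variant in collection.variants:
        if isinstance(variant.gene, Gene):
            variant.gene.variants.append(variant)

    collection.resolved = True
    return collection


# ---------------------------------------------------------------------------
# Status filtering


def _coerce_statuses(allowed: Iterable[ReviewStatus | str]) -> frozenset[ReviewStatus]:
    coerced = frozenset(ReviewStatus(s) for s in allowed)
    if not coerced:
        raise ValueError("allowed status set must be non-empty")
    return coerced


def filter_by_status(
    collection: RecordCollection,
    allowed: Iterable[ReviewStatus | str] = DEFAULT_STATUSES,
) -> RecordCollection:
    """Return a new collection restricted to evidence/assertions whose status
    is in ``allowed``.  Genes and variants are retained with filtered link
    lists; the input collection is not modified.
    """
    statuses = _coerce_statuses(allowed)
    filtered = RecordCollection(reference_build=collection.reference_build)

    keep: dict[RecordIdentifier, KbRecord] = {}
    for record in collection:
        if isinstance(record, (EvidenceItem, Assertion)):
            if record.status in statuses:
                keep[record.identifier] = record
        else:
            keep[record.identifier] = record

    for identifier, record in keep.items():
        if isinstance(record, VariantRecord):
            clone = copy.copy(record)
            clone.evidence = [e for e in record.evidence if e.status in statuses]
            clone.assertions = [a for a in record.assertions if a.status in statuses]
            filtered.add(clone)
        else:
            filtered.add(record)

    _flag_dangling(filtered)
    filtered.resolved = collection.resolved
    return filtered


# ---------------------------------------------------------------------------
# Serialization (inverse of parse_snapshot)


def snapshot_to_dict(collection: RecordCollection) -> dict[str, Any]:
    """Serialize a collection back to the snapshot JSON dialect."""
    doc: dict[str, Any] = {
        "format": SNAPSHOT_FORMAT,
        "version": SNAPSHOT_VERSION,
        "reference_build": collection.reference_build,
    }
    for section in _SECTION_TYPES:
        doc[section] = []
    for record in sorted(collection, key=lambda r: (r.type, r.id)):
        doc[_TYPE_SECTIONS[record.type]].append(_entity_to_dict(record))
    return doc


def _coords_to_dict(c: Coordinates) -> dict[str, Any] | None:
    out = {
        k: getattr(c, k)
        for k in (
            "chromosome",
            "start",
            "stop",
            "reference_bases",
            "variant_bases",
            "chromosome2",
            "start2",
            "stop2",
            "representative_transcript",
        )
        if getattr(c, k) is not None
    }
    return out or None


def _entity_to_dict(record: KbRecord) -> dict[str, Any]:
    out: dict[str, Any] = {"id": record.id}
    if isinstance(record, Gene):
        out.update(name=record.name, aliases=record.aliases, description=record.description)
    elif isinstance(record, VariantRecord):
        out.update(
            name=record.name,
            aliases=record.aliases,
            variant_types=record.variant_types,
        )
        if record.gene_id is not None:
            out["gene_id"] = record.gene_id.record_id
        coords = _coords_to_dict(record.coordinates)
        if coords is not None:
            out["coordinates"] = coords
    elif isinstance(record, EvidenceItem):
        out.update(
            status=record.status.value,
            evidence_level=record.evidence_level,
            evidence_direction=record.evidence_direction,
            clinical_significance=record.clinical_significance,
        )
        if record.variant_id is not None:
            out["variant_id"] = record.variant_id.record_id
        if record.source_id is not None:
            out["source_id"] = record.source_id.record_id
        if record.disease is not None:
            out["disease"] = record.disease.to_dict()
        if record.drugs:
            out["drugs"] = [d.to_dict() for d in record.drugs]
        if record.rating is not None:
            out["rating"] = record.rating
    elif isinstance(record, Assertion):
        out.update(status=record.status.value)
        if record.variant_id is not None:
            out["variant_id"] = record.variant_id.record_id
        if record.amp_category is not None:
            out["amp_category"] = record.amp_category
        if record.evidence_ids:
            out["evidence_ids"] = [e.record_id for e in record.evidence_ids]
        if record.disease is not None:
            out["disease"] = record.disease.to_dict()
        if record.drugs:
            out["drugs"] = [d.to_dict() for d in record.drugs]
    elif isinstance(record, Source):
        out.update(citation=record.citation, source_type=record.source_type)
    return out


def snapshot_to_json(collection: RecordCollection) -> str:
    """Canonical (sorted-keys) JSON serialization of a collection."""
    return json.dumps(snapshot_to_dict(collection), sort_keys=True, indent=1)
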