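"""VCF 4.2 export of variant records with per-evidence/assertion CSQ entries.

Each exported variant becomes one VCF record; its clinical statements are
encoded in the ``CSQ`` INFO field, one comma-separated entry per evidence
item or assertion, with pipe-delimited fields declared in the header.  The
``EntityType`` field discriminates evidence entries from assertion entries.

Allele dialect (no reference genome is assumed, so indels cannot be
left-anchored against a FASTA):

* SNVs/complex variants with both curated alleles: REF/ALT emitted verbatim.
* Pure insertions (variant bases only): ``POS=start, REF=N, ALT=N+bases``.
* Pure deletions (reference bases only): ``POS=start-1, REF=N+bases, ALT=N``.

This padding dialect is stated in the VCF header.  Fusions and other
variants with a second coordinate set are not exportable and are skipped
with a warning, as are variants missing required coordinate fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, NamedTuple

from .genome import chromosome_sort_key
from .records import (
    DEFAULT_STATUSES,
    Assertion,
    EvidenceItem,
    Gene,
    ReviewStatus,
    VariantRecord,
)

logger = logging.getLogger(__name__)

#: Ordered CSQ field names declared in the VCF header.  ``EntityType`` is the
#: evidence/assertion discriminator; level/rating fields apply to evidence
#: entries and the tier field to assertion entries (blank otherwise).
CSQ_FIELDS = (
    "Allele",
    "GeneSymbol",
    "VariantName",
    "VariantID",
    "VariantAliases",
    "VariantTypes",
    "EntityType",
    "EntityID",
    "EntityStatus",
    "EvidenceLevel",
    "EvidenceDirection",
    "ClinicalSignificance",
    "Disease",
    "Drugs",
    "EvidenceRating",
    "AssertionTier",
    "Citation",
)

#: Characters that survive encoding unescaped ('_' only ever encodes a space).
_SAFE_CHARS = frozenset(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789.:/-"
)

_VCF_RESERVED = frozenset(" ;,=|\t\n")

#: Joins multiple values (e.g. drug names) inside one CSQ field; '&' is never
#: produced by the encoder, so the join is unambiguous.
MULTI_VALUE_SEPARATOR = "&"


class WriterStateError(RuntimeError):
    """add_record/write_records called on a finalized writer."""


def encode_csq_value(raw: str) -> str:
    """Escape free text for use as a CSQ field value.

    Reversible: literal underscores are hex-escaped first, spaces become
    underscores, and every character outside ``[A-Za-z0-9_.:/-]`` is
    percent-hex-encoded (uppercase, UTF-8 bytes).  The output never contains
    VCF-reserved characters.
    """
    out: list[str] = []
    for ch in raw:
        if ch == "_":
            out.append("%5F")
        elif ch == " ":
            out.append("_")
        elif ch in _SAFE_CHARS:
            out.append(ch)
        else:
            out.extend(f"%{b:02X}" for b in ch.encode("utf-8"))
    return "".join(out)


def decode_csq_value(encoded: str) -> str:
    """Inverse of :func:`encode_csq_value`."""
    buf = bytearray()
    i = 0
    while i < len(encoded):
        ch = encoded[i]
        if ch == "%":
            if i + 3 > len(encoded):
                raise ValueError(f"truncated escape in {encoded!r}")
            buf.extend(bytes.fromhex(encoded[i + 1 : i + 3]))
            i += 3
        elif ch == "_":
            buf.extend(b" ")
            i += 1
        else:
            buf.extend(ch.encode("utf-8"))
            i += 1
    return buf.decode("utf-8")


class VcfValidity(NamedTuple):
    valid: bool
    reason: str | None


def is_valid_for_vcf(variant: VariantRecord) -> VcfValidity:
    """Decide whether a variant can be written to VCF, with a reason code.

    Requirements: chromosome and start present; no second coordinate set;
    and at least one of reference/variant bases (both for SNVs and complex
    variants, variant bases alone for insertions, reference bases alone for
    deletions).
    """
    c = variant.coordinates
    if c.chromosome is None:
        return VcfValidity(False, "missing_chromosome")
    if c.start is None:
        return VcfValidity(False, "missing_position")
    if c.is_compound:
        return VcfValidity(False, "second_coordinate_set")
    if c.reference_bases is None and c.variant_bases is None:
        return VcfValidity(False, "missing_sequence")
    return VcfValidity(True, None)


def _alleles(variant: VariantRecord) -> tuple[int, str, str]:
    """(pos, REF, ALT) under the documented padding dialect; requires a
    variant that passed :func:`is_valid_for_vcf`."""
    c = variant.coordinates
    if c.reference_bases is not None and c.variant_bases is not None:
        return c.start, c.reference_bases, c.variant_bases
    if c.variant_bases is not None:  # pure insertion
        return c.start, "N", "N" + c.variant_bases
    # pure deletion
    return max(c.start - 1, 1), "N" + c.reference_bases, "N"


@dataclass(frozen=True)
class CsqEntry:
    """One pipe-joined CSQ entry; ``values`` aligns with :data:`CSQ_FIELDS`."""

    values: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(CSQ_FIELDS):
            raise ValueError(
                f"CSQ entry has {len(self.values)} fields, expected {len(CSQ_FIELDS)}"
            )

    def render(self) -> str:
        return "|".join(self.values)


def _entity_fields(entity: EvidenceItem | Assertion) -> dict[str, str]:
    disease = entity.disease.get("name", "") if entity.disease else ""
    drugs = MULTI_VALUE_SEPARATOR.join(
        encode_csq_value(str(d.get("name", ""))) for d in entity.drugs
    )
    common = {
        "EntityID": str(entity.id),
        "EntityStatus": entity.status.value,
        "Disease": encode_csq_value(disease),
        "Drugs": drugs,
    }
    if isinstance(entity, EvidenceItem):
        citation = ""
        if entity.source is not None and hasattr(entity.source, "citation"):
            citation = entity.source.citation
        common.update(
            EntityType="evidence",
            EvidenceLevel=entity.evidence_level,
            EvidenceDirection=encode_csq_value(entity.evidence_direction),
            ClinicalSignificance=encode_csq_value(entity.clinical_significance),
            EvidenceRating=str(entity.rating) if entity.rating is not None else "",
            AssertionTier="",
            Citation=encode_csq_value(citation),
        )
    else:
        common.update(
            EntityType="assertion",
            EvidenceLevel="",
            EvidenceDirection="",
            ClinicalSignificance="",
            EvidenceRating="",
            AssertionTier=encode_csq_value(entity.amp_category or ""),
            Citation="",
        )
    return common


def build_csq_entries(
    variant: VariantRecord,
    allowed_statuses: Iterable[ReviewStatus | str] = DEFAULT_STATUSES,
) -> list[CsqEntry]:
    """One CSQ entry per status-passing evidence item and assertion linked to
    ``variant``, ordered evidence-then-assertion, ascending id."""
    statuses = frozenset(ReviewStatus(s) for s in allowed_statuses)
    if not statuses:
        raise ValueError("allowed_statuses must be non-empty")

    allele = _alleles(variant)[2] if is_valid_for_vcf(variant).valid else ""
    gene_symbol = variant.gene.name if isinstance(variant.gene, Gene) else ""
    variant_fields = {
        "Allele": allele,
        "GeneSymbol": encode_csq_value(gene_symbol),
        "VariantName": encode_csq_value(variant.name),
        "VariantID": str(variant.id),
        "VariantAliases": MULTI_VALUE_SEPARATOR.join(
            encode_csq_value(a) for a in variant.aliases
        ),
        "VariantTypes": MULTI_VALUE_SEPARATOR.join(
            encode_csq_value(t) for t in variant.variant_types
        ),
    }

    entities: list[EvidenceItem | Assertion] = [
        e for e in sorted(variant.evidence, key=lambda e: e.id) if e.status in statuses
    ]
    entities.extend(
        a for a in sorted(variant.assertions, key=lambda a: a.id) if a.status in statuses
    )

    entries = []
    for entity in entities:
        fields = {**variant_fields, **_entity_fields(entity)}
        entries.append(CsqEntry(tuple(fields[name] for name in CSQ_FIELDS)))
    return entries


@dataclass
class VcfRecordDraft:
    chromosome: str
    position: int
    id: str
    ref: str
    alt: str
    csq_entries: list[CsqEntry]


class VcfWriter:
    """Collects variant records and writes them as one VCF 4.2 document.

    Invalid variants (fusions, incomplete coordinates) are skipped with a
    logged warning rather than an exception.  Variants sharing a position
    are written as separate records, and duplicate ``add_record`` calls are
    not deduplicated.  ``write_records`` is single-shot.
    """

    def __init__(
        self, include_statuses: Iterable[ReviewStatus | str] = DEFAULT_STATUSES
    ) -> None:
        self.include_statuses = frozenset(ReviewStatus(s) for s in include_statuses)
        if not self.include_statuses:
            raise ValueError("include_statuses must be non-empty")
        self._variants: list[VariantRecord] = []
        self.skipped: list[tuple[VariantRecord, str]] = []
        self.dropped_no_annotations: list[VariantRecord] = []
        self._finalized = False

    def __len__(self) -> int:
        return len(self._variants)

    def add_record(self, variant: VariantRecord) -> bool:
        """Queue a variant for output; returns False (and warns) if invalid."""
        if self._finalized:
            raise WriterStateError("writer already finalized")
        valid, reason = is_valid_for_vcf(variant)
        if not valid:
            self.skipped.append((variant, reason))
            logger.warning(
                "variant %d (%s) cannot be written to VCF: %s",
                variant.id,
                variant.name,
                reason,
            )
            return False
        self._variants.append(variant)
        return True

    def _drafts(self) -> list[VcfRecordDraft]:
        drafts = []
        for variant in self._variants:
            csq = build_csq_entries(variant, self.include_statuses)
            if not csq:
                self.dropped_no_annotations.append(variant)
                logger.warning(
                    "variant %d has no evidence/assertions with statuses %s; "
                    "not included in VCF",
                    variant.id,
                    sorted(s.value for s in self.include_statuses),
                )
                continue
            pos, ref, alt = _alleles(variant)
            drafts.append(
                VcfRecordDraft(
                    chromosome=variant.coordinates.chromosome,
                    position=pos,
                    id=str(variant.id),
                    ref=ref,
                    alt=alt,
                    csq_entries=csq,
                )
            )
        drafts.sort(key=lambda d: (chromosome_sort_key(d.chromosome), d.position, d.id))
        return drafts

    def write_records(self, stream: IO[str] | str) -> int:
        """Write the VCF document; returns the number of records written."""
        if self._finalized:
            raise WriterStateError("writer already finalized")
        self._finalized = True
        drafts = self._drafts()

        own = isinstance(stream, str)
        fh: IO[str] = open(stream, "w") if own else stream  # noqa: SIM115
        try:
            self._write_header(fh, drafts)
            for d in drafts:
                csq = ",".join(entry.render() for entry in d.csq_entries)
                fh.write(
                    f"{d.chromosome}\t{d.position}\t{d.id}\t{d.ref}\t{d.alt}\t.\t.\t"
                    f"CSQ={csq}\n"
                )
        finally:
            if own:
                fh.close()
        return len(drafts)

    def _write_header(self, fh: IO[str], drafts: list[VcfRecordDraft]) -> None:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            "##ALLELE_DIALECT=insertions padded as REF=N/ALT=N+bases at start; "
            "deletions as REF=N+bases/ALT=N at start-1 (no reference FASTA)\n"
        )
        for chrom in sorted(
            {d.chromosome for d in drafts}, key=chromosome_sort_key
        ):
            fh.write(f"##contig=<ID={chrom}>\n")
        fmt = "|".join(CSQ_FIELDS)
        fh.write(
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="Clinical '
            f'annotations, one entry per evidence item or assertion. Format: {fmt}">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")


def write_vcf(
    variants: Iterable[VariantRecord],
    stream: IO[str] | str,
    include_statuses: Iterable[ReviewStatus | str] = DEFAULT_STATUSES,
) -> VcfWriter:
    """Convenience: add every variant to a writer and write the document."""
    writer = VcfWriter(include_statuses)
    for v in variants:
        writer.add_record(v)
    writer.write_records(stream)
    return writer
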