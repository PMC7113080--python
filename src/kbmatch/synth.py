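"""Synthetic knowledgebase snapshots and query cohorts with known ground truth.

Everything is generated from a seeded ``random.Random`` using integer
arithmetic only, so a fixed seed yields byte-identical snapshots across
platforms.  Coordinates are drawn from a small simulated genome (5
chromosomes x 1 Mb) to keep overlap densities controllable; cohort
background variants are placed in a disjoint region (2-3 Mb) so unplanted
rows cannot accidentally overlap knowledgebase variants.

Per-row truth labels (``exact`` / ``overlap`` / ``none``) are computed with
the same match predicates the search engine uses, so running the real
pipeline over a generated cohort reproduces them exactly.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import pandas as pd

from .records import EVIDENCE_LEVELS, SNAPSHOT_FORMAT, SNAPSHOT_VERSION
from .search import CoordinateIndexEntry, CoordinateQuery, MatchMode, match

GENOME_CHROMOSOMES = ("1", "2", "3", "4", "5")
GENOME_CHROM_LENGTH = 1_000_000
#: Background cohort variants live here: disjoint from every kb coordinate.
BACKGROUND_OFFSET = 2_000_000

_BASES = "ACGT"

_DISEASES = (
    "Lung Adenocarcinoma",
    "Chronic Myeloid Leukemia",
    "Colorectal Cancer",
    "Melanoma",
    "Breast Cancer",
    "Glioblastoma",
)
_DRUGS = ("Imatinib", "Trametinib", "Cetuximab", "Osimertinib", "Vemurafenib")
_SIGNIFICANCES = ("Sensitivity/Response", "Resistance", "Poor Outcome", "Positive")
_DIRECTIONS = ("Supports", "Does Not Support")
_TIERS = ("Tier I", "Tier II")


@dataclass
class GeneratorConfig:
    """Tunable knobs of the synthetic generator; all randomness flows from
    ``seed``.  ``variants_per_sample_mean`` defaults to the reported cohort
    average of 6.88 variants per tumor."""

    seed: int = 0
    n_genes: int = 10
    n_variants: int = 100
    n_evidence: int = 200
    n_assertions: int = 10
    fraction_compound: float = 0.05
    fraction_missing_coords: float = 0.05
    status_weights: Mapping[str, float] = field(
        default_factory=lambda: {"accepted": 0.7, "submitted": 0.2, "rejected": 0.1}
    )
    level_weights: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.05, "B": 0.25, "C": 0.30, "D": 0.25, "E": 0.15}
    )
    cohort_size: int = 100
    variants_per_sample_mean: float = 6.88
    planted_exact_fraction: float = 0.076
    planted_overlap_fraction: float = 0.10

    def validate(self) -> None:
        for name in (
            "fraction_compound",
            "fraction_missing_coords",
            "planted_exact_fraction",
            "planted_overlap_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.planted_exact_fraction + self.planted_overlap_fraction > 1.0:
            raise ValueError("planted fractions must sum to at most 1")
        for name in ("n_genes", "n_variants", "n_evidence", "n_assertions", "cohort_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("status_weights", "level_weights"):
            weights = getattr(self, name)
            if weights and abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if self.variants_per_sample_mean < 0:
            raise ValueError("variants_per_sample_mean must be >= 0")


@dataclass
class GroundTruth:
    """Generator-side ledger: every indexable coordinate row, which variants
    are exact-plantable, and each variant's evidence statuses/levels."""

    entries: list[CoordinateIndexEntry]
    plantable: list[CoordinateIndexEntry]  # simple (non-compound) rows
    evidence_by_variant: dict[int, list[tuple[str, str]]]  # id -> [(status, level)]
    ref_by_variant: dict[int, str | None]
    n_compound: int = 0
    n_missing: int = 0


@dataclass
class SyntheticCohort:
    """A MAF-like table, per-row truth labels aligned with its rows, and the
    full sample list (including samples with zero variants)."""

    table: pd.DataFrame
    labels: list[str]
    barcodes: list[str]


def _weighted_choice(rng: random.Random, weights: Mapping[str, float]) -> str:
    u = rng.random()
    acc = 0.0
    items = sorted(weights.items())
    for value, w in items:
        acc += w
        if u < acc:
            return value
    return items[-1][0]


def _poisson(rng: random.Random, mean: float) -> int:
    """Knuth's algorithm; deterministic for a seeded rng, fine for small means."""
    if mean <= 0:
        return 0
    limit = math.exp(-mean)
    k = 0
    p = 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def _base(rng: random.Random, exclude: str | None = None) -> str:
    choices = [b for b in _BASES if b != exclude]
    return choices[rng.randrange(len(choices))]


def generate_knowledgebase(config: GeneratorConfig) -> tuple[dict[str, Any], GroundTruth]:
    """Build a snapshot document plus its ground-truth ledger.

    Every variant gets at least one evidence item while evidence remains
    (round-robin base assignment), so level summaries are well-defined for
    any matched variant.  Same config => identical document.
    """
    config.validate()
    rng = random.Random(config.seed)

    doc: dict[str, Any] = {
        "format": SNAPSHOT_FORMAT,
        "version": SNAPSHOT_VERSION,
        "reference_build": "GRCh37",
        "genes": [],
        "variants": [],
        "evidence_items": [],
        "assertions": [],
        "sources": [],
        "variant_groups": [],
        "users": [],
        "organizations": [],
    }
    truth = GroundTruth(
        entries=[], plantable=[], evidence_by_variant={}, ref_by_variant={}
    )

    for gid in range(1, config.n_genes + 1):
        doc["genes"].append(
            {
                "id": gid,
                "name": f"GENE{gid}",
                "aliases": [f"G{gid}ALT"] if rng.random() < 0.3 else [],
                "description": f"synthetic gene {gid}",
            }
        )

    n_sources = max(1, config.n_evidence // 3) if config.n_evidence else 0
    for sid in range(1, n_sources + 1):
        doc["sources"].append(
            {
                "id": sid,
                "citation": f"Synth et al., {2000 + sid % 25}",
                "source_type": "PubMed",
            }
        )

    for vid in range(1, config.n_variants + 1):
        entry: dict[str, Any] = {
            "id": vid,
            "name": f"VAR{vid}",
            "aliases": [f"VAR{vid}.1"] if rng.random() < 0.2 else [],
            "variant_types": ["missense_variant"],
        }
        if config.n_genes:
            entry["gene_id"] = rng.randrange(1, config.n_genes + 1)
        roll = rng.random()
        if roll < config.fraction_missing_coords:
            truth.n_missing += 1
        elif roll < config.fraction_missing_coords + config.fraction_compound:
            # compound (fusion-like): two coordinate sets, no allele strings
            c1, c2 = (
                GENOME_CHROMOSOMES[rng.randrange(len(GENOME_CHROMOSOMES))],
                GENOME_CHROMOSOMES[rng.randrange(len(GENOME_CHROMOSOMES))],
            )
            s1 = rng.randrange(1, GENOME_CHROM_LENGTH - 100)
            s2 = rng.randrange(1, GENOME_CHROM_LENGTH - 100)
            l1, l2 = rng.randrange(1, 100), rng.randrange(1, 100)
            entry["coordinates"] = {
                "chromosome": c1,
                "start": s1,
                "stop": s1 + l1,
                "chromosome2": c2,
                "start2": s2,
                "stop2": s2 + l2,
            }
            entry["variant_types"] = ["fusion"]
            truth.n_compound += 1
            for chrom, start, stop in ((c1, s1, s1 + l1), (c2, s2, s2 + l2)):
                truth.entries.append(
                    CoordinateIndexEntry(chrom, start, stop, None, 0, vid)
                )
            truth.ref_by_variant[vid] = None
        else:
            chrom = GENOME_CHROMOSOMES[rng.randrange(len(GENOME_CHROMOSOMES))]
            start = rng.randrange(1, GENOME_CHROM_LENGTH - 100)
            kind = rng.random()
            coords: dict[str, Any] = {"chromosome": chrom, "start": start}
            if kind < 0.60:  # SNV
                ref = _base(rng)
                alt = _base(rng, exclude=ref)
                coords.update(stop=start, reference_bases=ref, variant_bases=alt)
            elif kind < 0.75:  # insertion: variant bases only
                alt = "".join(_base(rng) for _ in range(rng.randrange(1, 6)))
                coords.update(stop=start, variant_bases=alt)
                entry["variant_types"] = ["insertion"]
            elif kind < 0.90:  # deletion: reference bases only
                length = rng.randrange(1, 11)
                ref = "".join(_base(rng) for _ in range(length))
                coords.update(stop=start + length - 1, reference_bases=ref)
                entry["variant_types"] = ["deletion"]
            else:  # multi-base substitution over a range
                length = rng.randrange(2, 21)
                ref = "".join(_base(rng) for _ in range(length))
                alt = "".join(_base(rng) for _ in range(length))
                coords.update(stop=start + length - 1, reference_bases=ref, variant_bases=alt)
            entry["coordinates"] = coords
            row = CoordinateIndexEntry(
                chrom, start, coords["stop"], coords.get("variant_bases"), 0, vid
            )
            truth.entries.append(row)
            truth.plantable.append(row)
            truth.ref_by_variant[vid] = coords.get("reference_bases")
        doc["variants"].append(entry)

    for eid in range(1, config.n_evidence + 1):
        if not config.n_variants:
            break
        # round-robin guarantees every variant >= 1 evidence item when
        # n_evidence >= n_variants; remaining items land uniformly
        vid = (
            ((eid - 1) % config.n_variants) + 1
            if eid <= config.n_variants
            else rng.randrange(1, config.n_variants + 1)
        )
        status = _weighted_choice(rng, config.status_weights)
        level = _weighted_choice(rng, config.level_weights)
        ev: dict[str, Any] = {
            "id": eid,
            "variant_id": vid,
            "status": status,
            "evidence_level": level,
            "evidence_direction": _DIRECTIONS[rng.randrange(2)],
            "clinical_significance": _SIGNIFICANCES[rng.randrange(len(_SIGNIFICANCES))],
            "disease": {"name": _DISEASES[rng.randrange(len(_DISEASES))]},
            "source_id": rng.randrange(1, n_sources + 1),
            "rating": rng.randrange(1, 6),
        }
        if rng.random() < 0.6:
            ev["drugs"] = [{"name": _DRUGS[rng.randrange(len(_DRUGS))]}]
        doc["evidence_items"].append(ev)
        truth.evidence_by_variant.setdefault(vid, []).append((status, level))

    for aid in range(1, config.n_assertions + 1):
        if not truth.evidence_by_variant:
            break
        vid = sorted(truth.evidence_by_variant)[rng.randrange(len(truth.evidence_by_variant))]
        own_evidence = [
            e["id"] for e in doc["evidence_items"] if e["variant_id"] == vid
        ]
        rng.shuffle(own_evidence)
        doc["assertions"].append(
            {
                "id": aid,
                "variant_id": vid,
                "status": _weighted_choice(rng, config.status_weights),
                "amp_category": _TIERS[rng.randrange(2)],
                "evidence_ids": sorted(own_evidence[: rng.randrange(1, len(own_evidence) + 1)]),
                "disease": {"name": _DISEASES[rng.randrange(len(_DISEASES))]},
            }
        )

    return doc, truth


def snapshot_bytes(doc: Mapping[str, Any]) -> bytes:
    """Canonical byte serialization: same document => same bytes."""
    return json.dumps(doc, sort_keys=True, indent=1).encode("utf-8")


# ---------------------------------------------------------------------------
# Cohort generation


def _label_row(
    chrom: str,
    start: int,
    stop: int,
    alt: str | None,
    entries_by_chrom: Mapping[str, Sequence[CoordinateIndexEntry]],
) -> str:
    q = CoordinateQuery(chromosome=chrom, start=start, stop=stop, alt=alt)
    exact = False
    overlap = False
    for entry in entries_by_chrom.get(q.chromosome, ()):
        if match(q, entry, MatchMode.EXACT):
            exact = True
            break
        if match(q, entry, MatchMode.ANY):
            overlap = True
    if exact:
        return "exact"
    return "overlap" if overlap else "none"


def generate_cohort(config: GeneratorConfig, truth: GroundTruth) -> SyntheticCohort:
    """Generate a MAF-like cohort table with per-row truth labels.

    Each sample draws Poisson(``variants_per_sample_mean``) variants.  A row
    is, with probability ``planted_exact_fraction``, an exact copy of a
    plantable knowledgebase row; with ``planted_overlap_fraction``, a
    jittered (extended by 1-50 bases, different allele) overlap of one; and
    otherwise background placed in a region disjoint from the knowledgebase.
    Labels are recomputed against the ledger with the real match predicates,
    so chance collisions are labeled correctly.
    """
    config.validate()
    rng = random.Random(config.seed + 1)  # decoupled from snapshot stream

    entries_by_chrom: dict[str, list[CoordinateIndexEntry]] = {}
    for entry in truth.entries:
        entries_by_chrom.setdefault(entry.chromosome, []).append(entry)

    rows: list[dict[str, Any]] = []
    labels: list[str] = []
    barcodes: list[str] = []
    plantable = truth.plantable

    for s in range(1, config.cohort_size + 1):
        barcode = f"SAMPLE-{s:05d}"
        barcodes.append(barcode)
        for _ in range(_poisson(rng, config.variants_per_sample_mean)):
            u = rng.random()
            if plantable and u < config.planted_exact_fraction:
                src = plantable[rng.randrange(len(plantable))]
                chrom, start, stop, alt = src.chromosome, src.start, src.stop, src.alt
                ref = truth.ref_by_variant.get(src.variant_id)
            elif plantable and u < config.planted_exact_fraction + config.planted_overlap_fraction:
                src = plantable[rng.randrange(len(plantable))]
                d1 = rng.randrange(0, 51)
                d2 = rng.randrange(1, 51) if d1 == 0 else rng.randrange(0, 51)
                chrom = src.chromosome
                start = max(1, src.start - d1)
                stop = src.stop + d2
                alt = _base(rng, exclude=src.alt if src.alt and len(src.alt) == 1 else None)
                ref = _base(rng, exclude=alt)
            else:
                chrom = GENOME_CHROMOSOMES[rng.randrange(len(GENOME_CHROMOSOMES))]
                start = BACKGROUND_OFFSET + rng.randrange(1, GENOME_CHROM_LENGTH - 100)
                stop = start + (rng.randrange(0, 10) if rng.random() < 0.2 else 0)
                ref = _base(rng)
                alt = _base(rng, exclude=ref)
            rows.append(
                {
                    "Hugo_Symbol": "UNKNOWN",
                    "Tumor_Sample_Barcode": barcode,
                    "Chromosome": chrom,
                    "Start_Position": start,
                    "End_Position": stop,
                    "Reference_Allele": ref if ref else "-",
                    "Tumor_Seq_Allele2": alt if alt else "-",
                }
            )
            labels.append(_label_row(chrom, start, stop, alt, entries_by_chrom))

    columns = [
        "Hugo_Symbol",
        "Tumor_Sample_Barcode",
        "Chromosome",
        "Start_Position",
        "End_Position",
        "Reference_Allele",
        "Tumor_Seq_Allele2",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return SyntheticCohort(table=table, labels=labels, barcodes=barcodes)


def write_cohort_tsv(cohort: SyntheticCohort, path: str) -> None:
    cohort.table.to_csv(path, sep="\t", index=False)
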