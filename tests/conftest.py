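import json

import pytest

from kbmatch.records import parse_snapshot, resolve_links


def small_snapshot_dict() -> dict:
    """1 gene, 3 variants, 5 evidence (3 accepted / 1 submitted / 1 rejected),
    1 assertion, 2 sources.  Variant 2 lacks coordinates; variant 3 is a
    fusion (second coordinate set)."""
    return {
        "format": "kb-snapshot",
        "version": 1,
        "reference_build": "GRCh37",
        "genes": [{"id": 1, "name": "GENE1", "aliases": ["G1"], "description": "g"}],
        "variants": [
            {
                "id": 1,
                "gene_id": 1,
                "name": "V600E",
                "aliases": ["VAL600GLU"],
                "variant_types": ["missense_variant"],
                "coordinates": {
                    "chromosome": "7",
                    "start": 140453136,
                    "stop": 140453136,
                    "reference_bases": "A",
                    "variant_bases": "T",
                },
            },
            {"id": 2, "gene_id": 1, "name": "EXPRESSION", "variant_types": ["expression"]},
            {
                "id": 3,
                "gene_id": 1,
                "name": "FUSION",
                "variant_types": ["fusion"],
                "coordinates": {
                    "chromosome": "2",
                    "start": 100,
                    "stop": 200,
                    "chromosome2": "5",
                    "start2": 5000,
                    "stop2": 5100,
                },
            },
        ],
        "evidence_items": [
            {"id": 1, "variant_id": 1, "status": "accepted", "evidence_level": "A",
             "clinical_significance": "Sensitivity/Response", "evidence_direction": "Supports",
             "disease": {"name": "Melanoma"}, "drugs": [{"name": "Vemurafenib"}],
             "source_id": 1, "rating": 5},
            {"id": 2, "variant_id": 1, "status": "accepted", "evidence_level": "B",
             "disease": {"name": "Colorectal Cancer"}, "source_id": 1},
            {"id": 3, "variant_id": 1, "status": "rejected", "evidence_level": "C",
             "source_id": 2},
            {"id": 4, "variant_id": 3, "status": "submitted", "evidence_level": "D",
             "source_id": 2},
            {"id": 5, "variant_id": 3, "status": "accepted", "evidence_level": "E"},
        ],
        "assertions": [
            {"id": 1, "variant_id": 1, "status": "accepted", "amp_category": "Tier I",
             "evidence_ids": [1, 2], "disease": {"name": "Melanoma"}}
        ],
        "sources": [
            {"id": 1, "citation": "Chapman et al., 2011", "source_type": "PubMed"},
            {"id": 2, "citation": "Flaherty et al., 2012", "source_type": "PubMed"},
        ],
        "variant_groups": [],
        "users": [],
        "organizations": [],
    }


@pytest.fixture
def snapshot_dict() -> dict:
    return small_snapshot_dict()


@pytest.fixture
def snapshot_bytes(snapshot_dict) -> bytes:
    return json.dumps(snapshot_dict).encode()


@pytest.fixture
def collection(snapshot_bytes):
    return resolve_links(parse_snapshot(snapshot_bytes))
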