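import io
import itertools

import pytest

from kbmatch.cohort import (
    CohortConsistencyError,
    CohortFormatError,
    LEVEL_ORDER,
    SampleSummary,
    SampleVariant,
    annotate_cohort,
    classify_samples,
    cohort_report,
    highest_evidence_level,
    queries_from_cohort,
    read_cohort_table,
)
from kbmatch.records import EvidenceItem, RecordIdentifier, ReviewStatus
from kbmatch.search import CoordinateQuery, build_index, bulk_search, query_sort_key
from search_oracle import make_variant

HEADER = (
    "Hugo_Symbol\tTumor_Sample_Barcode\tChromosome\tStart_Position\t"
    "End_Position\tReference_Allele\tTumor_Seq_Allele2\n"
)


def maf(rows: list[str]) -> io.StringIO:
    return io.StringIO(HEADER + "".join(r + "\n" for r in rows))


class TestReadCohortTable:
    def test_bad_coordinate_dropped_and_counted(self):
        table = read_cohort_table(maf([
            "TP53\tS1\t1\t100\t100\tA\tT",
            "TP53\tS1\t1\tnot_a_number\t100\tA\tT",
            "KRAS\tS2\t2\t200\t200\tG\tC",
            "BRAF\tS2\t7\t300\t310\tAA\t-",
        ]))
        assert len(table.variants) == 3
        assert table.n_dropped == 1

    def test_empty_file_with_header(self):
        table = read_cohort_table(maf([]))
        assert table.variants == [] and table.n_dropped == 0

    def test_duplicate_rows_preserved(self):
        row = "TP53\tS1\t1\t100\t100\tA\tT"
        table = read_cohort_table(maf([row, row]))
        assert len(table.variants) == 2
        assert table.variants[0] == table.variants[1]

    def test_missing_column_named(self):
        stream = io.StringIO("Tumor_Sample_Barcode\tChromosome\nS1\t1\n")
        with pytest.raises(CohortFormatError, match="Start_Position"):
            read_cohort_table(stream)

    def test_allele_normalization(self):
        table = read_cohort_table(maf(["X\tS1\tchr7\t10\t10\ta\t-"]))
        v = table.variants[0]
        assert v.chromosome == "7"
        assert v.ref == "A"
        assert v.alt is None  # MAF '-' convention

    def test_invariants(self):
        with pytest.raises(ValueError):
            SampleVariant("", "1", 1, 1, None, None)
        with pytest.raises(ValueError):
            SampleVariant("S", "1", 5, 1, None, None)


class TestQueriesFromCohort:
    def test_same_coords_different_barcodes_distinct(self):
        variants = [
            SampleVariant("S1", "1", 100, 100, "A", "T"),
            SampleVariant("S2", "1", 100, 100, "A", "T"),
        ]
        queries = queries_from_cohort(variants)
        assert len(queries) == 2
        assert {q.key for q in queries} == {"S1", "S2"}

    def test_sorted_by_index_ordering(self):
        variants = [
            SampleVariant("S1", "X", 5, 5, "A", "T"),
            SampleVariant("S1", "2", 9, 9, "A", "T"),
            SampleVariant("S1", "2", 3, 4, "A", "T"),
            SampleVariant("S1", "10", 1, 1, "A", "T"),
        ]
        queries = queries_from_cohort(variants)
        assert queries == sorted(queries, key=query_sort_key)
        assert [(q.chromosome, q.start) for q in queries] == [
            ("2", 3), ("2", 9), ("10", 1), ("X", 5)
        ]

    def test_empty(self):
        assert queries_from_cohort([]) == []

    def test_alt_carried_into_exact_queries(self):
        q = queries_from_cohort([SampleVariant("S1", "1", 7, 7, "A", "t")])[0]
        assert q.alt == "T" and q.key == "S1"


def _mk_results(pairs):
    return [(q, tuple(m)) for q, m in pairs]


def _query(bc, start=100, alt="T"):
    return CoordinateQuery(chromosome="1", start=start, stop=start, alt=alt, key=bc)


def _variant_with_levels(vid, levels, status="accepted"):
    v = make_variant(vid, "1", 100, 100, "T")
    v.evidence = [
        EvidenceItem(
            identifier=RecordIdentifier("evidence", vid * 100 + i),
            variant_id=v.identifier,
            status=ReviewStatus(status),
            evidence_level=lv,
        )
        for i, lv in enumerate(levels, 1)
    ]
    return v


class TestClassifySamples:
    def test_class_assignment(self):
        v = _variant_with_levels(1, ["B"])
        q_exact = _query("S_exact")
        q_any = _query("S_any_only", start=105)
        q_none = _query("S_none", start=900)
        exact = _mk_results([(q_exact, (v,)), (q_any, ()), (q_none, ())])
        any_ = _mk_results([(q_exact, (v,)), (q_any, (v,)), (q_none, ())])
        summaries = classify_samples(exact, any_, ["S_exact", "S_any_only", "S_none", "S_empty"])
        by_bc = {s.sample_barcode: s for s in summaries}
        assert by_bc["S_exact"].match_class == "exact"
        assert by_bc["S_any_only"].match_class == "any_only"
        assert by_bc["S_none"].match_class == "none"
        assert by_bc["S_empty"].match_class == "no_variants"
        assert by_bc["S_empty"].n_variants == 0
        assert by_bc["S_exact"].highest_level == "B"
        assert by_bc["S_any_only"].highest_level is None

    def test_unknown_barcode_is_consistency_error(self):
        q = _query("mystery")
        with pytest.raises(CohortConsistencyError):
            classify_samples(_mk_results([(q, ())]), _mk_results([(q, ())]), ["S1"])

    def test_misaligned_results_rejected(self):
        q = _query("S1")
        with pytest.raises(CohortConsistencyError):
            classify_samples(_mk_results([(q, ())]), _mk_results([]), ["S1"])

    def test_partition_property(self):
        v = _variant_with_levels(1, ["A"])
        queries = [_query(f"S{i}", start=100 + (i % 4)) for i in range(20)]
        exact = _mk_results([(q, (v,) if q.start == 100 else ()) for q in queries])
        any_ = _mk_results([(q, (v,) if q.start <= 102 else ()) for q in queries])
        barcodes = [f"S{i}" for i in range(25)]  # 5 extra with no variants
        summaries = classify_samples(exact, any_, barcodes)
        assert len(summaries) == 25
        counts = {}
        for s in summaries:
            counts[s.match_class] = counts.get(s.match_class, 0) + 1
        assert sum(counts.values()) == 25

    def test_monotonicity_adding_exact_match(self):
        """An extra exact match never lowers the class or the highest level."""
        rank = {"exact": 0, "any_only": 1, "none": 2, "no_variants": 3}
        v_b = _variant_with_levels(1, ["B"])
        v_a = _variant_with_levels(2, ["A"])
        q1, q2 = _query("S1"), _query("S1", start=101)
        base = classify_samples(
            _mk_results([(q1, ()), (q2, ())]),
            _mk_results([(q1, (v_b,)), (q2, ())]), ["S1"])[0]
        more = classify_samples(
            _mk_results([(q1, (v_b,)), (q2, ())]),
            _mk_results([(q1, (v_b,)), (q2, ())]), ["S1"])[0]
        most = classify_samples(
            _mk_results([(q1, (v_b,)), (q2, (v_a,))]),
            _mk_results([(q1, (v_b,)), (q2, (v_a,))]), ["S1"])[0]
        assert rank[more.match_class] <= rank[base.match_class]
        assert most.highest_level == "A" and more.highest_level == "B"


class TestHighestEvidenceLevel:
    def test_bce_gives_b(self):
        v = _variant_with_levels(1, ["B", "C", "E"])
        assert highest_evidence_level([v]) == "B"

    def test_single_a(self):
        assert highest_evidence_level([_variant_with_levels(1, ["A"])]) == "A"

    def test_no_variants_absent(self):
        assert highest_evidence_level([]) is None

    def test_status_filtering(self):
        v = _variant_with_levels(1, ["A"], status="rejected")
        assert highest_evidence_level([v], {"accepted"}) is None
        assert highest_evidence_level([v], {"rejected"}) == "A"

    def test_exhaustive_subsets(self):
        for r in range(1, 6):
            for combo in itertools.combinations(LEVEL_ORDER, r):
                v = _variant_with_levels(1, list(combo))
                assert highest_evidence_level([v]) == min(combo)  # 'A' < 'B' < ...


class TestCohortReport:
    def _summaries(self, layout):
        out = []
        for i, (cls, level) in enumerate(layout):
            n = 0 if cls == "no_variants" else 3
            out.append(SampleSummary(
                sample_barcode=f"S{i}", n_variants=n,
                n_exact=1 if cls == "exact" else 0,
                n_any_only=1 if cls == "any_only" else 0,
                match_class=cls, highest_level=level,
            ))
        return out

    def test_fraction_arithmetic(self):
        layout = [("exact", "A")] * 3 + [("any_only", None)] * 4 + \
               [("none", None)] * 2 + [("no_variants", None)]
        report = cohort_report(self._summaries(layout))
        assert report.class_fractions == {
            "exact": 0.3, "any_only": 0.4, "none": 0.2, "no_variants": 0.1
        }
        assert sum(report.class_counts.values()) == 10

    def test_all_exact(self):
        report = cohort_report(self._summaries([("exact", "B")] * 5))
        assert report.class_fractions["exact"] == 1.0
        assert report.level_fractions == {"B": 1.0}

    def test_fractions_sum_to_one(self):
        layout = [("exact", "A")] * 2 + [("exact", "C")] * 3 + [("none", None)] * 5
        report = cohort_report(self._summaries(layout))
        assert abs(sum(report.class_fractions.values()) - 1.0) < 1e-12
        assert abs(sum(report.level_fractions.values()) - 1.0) < 1e-12
        assert sum(report.exact_count_distribution.values()) == report.n_samples

    def test_to_frame_and_tsv(self):
        report = cohort_report(self._summaries([("exact", "A"), ("none", None)]))
        frame = report.to_frame()
        assert set(frame.columns) == {"breakdown", "group", "count", "fraction"}
        buf = io.StringIO()
        report.to_tsv(buf)
        assert "exact" in buf.getvalue()


class TestAnnotateCohortPipeline:
    def test_end_to_end(self):
        kb = [_variant_with_levels(1, ["A", "C"]), _variant_with_levels(2, ["D"])]
        kb[1].coordinates.start = kb[1].coordinates.stop = 500
        index = build_index(kb)
        table = read_cohort_table(maf([
            "X\tS1\t1\t100\t100\tA\tT",    # exact match to variant 1
            "X\tS1\t1\t900\t900\tA\tT",    # none
            "X\tS2\t1\t95\t105\tA\tG",     # any-overlap of variant 1 only
            "X\tS3\t2\t100\t100\tA\tT",    # wrong chromosome: none
        ]))
        summaries, report = annotate_cohort(table, index, all_samples=["S1", "S2", "S3", "S4"])
        by_bc = {s.sample_barcode: s for s in summaries}
        assert by_bc["S1"].match_class == "exact"
        assert by_bc["S1"].highest_level == "A"
        assert by_bc["S2"].match_class == "any_only"
        assert by_bc["S3"].match_class == "none"
        assert by_bc["S4"].match_class == "no_variants"
        assert report.n_samples == 4 and report.n_queries == 4
        assert report.class_counts == {
            "exact": 1, "any_only": 1, "none": 1, "no_variants": 1
        }
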