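import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kbmatch.search import (
    BuildMismatchError,
    CoordinateIndexEntry,
    CoordinateQuery,
    MatchMode,
    build_index,
    bulk_search,
    match,
    search_single,
)
from search_oracle import (
    brute_force_match_sets,
    make_variant,
    random_instance,
    result_id_sets,
)

MODES = [m.value for m in MatchMode]


def entry(chrom, start, stop, alt=None, vid=1):
    return CoordinateIndexEntry(
        chromosome=str(chrom), start=start, stop=stop, alt=alt,
        variant_key=vid, variant_id=vid,
    )


class TestBuildIndex:
    def test_split_and_exclusion(self):
        variants = [
            make_variant(1, "7", 100, 100, "T"),
            make_variant(2, None, None, None),  # missing coordinates
            make_variant(3, "2", 100, 200, None, "5", 5000, 5100),  # fusion
        ]
        index = build_index(variants)
        assert len(index) == 3  # 1 + 0 + 2
        assert index.report.n_skipped_missing_coordinates == 1
        assert index.report.n_compound == 1
        fusion_entries = [e for e in index if e.variant_id == 3]
        assert len(fusion_entries) == 2
        assert len({e.variant_key for e in fusion_entries}) == 1

    def test_empty(self):
        assert len(build_index([])) == 0

    def test_sort_matches_generic_tuple_sort(self):
        rng = np.random.default_rng(42)
        index, _ = random_instance(rng, 200, 0)
        from kbmatch.genome import chromosome_sort_key

        expected = sorted(
            index.entries,
            key=lambda e: (
                chromosome_sort_key(e.chromosome), e.start, e.stop, e.alt or "",
                e.variant_id,
            ),
        )
        assert index.entries == expected

    def test_rebuild_deterministic(self):
        rng = np.random.default_rng(7)
        variants = [make_variant(i, "1", int(rng.integers(1, 100)), 100 + i) for i in range(1, 50)]
        assert build_index(variants).entries == build_index(variants).entries


class TestMatchPredicate:
    def test_identical_coordinates_match_all_modes(self):
        q = CoordinateQuery(chromosome="1", start=5, stop=10, alt="T")
        e = entry("1", 5, 10, alt="T")
        assert all(match(q, e, m) for m in MODES)

    def test_query_encompassing_scenario(self):
        q = CoordinateQuery(chromosome="1", start=3, stop=12)
        e = entry("1", 5, 10)
        assert match(q, e, "any")
        assert match(q, e, "query_encompassing")
        assert not match(q, e, "exact")
        assert not match(q, e, "record_encompassing")

    def test_record_encompassing_scenario(self):
        q = CoordinateQuery(chromosome="1", start=6, stop=9)
        e = entry("1", 5, 10)
        assert match(q, e, "any")
        assert match(q, e, "record_encompassing")
        assert not match(q, e, "query_encompassing")
        assert not match(q, e, "exact")

    def test_alt_mismatch_fails_exact_only(self):
        q = CoordinateQuery(chromosome="1", start=5, stop=10, alt="T")
        e = entry("1", 5, 10, alt="G")
        assert not match(q, e, "exact")
        for m in ("any", "query_encompassing", "record_encompassing"):
            assert match(q, e, m)

    def test_alt_wildcards(self):
        e = entry("1", 5, 10, alt="G")
        for alt in (None, "*"):
            assert match(CoordinateQuery(chromosome="1", start=5, stop=10, alt=alt), e, "exact")

    def test_different_chromosome_never_matches(self):
        q = CoordinateQuery(chromosome="2", start=5, stop=10)
        e = entry("1", 5, 10)
        assert not any(match(q, e, m) for m in MODES)

    def test_mode_aliases(self):
        assert MatchMode.coerce("qe") is MatchMode.QUERY_ENCOMPASSING
        assert MatchMode.coerce("re") is MatchMode.RECORD_ENCOMPASSING

    @given(
        qs=st.integers(1, 50), ql=st.integers(0, 10),
        es=st.integers(1, 50), el=st.integers(0, 10),
        qalt=st.sampled_from([None, "*", "A", "T"]),
        ealt=st.sampled_from([None, "A", "T"]),
        mode=st.sampled_from(MODES),
    )
    def test_against_inline_oracle(self, qs, ql, es, el, qalt, ealt, mode):
        q = CoordinateQuery(chromosome="1", start=qs, stop=qs + ql, alt=qalt)
        e = entry("1", es, es + el, alt=ealt)
        alt_ok = qalt in (None, "*") or qalt == ealt
        expected = {
            "any": qs <= es + el and es <= qs + ql,
            "query_encompassing": es >= qs and es + el <= qs + ql,
            "record_encompassing": qs >= es and qs + ql <= es + el,
            "exact": qs == es and ql == el and alt_ok,
        }[mode]
        assert match(q, e, mode) == expected


class TestBulkSearch:
    def test_no_queries(self):
        rng = np.random.default_rng(0)
        index, _ = random_instance(rng, 20, 0)
        result = bulk_search(index, [], "any")
        assert len(result.matches) == 0

    def test_empty_index(self):
        index = build_index([])
        q = CoordinateQuery(chromosome="1", start=1, stop=10)
        assert bulk_search(index, [q], "any").matches == ((),)

    @pytest.mark.parametrize("mode", MODES)
    def test_random_instances_vs_oracle(self, mode):
        rng = np.random.default_rng(hash(mode) % 2**32)
        for _ in range(25):
            index, queries = random_instance(rng, 50, 30)
            got = result_id_sets(bulk_search(index, queries, mode))
            expected = brute_force_match_sets(index.entries, queries, mode)
            assert got == expected

    @pytest.mark.parametrize("mode", MODES)
    def test_adversarial_long_entry(self, mode):
        """A long entry early in start order must be reported for every
        overlapping query despite later short entries (pointer restore)."""
        variants = [make_variant(1, "1", 1, 1_000_000)]
        variants += [
            make_variant(i, "1", i * 1000, i * 1000 + 5, "A") for i in range(2, 100)
        ]
        index = build_index(variants)
        queries = [
            CoordinateQuery(chromosome="1", start=p, stop=p + 10)
            for p in range(500, 900_000, 7919)
        ]
        got = result_id_sets(bulk_search(index, queries, mode))
        expected = brute_force_match_sets(index.entries, queries, mode)
        assert got == expected
        if mode in ("any", "record_encompassing"):
            assert all(1 in s for s in got)  # the long entry overlaps every query

    def test_unsorted_input_output_order_preserved(self):
        rng = np.random.default_rng(3)
        index, queries = random_instance(rng, 40, 20)
        result = bulk_search(index, queries, "any")
        assert result.queries == tuple(queries)  # original order, not sorted

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        index, queries = random_instance(rng, 40, 25)
        base = {q: s for q, s in zip(queries, result_id_sets(bulk_search(index, queries, "any")))}
        perm = list(queries)[::-1]
        permuted = {q: s for q, s in zip(perm, result_id_sets(bulk_search(index, perm, "any")))}
        assert base == permuted

    def test_compound_variant_reported_once(self):
        v = make_variant(1, "1", 10, 20, None, "1", 30, 40)
        index = build_index([v])
        q = CoordinateQuery(chromosome="1", start=1, stop=100)
        matched = search_single(index, q, "any")
        assert [m.id for m in matched] == [1]

    def test_matches_deduplicated_and_sorted_by_id(self):
        variants = [make_variant(i, "1", 10, 20, "A") for i in (3, 1, 2)]
        index = build_index(variants)
        q = CoordinateQuery(chromosome="1", start=10, stop=20)
        assert [m.id for m in search_single(index, q, "any")] == [1, 2, 3]

    def test_build_mismatch(self):
        index = build_index([make_variant(1, "1", 1, 1, "A")])
        q = CoordinateQuery(chromosome="1", start=1, stop=1, build="GRCh38")
        with pytest.raises(BuildMismatchError):
            bulk_search(index, [q], "any")

    @pytest.mark.parametrize("mode", MODES)
    def test_mode_nesting(self, mode):
        rng = np.random.default_rng(11)
        for _ in range(10):
            index, queries = random_instance(rng, 60, 40)
            exact = result_id_sets(bulk_search(index, queries, "exact"))
            qe = result_id_sets(bulk_search(index, queries, "query_encompassing"))
            re_ = result_id_sets(bulk_search(index, queries, "record_encompassing"))
            any_ = result_id_sets(bulk_search(index, queries, "any"))
            for x, q_, r, a in zip(exact, qe, re_, any_):
                assert x <= (q_ & r) <= a

    def test_singleton_equivalence(self):
        rng = np.random.default_rng(12)
        index, queries = random_instance(rng, 50, 10)
        for q in queries:
            for mode in MODES:
                assert search_single(index, q, mode) == bulk_search(index, [q], mode)[q]

    def test_exact_mode_fixture_snv(self):
        variants = [
            make_variant(1, "7", 140453136, 140453136, "T"),
            make_variant(2, "7", 140453136, 140453137, "T"),
        ]
        index = build_index(variants)
        q = CoordinateQuery(chromosome="7", start=140453136, stop=140453136, alt="T")
        assert [m.id for m in search_single(index, q, "exact")] == [1]

    def test_no_overlap_empty(self):
        index = build_index([make_variant(1, "1", 100, 110, "A")])
        q = CoordinateQuery(chromosome="1", start=500, stop=510)
        assert search_single(index, q, "any") == ()


class TestInstrumentation:
    def test_comparison_count_linear_contract(self):
        """Doubling n=m at fixed overlap density must not super-linearly
        inflate the predicate-evaluation count."""
        counts = []
        for n in (500, 1000, 2000):
            rng = np.random.default_rng(99)
            span = 5 * n  # genome scales with n: fixed overlap density
            index, queries = random_instance(rng, n, n, span=span, max_len=10)
            counts.append(bulk_search(index, queries, "any").n_predicate_evaluations)
        assert counts[1] <= 2.2 * counts[0]
        assert counts[2] <= 2.2 * counts[1]

    def test_pointer_steps_bounded_by_index_size(self):
        rng = np.random.default_rng(13)
        index, queries = random_instance(rng, 300, 300)
        result = bulk_search(index, queries, "any")
        assert result.n_pointer_steps <= len(index)


@settings(max_examples=50, deadline=None)
@given(seed=st.integers(0, 2**31), n=st.integers(0, 40), m=st.integers(0, 25),
       mode=st.sampled_from(MODES))
def test_bulk_search_oracle_property(seed, n, m, mode):
    rng = np.random.default_rng(seed)
    index, queries = random_instance(rng, n, m, span=300)
    got = result_id_sets(bulk_search(index, queries, mode))
    expected = brute_force_match_sets(index.entries, queries, mode)
    assert got == expected
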