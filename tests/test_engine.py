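"""Unit tests for the cluster-grammar engine: validation, counting,
enumeration, order/orientation, adjacency, and the full scan."""

from __future__ import annotations

from dataclasses import replace

import pytest

import siteclust as sc
from siteclust import (
    ClusterQuery,
    QueryError,
    SiteSet,
    check_combination,
    enumerate_candidates,
    filter_adjacent,
    match_order_orientation,
    scan,
    subset_sites,
    validate_query,
)
from siteclust.engine import EXCLUDED, INSUFFICIENT, PASS

from conftest import make_site


def sset(*sites):
    return SiteSet(sites)


class TestValidateQuery:
    @pytest.mark.parametrize(
        "query",
        [
            ClusterQuery(w=200, conditions={"a": 1}, orientation=("+",)),
            ClusterQuery(w=0, conditions={"a": 1}),
            ClusterQuery(w=200, conditions={"a": 0, "b": 0}),
            ClusterQuery(w=200, conditions={"a": 1, "b": 0}, order=("a", "b")),
            ClusterQuery(w=200, conditions={"a": 1}, order=("a", "z")),
            ClusterQuery(
                w=200, conditions={"a": 1, "b": 1}, order=("a", "b"), orientation=("+",)
            ),
            ClusterQuery(w=200, conditions={"a": -1, "b": 1}),
            ClusterQuery(w=200, conditions={"a": 1}, strand_filter="x"),
            ClusterQuery(
                w=200,
                conditions={"a": 1, "b": 1},
                order=("a", "b"),
                orientation=("+", "?"),
            ),
        ],
    )
    def test_invalid_queries_raise(self, query):
        with pytest.raises(QueryError):
            validate_query(query, sset(make_site()))

    def test_valid_query_passes_through_with_missing_label_warning(self, caplog):
        q = ClusterQuery(w=200, conditions={"a": 1, "zz": 2})
        with caplog.at_level("WARNING"):
            out = validate_query(q, sset(make_site(label="a")))
        assert out is q
        assert any("zz" in r.message for r in caplog.records)


class TestSubsetSites:
    def test_seqname_and_strand_filters(self):
        sites = sset(
            make_site(seqname="chr7", strand="+"),
            make_site(seqname="chr7", strand="-", start=200, end=210),
            make_site(seqname="chr8", strand="+", start=300, end=310),
            make_site(seqname="chr7", strand=".", start=400, end=410),
        )
        assert {s.seqname for s in subset_sites(sites, seqnames={"chr7"})} == {"chr7"}
        plus = subset_sites(sites, strand_filter="+")
        assert all(s.strand == "+" for s in plus) and len(plus) == 2
        both = subset_sites(sites, seqnames={"chr7"}, strand_filter="+")
        assert len(both) == 1
        assert subset_sites(sites) is sites


class TestCheckCombination:
    @pytest.mark.parametrize(
        "observed, expected",
        [
            ({"a": 2, "b": 2}, (True, None)),
            ({"a": 3, "b": 2}, (True, None)),  # counts are minima
            ({"a": 2, "b": 2, "c": 1}, (False, EXCLUDED)),
            ({"a": 1, "b": 2}, (False, INSUFFICIENT)),
            ({"a": 1, "b": 2, "c": 1}, (False, EXCLUDED)),  # excluded wins
            ({}, (False, INSUFFICIENT)),
        ],
    )
    def test_against_two_and_two_but_no_c(self, observed, expected):
        conditions = {"a": 2, "b": 2, "c": 0}
        assert check_combination(observed, conditions) == expected


class TestEnumerateCandidates:
    def test_minimal_pair_within_window(self):
        sites = sset(
            make_site(start=100, end=110, label="a"),
            make_site(start=150, end=160, label="b"),
        )
        q = ClusterQuery(w=200, conditions={"a": 1, "b": 1})
        (cand,) = enumerate_candidates(sites, q)
        assert (cand.start, cand.end, cand.width) == (100, 160, 61)

    def test_pair_wider_than_window_yields_nothing(self):
        sites = sset(
            make_site(start=100, end=110, label="a"),
            make_site(start=290, end=310, label="b"),
        )
        q = ClusterQuery(w=200, conditions={"a": 1, "b": 1})
        assert enumerate_candidates(sites, q) == []

    def test_greedy_extends_past_satisfaction(self):
        sites = sset(
            make_site(start=100, end=110, label="a"),
            make_site(start=150, end=160, label="b"),
            make_site(start=180, end=190, label="a"),
        )
        lazy = ClusterQuery(w=200, conditions={"a": 1, "b": 1})
        greedy = replace(lazy, greedy=True)
        spans_lazy = {(c.start, c.end) for c in enumerate_candidates(sites, lazy)}
        spans_greedy = {(c.start, c.end) for c in enumerate_candidates(sites, greedy)}
        assert (100, 160) in spans_lazy and (100, 190) not in spans_lazy
        assert (100, 190) in spans_greedy
        # cross-check both modes against the exhaustive oracle
        for q in (lazy, greedy):
            bf = sc.brute_force_scan(sites, replace(q, verbose=True, overlap=-200))
            assert {(c.start, c.end) for c in bf} == {
                (c.start, c.end) for c in enumerate_candidates(sites, q)
            }

    def test_members_reexpand_to_all_condition_sites_in_span(self):
        # b at 140 is past the satisfying prefix (a@100, b@120) but inside
        # the trimmed span only if its end fits; here span end is 160.
        sites = sset(
            make_site(start=100, end=160, label="a"),
            make_site(start=120, end=130, label="b"),
            make_site(start=140, end=150, label="b"),
        )
        q = ClusterQuery(w=100, conditions={"a": 1, "b": 1})
        (cand,) = enumerate_candidates(sites, q)
        assert (cand.start, cand.end) == (100, 160)
        assert cand.label_counts == {"a": 1, "b": 2}

    def test_non_condition_labels_are_invisible(self):
        sites = sset(
            make_site(start=100, end=110, label="a"),
            make_site(start=120, end=400, label="noise"),
            make_site(start=150, end=160, label="b"),
        )
        q = ClusterQuery(w=200, conditions={"a": 1, "b": 1})
        (cand,) = enumerate_candidates(sites, q)
        assert (cand.start, cand.end) == (100, 160)
        assert all(m.label != "noise" for m in cand.members)

    def test_identical_spans_deduplicated(self):
        sites = sset(
            make_site(start=100, end=110, label="a"),
            make_site(start=100, end=110, label="a"),
            make_site(start=150, end=160, label="b"),
        )
        q = ClusterQuery(w=200, conditions={"a": 1, "b": 1})
        cands = enumerate_candidates(sites, q)
        assert len(cands) == 1
        assert cands[0].label_counts == {"a": 2, "b": 1}  # duplicates both count


class TestMatchOrderOrientation:
    def test_direct_match(self):
        members = (
            make_site(start=100, end=110, strand="+", label="a"),
            make_site(start=150, end=160, strand="+", label="b"),
        )
        assert match_order_orientation(members, ("a", "b"), ("+", "+")) == "PASS"

    def test_wrong_order(self):
        members = (
            make_site(start=100, end=110, label="b"),
            make_site(start=150, end=160, label="a"),
        )
        assert match_order_orientation(members, ("a", "b")) == "orderFail"

    def test_subcluster_rescues_orientation(self):
        members = (
            make_site(start=100, end=110, strand="+", label="a"),
            make_site(start=150, end=160, strand="-", label="b"),
            make_site(start=180, end=190, strand="+", label="b"),
        )
        assert match_order_orientation(members, ("a", "b"), ("+", "+")) == "PASS"

    def test_orientation_fail_when_labels_match_but_strands_cannot(self):
        members = (
            make_site(start=100, end=110, strand="+", label="a"),
            make_site(start=150, end=160, strand="-", label="b"),
        )
        assert (
            match_order_orientation(members, ("a", "b"), ("+", "+"))
            == "orientationFail"
        )

    def test_dot_strand_never_satisfies_orientation(self):
        members = (
            make_site(start=100, end=110, strand=".", label="a"),
            make_site(start=150, end=160, strand="+", label="b"),
        )
        assert match_order_orientation(members, ("a", "b")) == "PASS"
        assert (
            match_order_orientation(members, ("a", "b"), ("+", "+"))
            == "orientationFail"
        )


def _cluster(seqname, start, end):
    m = make_site(seqname=seqname, start=start, end=end, label="a")
    return sc.Cluster(seqname, start, end, (m,), {"a": 1}, "PASS")


class TestFilterAdjacent:
    def test_minimum_gap_drops_close_neighbor(self):
        out = filter_adjacent(
            [_cluster("chr1", 100, 200), _cluster("chr1", 210, 300)], overlap=20
        )
        assert [c.status for c in out] == ["PASS", "adjacencyFail"]  # gap 9 < 20

    def test_zero_overlap_allows_touching(self):
        out = filter_adjacent(
            [_cluster("chr1", 100, 200), _cluster("chr1", 210, 300)], overlap=0
        )
        assert [c.status for c in out] == ["PASS", "PASS"]

    def test_negative_overlap_permits_bounded_sharing(self):
        out = filter_adjacent(
            [_cluster("chr1", 100, 200), _cluster("chr1", 190, 300)], overlap=-20
        )
        assert [c.status for c in out] == ["PASS", "PASS"]  # 11 shared <= 20
        out = filter_adjacent(
            [_cluster("chr1", 100, 200), _cluster("chr1", 150, 300)], overlap=-20
        )
        assert [c.status for c in out] == ["PASS", "adjacencyFail"]  # 51 shared

    def test_comparison_is_against_last_kept(self):
        out = filter_adjacent(
            [
                _cluster("chr1", 100, 200),
                _cluster("chr1", 205, 300),  # dropped, gap 4
                _cluster("chr1", 206, 320),  # compared with 100-200, gap 5 -> kept
            ],
            overlap=5,
        )
        assert [c.status for c in out] == ["PASS", "adjacencyFail", "PASS"]

    def test_seqnames_swept_independently(self):
        out = filter_adjacent(
            [_cluster("chr1", 100, 200), _cluster("chr2", 205, 300)], overlap=50
        )
        assert [c.status for c in out] == ["PASS", "PASS"]


class TestScan:
    def test_worked_example_verbose_statuses(self):
        sites, query = sc.worked_example()
        result = scan(sites, query)
        by_status = {c.status: (c.start, c.end) for c in result}
        assert by_status["PASS"] == (100, 160)
        assert by_status["excludedSiteFail"] == (1000, 1060)
        assert by_status["orderFail"] == (3000, 3060)
        assert by_status["orientationFail"] == (4000, 4060)
        # the too-wide combination never becomes a candidate at all
        assert not any(2000 <= c.start <= 2400 for c in result)

    def test_non_verbose_returns_only_pass(self):
        sites, query = sc.worked_example()
        result = scan(sites, replace(query, verbose=False))
        assert [c.status for c in result] == ["PASS"]

    def test_empty_input_gives_empty_result_with_warnings(self):
        result = scan(SiteSet([]), ClusterQuery(w=100, conditions={"a": 1}))
        assert len(result) == 0
        assert any("'a'" in w for w in result.warnings)

    def test_strand_filter_restricts_search(self):
        sites = sset(
            make_site(start=100, end=110, strand="+", label="a"),
            make_site(start=150, end=160, strand="-", label="b"),
        )
        q = ClusterQuery(w=200, conditions={"a": 1, "b": 1})
        assert len(scan(sites, q).passes) == 1
        assert len(scan(sites, replace(q, strand_filter="+")).passes) == 0

    def test_extent_of_exactly_w_passes(self):
        sites = sset(
            make_site(start=100, end=110, label="a"),
            make_site(start=250, end=299, label="b"),
        )
        q = ClusterQuery(w=200, conditions={"a": 1, "b": 1})
        (c,) = scan(sites, q).passes
        assert c.width == 200
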