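"""Shared fixtures: random small instances and the soundness assertion suite."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from siteclust import ClusterQuery, GenomicSite, PASS, ScanResult, SiteSet, check_combination
from siteclust.synthetic import _order_assignment_exists

LABEL_POOL = ("a", "b", "c", "d")


def make_site(seqname="chr1", start=100, end=110, strand="+", label="a"):
    return GenomicSite(seqname, start, end, strand, label)


def random_sites(
    rng: np.random.Generator,
    n: int,
    labels=LABEL_POOL[:3],
    n_chroms: int = 1,
    span: int = 1500,
    fixed_width: int | None = None,
) -> list[GenomicSite]:
    sites = []
    for _ in range(n):
        width = fixed_width if fixed_width else int(rng.integers(1, 11))
        start = int(rng.integers(1, span))
        strand = ("+", "-", ".")[int(rng.choice(3, p=[0.45, 0.45, 0.10]))]
        label = labels[int(rng.integers(0, len(labels)))]
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        sites.append(GenomicSite(chrom, start, start + width - 1, strand, label))
    return sites


def random_instance(
    rng: np.random.Generator,
    *,
    w: int = 200,
    greedy: bool = False,
    order_mode: str = "none",  # none | order | orientation
    overlap: int = 0,
    fixed_width: int | None = None,
    allow_exclusion: bool = True,
) -> tuple[SiteSet, ClusterQuery]:
    """One randomized scan instance: a small site collection and a query."""
    n_labels = int(rng.integers(3, 5))
    labels = LABEL_POOL[:n_labels]
    n = int(rng.integers(4, 90))
    n_chroms = int(rng.integers(1, 3))
    sites = random_sites(
        rng, n, labels=labels, n_chroms=n_chroms, fixed_width=fixed_width
    )
    k_pos = int(rng.integers(2, min(3, n_labels) + 1))
    positive = [str(l) for l in rng.permutation(labels)[:k_pos]]
    conditions = {l: int(rng.integers(1, 3)) for l in positive}
    rest = [l for l in labels if l not in positive]
    if allow_exclusion and rest and rng.random() < 0.5:
        conditions[rest[0]] = 0
    order = orientation = None
    if order_mode in ("order", "orientation"):
        k = int(rng.integers(2, len(positive) + 1))
        order = tuple(str(l) for l in rng.permutation(positive)[:k])
        if order_mode == "orientation":
            orientation = tuple(
                ("+", "-")[int(rng.integers(0, 2))] for _ in order
            )
    query = ClusterQuery(
        w=w,
        conditions=conditions,
        greedy=greedy,
        overlap=overlap,
        order=order,
        orientation=orientation,
        verbose=True,
    )
    return SiteSet(sites), query


def instance_grid():
    """Deterministic grid over the query dimensions (54 combinations)."""
    for w in (50, 200, 500):
        for greedy in (False, True):
            for order_mode in ("none", "order", "orientation"):
                for overlap in (-20, 0, 20):
                    yield dict(
                        w=w, greedy=greedy, order_mode=order_mode, overlap=overlap
                    )


def cluster_key(c):
    return (c.seqname, c.start, c.end, c.status, c.members)


def assert_same_result(res_a: ScanResult, res_b: ScanResult):
    assert [cluster_key(c) for c in res_a.clusters] == [
        cluster_key(c) for c in res_b.clusters
    ]
    for ca, cb in zip(res_a.clusters, res_b.clusters):
        assert dict(ca.label_counts) == dict(cb.label_counts)


def assert_sound(result: ScanResult, sites: SiteSet):
    """Every PASS cluster satisfies the full grammar it was called under."""
    q = result.query
    visible = [
        s
        for s in sites
        if s.label in q.conditions
        and (q.seqnames is None or s.seqname in q.seqnames)
        and (q.strand_filter is None or s.strand == q.strand_filter)
    ]
    seen_spans = set()
    prev = None
    for c in result.clusters:
        span = (c.seqname, c.start, c.end)
        assert span not in seen_spans, "duplicate cluster span reported"
        seen_spans.add(span)
        if prev is not None:
            assert (prev.seqname, prev.start, prev.end) <= span, "unsorted result"
        prev = c
        if not q.verbose:
            assert c.status == PASS
        if c.status != PASS:
            continue
        assert c.end - c.start + 1 <= q.w, "cluster extent exceeds the window"
        assert c.start == min(m.start for m in c.members)
        assert c.end == max(m.end for m in c.members)
        in_span = sorted(
            (
                s
                for s in visible
                if s.seqname == c.seqname and s.start >= c.start and s.end <= c.end
            ),
            key=GenomicSite.sort_key,
        )
        assert tuple(in_span) == tuple(
            sorted(c.members, key=GenomicSite.sort_key)
        ), "members are not exactly the condition-label sites in the span"
        counts = Counter(m.label for m in c.members)
        assert dict(counts) == dict(c.label_counts)
        ok, kind = check_combination(counts, q.conditions)
        assert ok, f"PASS cluster violates conditions ({kind})"
        if q.order is not None:
            assert _order_assignment_exists(
                c.members, q.order, q.orientation
            ), "PASS cluster lacks an order/orientation witness"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
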