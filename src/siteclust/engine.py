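"""Windowed cluster scan over labeled genomic sites.

The grammar: a cluster is a run of sites on one seqname whose extent
(first-member start to last-member end, ``end - start + 1``) fits inside a
window of ``w`` bp and whose per-label member counts meet user conditions.
A condition count of ``n > 0`` means "at least n sites of this label"; a
count of 0 means the label is excluded — any such site inside the cluster
span disqualifies it.  Optional constraints: a required left-to-right label
order, per-position strand orientation, greedy extension (absorb every site
that fits in the window, not just the minimal satisfying run), and a signed
spacing rule between consecutive reported clusters.

Sites whose labels do not appear in the conditions mapping are invisible to
the scan: they contribute nothing to extent, counts, order, or exclusion.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .model import GenomicSite, SiteSet

log = logging.getLogger(__name__)

# Cluster status vocabulary.  PASS is the only status reported when
# verbose is off; the *Fail statuses name the first check that rejected
# an otherwise-candidate cluster.
PASS = "PASS"
EXCLUDED_SITE_FAIL = "excludedSiteFail"
ORDER_FAIL = "orderFail"
ORIENTATION_FAIL = "orientationFail"
ADJACENCY_FAIL = "adjacencyFail"
STATUSES = frozenset(
    {PASS, EXCLUDED_SITE_FAIL, ORDER_FAIL, ORIENTATION_FAIL, ADJACENCY_FAIL}
)

# check_combination failure kinds
INSUFFICIENT = "insufficient"
EXCLUDED = "excluded"


class QueryError(ValueError):
    """A ClusterQuery violates its own invariants."""


@dataclass(frozen=True)
class ClusterQuery:
    """Full specification of one cluster search.

    Parameters
    ----------
    w
        Window size in bp: maximum allowed cluster extent (inclusive; a
        cluster of extent exactly ``w`` passes).
    conditions
        Mapping label -> required count.  Positive counts are minima;
        0 marks the label as excluded.  At least one count must be > 0.
    greedy
        When True, a cluster absorbs every site that fits in the window
        even after the counts are already satisfied (the absorbed
        sub-arrangements are "subclusters").
    overlap
        Signed spacing between consecutive reported clusters: ``>= 0``
        requires a gap of at least that many bp; ``< 0`` permits up to
        ``-overlap`` bp of overlap.  Default 0 (touching allowed).
    order
        Optional label sequence that must appear left-to-right among the
        members (as a subsequence; surplus members may interleave).
    orientation
        Optional strand sequence ("+"/"-"), parallel to ``order``; only
        valid when ``order`` is given.
    seqnames
        Optional restriction of the search to these seqnames.
    strand_filter
        Optional restriction to "+" or "-" input sites.
    verbose
        When True, rejected candidates are reported with their failure
        status; when False only PASS clusters are returned.
    """

    w: int
    conditions: Mapping[str, int]
    greedy: bool = False
    overlap: int = 0
    order: tuple[str, ...] | None = None
    orientation: tuple[str, ...] | None = None
    seqnames: frozenset[str] | None = None
    strand_filter: str | None = None
    verbose: bool = False

    def __post_init__(self):
        object.__setattr__(self, "conditions", dict(self.conditions))
        if self.order is not None:
            object.__setattr__(self, "order", tuple(self.order))
        if self.orientation is not None:
            object.__setattr__(self, "orientation", tuple(self.orientation))
        if self.seqnames is not None:
            object.__setattr__(self, "seqnames", frozenset(self.seqnames))

    @property
    def positive_conditions(self) -> dict[str, int]:
        return {l: n for l, n in self.conditions.items() if n > 0}

    @property
    def excluded_labels(self) -> set[str]:
        return {l for l, n in self.conditions.items() if n == 0}


@dataclass(frozen=True)
class Cluster:
    """A called region with its member sites and status.

    ``members`` holds every condition-label site fully contained in
    [start, end], position-sorted; ``start``/``end`` equal the minimum
    member start / maximum member end.
    """

    seqname: str
    start: int
    end: int
    members: tuple[GenomicSite, ...]
    label_counts: Mapping[str, int]
    status: str = PASS

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def is_cluster(self) -> bool:
        return self.status == PASS

    def span(self) -> tuple[str, int, int]:
        return (self.seqname, self.start, self.end)


@dataclass(frozen=True)
class ScanResult:
    """Sorted clusters plus the query that produced them and any warnings."""

    clusters: tuple[Cluster, ...]
    query: ClusterQuery
    warnings: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    @property
    def passes(self) -> tuple[Cluster, ...]:
        return tuple(c for c in self.clusters if c.status == PASS)


# ---------------------------------------------------------------------------
# validation / subsetting


def missing_condition_labels(query: ClusterQuery, sites: SiteSet) -> list[str]:
    """Positive-condition labels absent from the data (warning, not error)."""
    present = sites.labels
    return sorted(l for l, n in query.conditions.items() if n > 0 and l not in present)


def validate_query(query: ClusterQuery, sites: SiteSet) -> ClusterQuery:
    """Check all ClusterQuery invariants; raise :class:`QueryError` on violation.

    A positive-condition label absent from the data only logs a warning:
    the scan is well-defined (it finds nothing) and the absence may be the
    biological answer.
    """
    if query.w < 1:
        raise QueryError(f"window size must be >= 1, got {query.w}")
    if any(n < 0 for n in query.conditions.values()):
        raise QueryError("condition counts must be non-negative")
    if not query.positive_conditions:
        raise QueryError(
            "at least one condition count must be > 0 (all-zero conditions "
            "require nothing and exclude everything)"
        )
    if query.orientation is not None and query.order is None:
        raise QueryError("orientation can only be given together with order")
    if query.order is not None:
        unknown = [l for l in query.order if query.conditions.get(l, 0) <= 0]
        if unknown:
            raise QueryError(
                f"order refers to excluded or unknown label(s): {unknown}"
            )
        if query.orientation is not None:
            if len(query.orientation) != len(query.order):
                raise QueryError(
                    "orientation and order must have the same length "
                    f"({len(query.orientation)} != {len(query.order)})"
                )
            bad = [s for s in query.orientation if s not in ("+", "-")]
            if bad:
                raise QueryError(f"orientation entries must be '+' or '-': {bad}")
    if query.strand_filter is not None and query.strand_filter not in ("+", "-"):
        raise QueryError(
            f"strand filter must be '+' or '-', got {query.strand_filter!r}"
        )
    for l in missing_condition_labels(query, sites):
        log.warning("condition label %r not present in the input sites", l)
    return query


def subset_sites(
    sites: SiteSet,
    seqnames: Iterable[str] | None = None,
    strand_filter: str | None = None,
) -> SiteSet:
    """Restrict the search space to given seqnames and/or one strand."""
    if strand_filter is not None and strand_filter not in ("+", "-"):
        raise QueryError(
            f"strand filter must be '+' or '-', got {strand_filter!r}"
        )
    if seqnames is None and strand_filter is None:
        return sites
    return sites.filtered(seqnames=seqnames, strand=strand_filter)


def check_combination(
    label_counts: Mapping[str, int], conditions: Mapping[str, int]
) -> tuple[bool, str | None]:
    """Test observed per-label counts against the condition mapping.

    Returns ``(ok, failure_kind)``: ok iff every positive condition is met
    (observed >= required) and every excluded label is absent.  The failure
    kind is ``"excluded"`` when an excluded label is present (reported in
    preference to a count shortfall) else ``"insufficient"``.
    """
    excluded_hit = any(
        label_counts.get(l, 0) > 0 for l, n in conditions.items() if n == 0
    )
    short = any(
        label_counts.get(l, 0) < n for l, n in conditions.items() if n > 0
    )
    if excluded_hit:
        return False, EXCLUDED
    if short:
        return False, INSUFFICIENT
    return True, None


# ---------------------------------------------------------------------------
# candidate enumeration


def _enumerate_seqname(
    sites: Sequence[GenomicSite], query: ClusterQuery
) -> list[Cluster]:
    """Candidates on one seqname; ``sites`` are condition-label sites, sorted.

    Every site anchors a window [anchor.start, anchor.start + w - 1]; the
    candidate universe is every site fully contained in it, in sorted order.
    Non-greedy takes the shortest prefix of the universe meeting all positive
    conditions, trims the span to first-member start .. max member end, then
    re-expands the member set to ALL condition-label sites inside that span.
    Greedy takes the whole universe.  Identical spans are deduplicated.
    """
    if not sites:
        return []
    starts = [s.start for s in sites]
    need = query.positive_conditions
    total_needed = sum(need.values())
    w1 = query.w - 1
    greedy = query.greedy
    seen: set[tuple[int, int]] = set()
    out: list[Cluster] = []

    for anchor in sites:
        a_start = anchor.start
        limit = a_start + w1
        lo = bisect_left(starts, a_start)
        hi = bisect_right(starts, limit)
        if hi - lo < total_needed:
            continue
        if greedy:
            span_start = None
            span_end = 0
            counts: Counter[str] = Counter()
            for j in range(lo, hi):
                s = sites[j]
                if s.end > limit:
                    continue
                if span_start is None:
                    span_start = s.start
                if s.end > span_end:
                    span_end = s.end
                counts[s.label] += 1
            if span_start is None:
                continue
            if any(counts[l] < n for l, n in need.items()):
                continue
        else:
            remaining = dict(need)
            deficit = total_needed
            span_start = None
            span_end = 0
            satisfied = False
            for j in range(lo, hi):
                s = sites[j]
                if s.end > limit:
                    continue
                if span_start is None:
                    span_start = s.start
                if s.end > span_end:
                    span_end = s.end
                r = remaining.get(s.label, 0)
                if r > 0:
                    remaining[s.label] = r - 1
                    deficit -= 1
                    if deficit == 0:
                        satisfied = True
                        break
            if not satisfied:
                continue
        key = (span_start, span_end)
        if key in seen:
            continue
        seen.add(key)
        # re-expand members to every condition-label site inside the span
        mlo = bisect_left(starts, span_start)
        mhi = bisect_right(starts, span_end)
        members = tuple(
            sites[j] for j in range(mlo, mhi) if sites[j].end <= span_end
        )
        out.append(
            Cluster(
                seqname=anchor.seqname,
                start=span_start,
                end=span_end,
                members=members,
                label_counts=dict(Counter(m.label for m in members)),
                status=PASS,
            )
        )
    out.sort(key=lambda c: (c.start, c.end))
    return out


def enumerate_candidates(sites: SiteSet, query: ClusterQuery) -> list[Cluster]:
    """All candidate clusters (status PASS, grammar checks not yet applied).

    Sites with labels outside ``query.conditions`` are dropped first; the
    enumeration runs one seqname at a time.
    """
    cond = query.conditions
    by_seq: dict[str, list[GenomicSite]] = {}
    for s in sites:
        if s.label in cond:
            by_seq.setdefault(s.seqname, []).append(s)
    out: list[Cluster] = []
    for seq in sorted(by_seq):
        out.extend(_enumerate_seqname(by_seq[seq], query))
    return out


# ---------------------------------------------------------------------------
# order / orientation


def _has_subsequence(
    members: Sequence[GenomicSite],
    labels: Sequence[str],
    strands: Sequence[str] | None,
) -> bool:
    # Greedy leftmost matching is optimal for fixed-pattern subsequence search.
    i = 0
    k = len(labels)
    for m in members:
        if m.label == labels[i] and (strands is None or m.strand == strands[i]):
            i += 1
            if i == k:
                return True
    return False


def match_order_orientation(
    members: Sequence[GenomicSite],
    order: Sequence[str],
    orientation: Sequence[str] | None = None,
    greedy: bool = False,
) -> str:
    """Test the order (and optional orientation) grammar on sorted members.

    PASS iff some strictly position-increasing subsequence of the members
    matches the order labels — and, when orientation is given, the strands
    too (a "."-stranded member never satisfies an orientation entry).  Any
    satisfying sub-arrangement ("subcluster") is enough; surplus members may
    interleave freely, in greedy and non-greedy mode alike.  Returns
    ``orderFail`` when no label subsequence exists, ``orientationFail`` when
    a label subsequence exists but none is strand-consistent.
    """
    del greedy  # same subsequence semantics in both modes
    if not _has_subsequence(members, order, None):
        return ORDER_FAIL
    if orientation is not None and not _has_subsequence(members, order, orientation):
        return ORIENTATION_FAIL
    return PASS


# ---------------------------------------------------------------------------
# adjacency


def filter_adjacent(clusters: Sequence[Cluster], overlap: int) -> list[Cluster]:
    """Apply the inter-cluster spacing rule to sorted PASS clusters.

    Left-to-right sweep per seqname: the first cluster is kept; each later
    cluster is compared with the last *kept* one.  With ``overlap >= 0`` the
    gap ``next.start - kept.end - 1`` must be at least ``overlap``; with
    ``overlap < 0`` the shared extent ``max(0, kept.end - next.start + 1)``
    must not exceed ``-overlap``.  Dropped clusters are returned with status
    ``adjacencyFail``.
    """
    out: list[Cluster] = []
    last_kept: Cluster | None = None
    for c in clusters:
        if last_kept is None or c.seqname != last_kept.seqname:
            out.append(c)
            last_kept = c
            continue
        if overlap >= 0:
            ok = c.start - last_kept.end - 1 >= overlap
        else:
            ok = max(0, last_kept.end - c.start + 1) <= -overlap
        if ok:
            out.append(c)
            last_kept = c
        else:
            out.append(replace(c, status=ADJACENCY_FAIL))
    return out


# ---------------------------------------------------------------------------
# full pipeline


def _scan_once(sites: SiteSet, query: ClusterQuery) -> list[Cluster]:
    """Pipeline on an already-validated query; returns sorted clusters
    (all statuses, adjacency applied)."""
    work = subset_sites(sites, query.seqnames, query.strand_filter)
    candidates = enumerate_candidates(work, query)
    excluded = query.excluded_labels
    checked: list[Cluster] = []
    for cand in candidates:
        if excluded and any(m.label in excluded for m in cand.members):
            checked.append(replace(cand, status=EXCLUDED_SITE_FAIL))
        elif query.order is not None:
            status = match_order_orientation(
                cand.members, query.order, query.orientation, query.greedy
            )
            checked.append(replace(cand, status=status) if status != PASS else cand)
        else:
            checked.append(cand)
    checked.sort(key=lambda c: (c.seqname, c.start, c.end))
    passing = [c for c in checked if c.status == PASS]
    failing = [c for c in checked if c.status != PASS]
    swept = filter_adjacent(passing, query.overlap)
    merged = swept + failing
    merged.sort(key=lambda c: (c.seqname, c.start, c.end))
    return merged


def scan(sites: SiteSet, query: ClusterQuery, *, workers: int = 1) -> ScanResult:
    """Run the full cluster scan.

    ``workers`` partitions the seqnames into that many groups scanned
    independently and merged; because every stage of the pipeline operates
    one seqname at a time, the partitioning never changes the result (this
    is the contract that makes per-chromosome parallel execution safe).
    """
    query = validate_query(query, sites)
    warnings = tuple(
        f"condition label '{l}' has count > 0 but no such site in the input"
        for l in missing_condition_labels(query, sites)
    )
    work = subset_sites(sites, query.seqnames, query.strand_filter)
    if workers > 1:
        names = work.seqnames
        groups = [set(names[g::workers]) for g in range(workers)]
        clusters: list[Cluster] = []
        for grp in groups:
            if grp:
                clusters.extend(_scan_once(work.filtered(seqnames=grp), query))
        clusters.sort(key=lambda c: (c.seqname, c.start, c.end))
    else:
        clusters = _scan_once(work, query)
    if not query.verbose:
        clusters = [c for c in clusters if c.status == PASS]
    return ScanResult(tuple(clusters), query, warnings)
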