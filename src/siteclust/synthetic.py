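"""Synthetic site collections, a brute-force reference scanner, and a
hand-built worked example.

``simulate_sites`` emulates a large heterotypic benchmark: by default one
million sites of three categories (a/b/c), 7-10 bp wide, scattered uniformly
over five 10-Mb chromosomes — dense enough (one site per ~50 bp) that
windowed co-occurrence is frequent but not saturated.

``brute_force_scan`` is an exhaustive re-implementation of the cluster
grammar sharing only the data types with the fast engine, never its
enumeration code; it exists so engine results can be checked for exact
equality on small instances.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import engine
from .engine import (
    ADJACENCY_FAIL,
    EXCLUDED_SITE_FAIL,
    ORDER_FAIL,
    ORIENTATION_FAIL,
    PASS,
    Cluster,
    ClusterQuery,
    ScanResult,
    missing_condition_labels,
    validate_query,
)
from .model import GenomicSite, SiteSet

__all__ = ["SimSpec", "simulate_sites", "brute_force_scan", "worked_example"]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the uniform-placement site simulator.

    Defaults describe the heterotypic benchmark condition: 10^6 sites,
    labels a/b/c with equal weight, widths uniform on [7, 10] bp, five
    chromosomes of 10 Mb each, strands equiprobable.
    """

    n_sites: int = 1_000_000
    labels: tuple[str, ...] = ("a", "b", "c")
    weights: tuple[float, ...] | None = None
    width_range: tuple[int, int] = (7, 10)
    n_chroms: int = 5
    chrom_length: int = 10_000_000
    strand_probs: tuple[float, float] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if not self.labels:
            raise ValueError("need at least one label")
        if self.weights is not None and len(self.weights) != len(self.labels):
            raise ValueError("weights must parallel labels")
        lo, hi = self.width_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad width range {self.width_range}")
        if self.n_chroms < 1:
            raise ValueError("need at least one chromosome")
        if self.chrom_length < hi:
            raise ValueError(
                f"chrom_length {self.chrom_length} is shorter than the "
                f"maximum site width {hi}"
            )


def simulate_sites(spec: SimSpec) -> SiteSet:
    """Draw a random :class:`SiteSet` according to ``spec`` (seeded, so the
    same spec always yields the same set)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sites
    if n == 0:
        return SiteSet([])
    lo, hi = spec.width_range
    widths = rng.integers(lo, hi + 1, size=n)
    chrom_idx = rng.integers(0, spec.n_chroms, size=n)
    # uniform start in [1, L - width + 1] so the site fits on the chromosome
    starts = rng.integers(1, spec.chrom_length - widths + 2)
    weights = spec.weights
    p = None if weights is None else np.asarray(weights, dtype=float) / sum(weights)
    label_idx = rng.choice(len(spec.labels), size=n, p=p)
    pp, pm = spec.strand_probs
    strand_idx = rng.choice(2, size=n, p=[pp / (pp + pm), pm / (pp + pm)])
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    strand_sym = ("+", "-")
    labels = spec.labels
    sites = [
        GenomicSite(
            seqname=chrom_names[chrom_idx[i]],
            start=int(starts[i]),
            end=int(starts[i] + widths[i] - 1),
            strand=strand_sym[strand_idx[i]],
            label=labels[label_idx[i]],
            source="simulated",
        )
        for i in range(n)
    ]
    return SiteSet(sites)


# ---------------------------------------------------------------------------
# exhaustive reference scanner


def _counts_ok(counts: Counter, conditions) -> bool:
    return all(counts.get(l, 0) >= n for l, n in conditions.items() if n > 0)


def _order_assignment_exists(
    members: Sequence[GenomicSite],
    order: Sequence[str],
    orientation: Sequence[str] | None,
) -> bool:
    """Exhaustive backtracking search for a position-increasing assignment of
    members to order slots (label must match; strand too when given)."""

    def rec(slot: int, start_idx: int) -> bool:
        if slot == len(order):
            return True
        for i in range(start_idx, len(members)):
            m = members[i]
            if m.label != order[slot]:
                continue
            if orientation is not None and m.strand != orientation[slot]:
                continue
            if rec(slot + 1, i + 1):
                return True
        return False

    return rec(0, 0)


def brute_force_scan(sites: SiteSet, query: ClusterQuery) -> ScanResult:
    """Exhaustive scan with the identical output contract to :func:`engine.scan`.

    Every anchored window is materialized site-by-site; non-greedy minimality
    is established by testing every prefix; order/orientation by exhaustive
    subsequence search; exclusion by scanning the whole span.  Intended for
    small inputs (hundreds of sites).
    """
    query = validate_query(query, sites)
    warnings = tuple(
        f"condition label '{l}' has count > 0 but no such site in the input"
        for l in missing_condition_labels(query, sites)
    )
    cond = query.conditions
    work = [
        s
        for s in sites
        if s.label in cond
        and (query.seqnames is None or s.seqname in query.seqnames)
        and (query.strand_filter is None or s.strand == query.strand_filter)
    ]
    excluded = {l for l, n in cond.items() if n == 0}

    clusters: list[Cluster] = []
    for seq in sorted({s.seqname for s in work}):
        ssites = [s for s in work if s.seqname == seq]  # already sorted
        spans_seen: set[tuple[int, int]] = set()
        for anchor in ssites:
            limit = anchor.start + query.w - 1
            universe = [
                s for s in ssites if s.start >= anchor.start and s.end <= limit
            ]
            if not universe:
                continue
            if query.greedy:
                if not _counts_ok(Counter(s.label for s in universe), cond):
                    continue
                chosen = universe
            else:
                chosen = None
                for k in range(1, len(universe) + 1):
                    if _counts_ok(Counter(s.label for s in universe[:k]), cond):
                        chosen = universe[:k]
                        break
                if chosen is None:
                    continue
            span = (chosen[0].start, max(s.end for s in chosen))
            if span in spans_seen:
                continue
            spans_seen.add(span)
            members = tuple(
                s for s in ssites if s.start >= span[0] and s.end <= span[1]
            )
            counts = Counter(m.label for m in members)
            if any(counts.get(l, 0) > 0 for l in excluded):
                status = EXCLUDED_SITE_FAIL
            elif query.order is not None:
                if _order_assignment_exists(members, query.order, query.orientation):
                    status = PASS
                elif _order_assignment_exists(members, query.order, None):
                    status = ORIENTATION_FAIL
                else:
                    status = ORDER_FAIL
            else:
                status = PASS
            clusters.append(
                Cluster(
                    seqname=seq,
                    start=span[0],
                    end=span[1],
                    members=members,
                    label_counts=dict(counts),
                    status=status,
                )
            )

    clusters.sort(key=lambda c: (c.seqname, c.start, c.end))
    # naive adjacency sweep, re-implemented independently of the engine
    final: list[Cluster] = []
    last_kept_by_seq: dict[str, Cluster] = {}
    for c in clusters:
        if c.status != PASS:
            final.append(c)
            continue
        prev = last_kept_by_seq.get(c.seqname)
        keep = True
        if prev is not None:
            if query.overlap >= 0:
                gap = c.start - prev.end - 1
                keep = gap >= query.overlap
            else:
                shared = prev.end - c.start + 1
                if shared < 0:
                    shared = 0
                keep = shared <= -query.overlap
        if keep:
            last_kept_by_seq[c.seqname] = c
            final.append(c)
        else:
            final.append(
                Cluster(
                    seqname=c.seqname,
                    start=c.start,
                    end=c.end,
                    members=c.members,
                    label_counts=c.label_counts,
                    status=ADJACENCY_FAIL,
                )
            )
    if not query.verbose:
        final = [c for c in final if c.status == PASS]
    return ScanResult(tuple(final), query, warnings)


# ---------------------------------------------------------------------------
# worked example


def worked_example() -> tuple[SiteSet, ClusterQuery]:
    """Hand-placed demonstration of the full grammar on one chromosome.

    Three site categories — circle, square, triangle — with the query
    "one circle and one square within 200 bp, no triangle, circle before
    square, both on the + strand".  Five well-separated cases:

    1. circle(+) then square(+) within the window          -> PASS
    2. the pair with a triangle in between                 -> excludedSiteFail
    3. the pair spread wider than the window               -> no candidate
    4. square before circle (combination, wrong order)     -> orderFail
    5. circle(+) then square(-) (right order, wrong strand)-> orientationFail

    Coordinates are fixture constants; the scan of this fixture yields
    exactly one PASS cluster and, in verbose mode, one cluster for each of
    the failure statuses above.
    """
    mk = lambda start, end, strand, label: GenomicSite(
        "chr1", start, end, strand, label, source="worked-example"
    )
    sites = SiteSet(
        [
            # case 1: the one correct cluster
            mk(100, 110, "+", "circle"),
            mk(150, 160, "+", "square"),
            # case 2: excluded triangle inside the span
            mk(1000, 1010, "+", "circle"),
            mk(1030, 1036, "+", "triangle"),
            mk(1050, 1060, "+", "square"),
            # case 3: combination wider than the 200 bp window
            mk(2000, 2010, "+", "circle"),
            mk(2300, 2310, "+", "square"),
            # case 4: square before circle
            mk(3000, 3010, "+", "square"),
            mk(3050, 3060, "+", "circle"),
            # case 5: correct order, square on the wrong strand
            mk(4000, 4010, "+", "circle"),
            mk(4050, 4060, "-", "square"),
        ]
    )
    query = ClusterQuery(
        w=200,
        conditions={"circle": 1, "square": 1, "triangle": 0},
        order=("circle", "square"),
        orientation=("+", "+"),
        greedy=False,
        verbose=True,
    )
    return sites, query
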