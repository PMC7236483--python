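# Methods

## The clustering model

`siteclust` searches a collection of labeled genomic intervals ("sites") for
*clusters*: runs of sites on one chromosome whose extent fits inside a window
of `w` bp and whose composition obeys a user-defined grammar.  The motivating
use cases are cis-regulatory modules — combinations of transcription-factor
binding sites with, sometimes, a required order and strand orientation — and
loci where ChIP-seq peaks co-occur with dense somatic variation.

A site is a 1-based, closed interval `(seqname, start, end, strand, label)`;
`width = end − start + 1`.  The query is:

- **window `w`** — maximum cluster extent, measured from the start of the
  cluster's first site to the end of its last site (inclusive: extent
  exactly `w` passes);
- **conditions** `{label: count}` — `count > 0` is a *minimum* ("at least
  n sites of this label"); `count = 0` marks the label as *excluded*: any
  such site contained in the cluster span disqualifies it.  Surplus sites of
  required labels never invalidate a cluster — the greedy mode, which
  deliberately absorbs extra sites, forces the "at least" reading;
- **order / orientation** — an optional left-to-right label sequence, and
  optionally a parallel strand sequence, that some subsequence of the
  cluster's members must realize;
- **greedy** — off: a cluster is the shortest satisfying run; on: the
  cluster absorbs every site that fits in the window;
- **overlap** — signed spacing between consecutive reported clusters
  (`≥ 0`: minimum gap in bp; `< 0`: maximum permitted overlap of
  `−overlap` bp);
- **seqnames / strand filter** — optional input restriction;
- **verbose** — report rejected candidates with a failure status
  (`excludedSiteFail`, `orderFail`, `orientationFail`, `adjacencyFail`)
  instead of silently dropping them.

Sites whose labels are absent from the conditions mapping are invisible to
every stage: they contribute nothing to extent, counts, order, or exclusion.
The grammar's alphabet is exactly the condition labels.

## The scan algorithm

Sites are normalized to a total order (seqname, start, end, label, strand),
which makes every result deterministic and independent of input record
order.  Each seqname is processed independently:

1. **Anchoring.** Every site anchors a window `[start, start + w − 1]`.
   The anchor's *candidate universe* is every site fully contained in that
   window, in sorted order.
2. **Selection.** Non-greedy: the shortest prefix of the universe whose
   per-label counts meet all positive conditions; the span is trimmed to
   first-member start … maximum member end, and the member set is then
   re-expanded to *all* condition-label sites contained in the trimmed span
   (so counts and exclusion always describe the reported region, not the
   enumeration path).  Greedy: the candidate is the whole universe.
   Anchors with no satisfying candidate yield nothing; identical spans from
   different anchors are deduplicated.
3. **Exclusion.** A candidate whose span contains any excluded-label site
   fails (`excludedSiteFail`).  "Contains" means full containment; an
   excluded site merely overlapping the span boundary is legal.
4. **Order/orientation.** When an order is given, the members must admit a
   strictly position-increasing assignment to the order entries — a
   subsequence match, so any satisfying sub-arrangement ("subcluster")
   suffices and surplus members may interleave.  This one rule applies in
   greedy and non-greedy mode alike; the greedy subcluster behavior requires
   subsequence logic, and using it uniformly keeps the grammar coherent.
   A strand of "." never satisfies an orientation entry.  A label-only
   match without a strand-consistent one is `orientationFail`; no label
   match is `orderFail`.
5. **Adjacency.** PASS clusters are swept left to right per seqname; each
   cluster is compared with the last *kept* one under the `overlap` rule and
   dropped (`adjacencyFail`) on violation.  Keeping the earliest cluster of
   a violating pair is deterministic and input-order independent.

Because all stages are per-seqname, scanning any partition of the seqnames
separately and concatenating gives exactly the whole-input result.  That
invariance is the contract that makes per-chromosome parallel execution
safe; `scan(..., workers=k)` exercises it by round-robin partitioning (the
work is still executed sequentially — users wanting wall-clock speedups can
dispatch per-seqname scans to any process pool).

Complexity: with sites sorted, each anchor does a binary search plus a walk
over its window's contents, so the scan is O(n log n + Σ window occupancy).
One million uniformly placed sites over five 10-Mb chromosomes scan in a few
seconds at w = 100 on a single core.

## The synthetic generator

`simulate_sites(SimSpec())` draws, by default, 10⁶ sites of three
heterotypic labels a/b/c with equal weight, widths uniform on [7, 10] bp,
uniform placement over five chromosomes, strands equiprobable — the
large-scale benchmark condition this package is sized against.  Chromosome
length defaults to 10 Mb, giving one site per ~50 bp, dense enough that
windowed co-occurrence is common but unsaturated.  The generator emulates
*placement statistics only*: real binding-site data are clumped (open
chromatin, CpG islands), strand-correlated, and width-structured per factor,
none of which uniform placement reproduces.  Passing tests therefore
demonstrate algorithmic correctness and scale behavior, not biological
recall on real tracks.

`brute_force_scan` is an exhaustive reference implementation sharing only
the data types with the engine: universes are materialized by linear scans,
non-greedy minimality by testing every prefix, order/orientation by
backtracking over all assignments, and the adjacency sweep is re-implemented
naively.  Engine/oracle equality is asserted exactly (spans, members,
statuses) over a deterministic grid of queries (w ∈ {50, 200, 500}, greedy
on/off, order none/order/orientation, overlap ∈ {−20, 0, 20}) on more than
1000 randomized small instances.

## Numerical and design choices

- **Coordinates.** Internally 1-based closed everywhere; BED's 0-based
  half-open convention is converted at the I/O boundary in both directions.
  VCF records span their REF allele (`POS … POS + len(REF) − 1`), so
  deletions occupy their true extent; FILTER/QUAL are ignored (pre-filter
  upstream if needed).
- **Verbatim seqnames.** "chr7" ≠ "7"; mixing styles logs a warning rather
  than silently harmonizing, since a silent merge produces wrong joins.
- **Duplicates.** Identical sites are retained and each copy counts toward
  the conditions; deduplication is the caller's decision, not the scanner's.
- **Tie-breaks.** All sorting uses the total order above; the adjacency
  sweep keeps the earliest cluster of a conflicting pair.
- **Degenerate inputs.** Empty inputs produce empty results; a required
  label absent from the data is a warning, not an error (the absence may be
  the biological answer); all-zero conditions, `w < 1`, orientation without
  order, or order naming an excluded/unknown label are errors.
- **Window monotonicity.** For equal-width sites, growing the window can
  only add PASS clusters: the non-greedy PASS set at `w` recurs identically
  at any `w' > w` (with equal widths, start order equals end order, so no
  site can straddle the smaller window's limit and reshape a minimal run).
  With variable widths that exact subset relation can fail — a site whose
  end lies just beyond `anchor + w − 1` enters the larger window's universe
  mid-order and can terminate the minimal run with a larger span end — and
  what holds instead is span containment: for exclusion-free queries, every
  PASS span at `w` is contained (same start, equal-or-larger end) in a PASS
  span at `w'`.  The property tests assert both forms in their respective
  regimes.
- **Greedy containment.** For exclusion-free queries, every non-greedy PASS
  span is contained in some greedy PASS span under the same query (the
  greedy candidate from the same anchor has the same start, a
  superset universe, and therefore preserves any order witness).

## Known limitations

- Clusters never cross seqnames, and there is no probabilistic scoring,
  motif/PWM scanning, or conservation filtering — upstream tools produce
  the input sites.
- The uniform simulator understates clustering in real data (see above).
- Order matching uses subsequence semantics; an exact-sequence ("strict")
  mode would be a separate flag and is not implemented.
- GFF/GTF, bigBed, and remote inputs are out of scope; the tool is sequence-
  and genome-independent and never touches a reference FASTA.
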