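# siteclust

Grammar-constrained windowed clustering of labeled genomic sites.

Many questions in regulatory genomics reduce to: *where do given categories
of genomic features co-occur within a bounded stretch of DNA, in a
particular arrangement?*  Cis-regulatory modules are combinations of
transcription-factor binding sites inside ~200–500 bp, sometimes with a
required order and strand orientation; TAD boundaries carry oriented
CTCF/cohesin site clusters; cancer genomes harbor windows dense in somatic
SNVs around disrupted binding sites.  `siteclust` is for computational
biologists who already have such features as genomic intervals — ChIP-seq
peaks, motif/PWM hits, variant calls — and want the clusters, with full
control over the grammar, from Python or the shell.

## The model

A *site* is a labeled, stranded, 1-based closed interval.  Given a window
size `w` and conditions `c = {a: 2, b: 2, c: 0}` (at least two `a`, at
least two `b`, **no** `c`), a cluster is a run of sites on one seqname with

```
extent = end_last_site − start_first_site + 1 ≤ w
```

whose member counts satisfy every positive condition and whose span
contains no excluded-label site.  Optional constraints: a left-to-right
label `order` with per-position strand `orientation` (matched as a
subsequence, so any satisfying "subcluster" suffices); `greedy` extension
(absorb every site that fits the window, not just the minimal run); and a
signed `overlap` spacing rule between consecutive reported clusters
(`20` = at least 20 bp gap, `−20` = at most 20 bp overlap).  With
`verbose`, rejected candidates are reported with a status naming the first
failed check: `excludedSiteFail`, `orderFail`, `orientationFail`,
`adjacencyFail`.  See `docs/methods.md` for the algorithm and its
guarantees.

## Worked example

Search for "one circle then one square, both on +, within 200 bp, no
triangle anywhere in the cluster" over three BED files:

```sh
siteclust scan \
  --bed circle.bed=circle --bed square.bed=square --bed triangle.bed=triangle \
  --window 200 \
  --condition circle=1 --condition square=1 --condition triangle=0 \
  --order circle,square --orientation +,+ \
  --verbose --report -
```

```
INFO siteclust: loaded 11 sites from 3 file(s)
INFO siteclust: 1 PASS cluster(s) (3 rejected candidates reported)
seqname start   end     width  n_sites n_circle n_square n_triangle members                                                     status
chr1    100     160     61     2       1        1        0          circle:100-110:+,square:150-160:+                           PASS
chr1    1000    1060    61     3       1        1        1          circle:1000-1010:+,triangle:1030-1036:+,square:1050-1060:+  excludedSiteFail
chr1    3000    3060    61     2       1        1        0          square:3000-3010:+,circle:3050-3060:+                       orderFail
chr1    4000    4060    61     2       1        1        0          circle:4000-4010:+,square:4050-4060:-                       orientationFail
```

One cluster is called: circle at 100–110 followed by square at 150–160,
extent 61 bp, both on "+".  The three rejected candidates show why verbose
mode is useful: a triangle inside the span, the right combination in the
wrong order, and the right order on the wrong strand.  (A fourth
circle/square pair, spread over 311 bp, never becomes a candidate at all —
extent violations produce no cluster rather than a failed one.)  Omitting
`--report -` and passing `--out clusters.bed` writes BED6 instead; this
fixture is available programmatically as `siteclust.worked_example()`.

The same query from Python:

```python
import siteclust as sc

sites = sc.collate_inputs(
    ["circle.bed", "square.bed", "triangle.bed"],
    labels=["circle", "square", "triangle"],
)
query = sc.ClusterQuery(
    w=200,
    conditions={"circle": 1, "square": 1, "triangle": 0},
    order=("circle", "square"),
    orientation=("+", "+"),
    verbose=True,
)
result = sc.scan(sites, query)     # result.passes -> one Cluster, 100-160
sc.write_clusters(result, bed_path="clusters.bed", table_path="clusters.tsv")
```

Inputs may mix BED, VCF (`--vcf cosmic.vcf=snp`; records span their REF
allele) and labeled TSV tables; files given without `=label` are labeled
`"1"`, `"2"`, … in flag order.  `siteclust simulate --n 1000000 --seed 7
--out sites.tsv` generates the benchmark-style random dataset (three
heterotypic 7–10 bp site types over five chromosomes).

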