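"""Readers and writers for the standard interval formats.

Input: BED (3-6 column, 0-based half-open), VCF 4.x (plain or bgzipped,
via cyvcf2), and labeled TSV tables (1-based closed, with an explicit
``site`` column).  Output: BED6 plus a TSV cluster report.  The internal
convention is 1-based closed everywhere; BED coordinates are converted on
the boundary in both directions.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .engine import ScanResult
from .model import GenomicSite, SiteSet

__all__ = [
    "ParseError",
    "read_bed",
    "read_vcf",
    "read_table",
    "collate_inputs",
    "write_clusters",
    "write_sites_table",
    "write_sites_bed",
]


class ParseError(ValueError):
    """Malformed input file; the message names the file and offending record."""


_BED_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path: str | os.PathLike, label: str) -> SiteSet:
    """Read a BED3+ file, assigning every site the given label.

    BED is 0-based half-open; a line ``chr1  99  110`` becomes the 1-based
    closed site chr1:100-110.  Strand is taken from column 6 when present,
    else ".".  Name/score columns are ignored.
    """
    path = Path(path)
    sites: list[GenomicSite] = []
    try:
        text = path.read_text()
    except OSError as e:
        raise ParseError(f"{path}: cannot read BED file: {e}") from e
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"{path}: line {lineno}: BED needs >= 3 tab-separated "
                f"columns, got {len(fields)}"
            )
        try:
            bed_start = int(fields[1])
            bed_end = int(fields[2])
        except ValueError as e:
            raise ParseError(
                f"{path}: line {lineno}: non-integer BED coordinates "
                f"({fields[1]!r}, {fields[2]!r})"
            ) from e
        if bed_start >= bed_end:
            raise ParseError(
                f"{path}: line {lineno}: zero- or negative-width BED "
                f"interval ({bed_start} >= {bed_end})"
            )
        if bed_start < 0:
            raise ParseError(f"{path}: line {lineno}: negative BED start")
        strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
        sites.append(
            GenomicSite(
                seqname=fields[0],
                start=bed_start + 1,
                end=bed_end,
                strand=strand,
                label=label,
                source=str(path),
            )
        )
    return SiteSet(sites, input_manifest=[(str(path), "bed", label)])


def read_vcf(path: str | os.PathLike, label: str) -> SiteSet:
    """Read a VCF (plain or bgzipped), assigning every record the label.

    Each record spans its REF allele: start = POS, end = POS + len(REF) - 1,
    so SNPs are 1 bp and deletions occupy their true genomic extent.
    Strand is "." (variants are unstranded).  FILTER and QUAL are ignored:
    every record is loaded; pre-filter upstream if needed.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        reader = VCF(str(path))
    except Exception as e:  # cyvcf2 raises bare Exception subclasses
        raise ParseError(f"{path}: not a readable VCF: {e}") from e
    sites: list[GenomicSite] = []
    try:
        for rec in reader:
            ref = rec.REF or ""
            if not ref:
                raise ParseError(
                    f"{path}: record {rec.CHROM}:{rec.POS} has an empty REF"
                )
            sites.append(
                GenomicSite(
                    seqname=rec.CHROM,
                    start=rec.POS,
                    end=rec.POS + len(ref) - 1,
                    strand=".",
                    label=label,
                    source=str(path),
                )
            )
    except ParseError:
        raise
    except Exception as e:
        raise ParseError(f"{path}: malformed VCF record: {e}") from e
    finally:
        reader.close()
    return SiteSet(sites, input_manifest=[(str(path), "vcf", label)])


_TABLE_REQUIRED = ("seqname", "start", "end")


def read_table(path: str | os.PathLike, label: str | None = None) -> SiteSet:
    """Read a labeled TSV (header: seqname/start/end[/strand]/site, 1-based closed).

    The ``site`` column supplies per-row labels; an explicit ``label``
    argument overrides it.  Without either, the table is rejected: the
    clustering grammar needs a site category for every interval.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"seqname": str})
    except OSError as e:
        raise ParseError(f"{path}: cannot read table: {e}") from e
    except Exception as e:
        raise ParseError(f"{path}: malformed TSV table: {e}") from e
    missing = [c for c in _TABLE_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: table is missing column(s) {missing}")
    if label is None and "site" not in df.columns:
        raise ParseError(
            f"{path}: tabular input must carry a 'site' column naming each "
            "row's category (or pass an explicit label for the whole file)"
        )
    has_strand = "strand" in df.columns
    sites: list[GenomicSite] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            sites.append(
                GenomicSite(
                    seqname=str(getattr(row, "seqname")),
                    start=int(getattr(row, "start")),
                    end=int(getattr(row, "end")),
                    strand=str(getattr(row, "strand")) if has_strand else ".",
                    label=label if label is not None else str(getattr(row, "site")),
                    source=str(path),
                )
            )
        except (ValueError, TypeError) as e:
            raise ParseError(f"{path}: line {idx}: {e}") from e
    manifest_label = label if label is not None else "<site column>"
    return SiteSet(sites, input_manifest=[(str(path), "table", manifest_label)])


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".bed"):
        return "bed"
    if name.endswith(".vcf") or name.endswith(".vcf.gz"):
        return "vcf"
    if name.endswith((".tsv", ".tab", ".txt")):
        return "table"
    raise ParseError(
        f"{path}: cannot infer format from extension "
        "(expected .bed, .vcf[.gz], .tsv/.tab/.txt)"
    )


def collate_inputs(
    paths: Sequence[str | os.PathLike],
    labels: Sequence[str] | None = None,
    formats: Sequence[str] | None = None,
) -> SiteSet:
    """Read several input files into one merged, sorted :class:`SiteSet`.

    When ``labels`` is omitted, file k (1-based, in input order) contributes
    the label ``"k"`` — except tabular files, which carry their own ``site``
    column.  Explicit labels override both.  ``formats`` (entries "bed",
    "vcf", "table") overrides extension-based inference.
    """
    if labels is not None and len(labels) != len(paths):
        raise ValueError(
            f"got {len(labels)} labels for {len(paths)} input files"
        )
    if formats is not None and len(formats) != len(paths):
        raise ValueError(
            f"got {len(formats)} format overrides for {len(paths)} input files"
        )
    merged: list[GenomicSite] = []
    manifest: list[tuple[str, str, str]] = []
    for k, p in enumerate(paths, start=1):
        path = Path(p)
        fmt = formats[k - 1] if formats is not None else _infer_format(path)
        explicit = labels[k - 1] if labels is not None else None
        if fmt == "bed":
            part = read_bed(path, explicit if explicit is not None else str(k))
        elif fmt == "vcf":
            part = read_vcf(path, explicit if explicit is not None else str(k))
        elif fmt == "table":
            part = read_table(path, explicit)
        else:
            raise ValueError(f"unknown input format {fmt!r} for {path}")
        merged.extend(part.sites)
        manifest.extend(part.input_manifest)
    return SiteSet(merged, input_manifest=manifest)


# ---------------------------------------------------------------------------
# output


def _report_columns(result: ScanResult) -> list[str]:
    cond_labels = sorted(result.query.conditions)
    return (
        ["seqname", "start", "end", "width", "n_sites"]
        + [f"n_{l}" for l in cond_labels]
        + ["members", "status"]
    )


def write_clusters(
    result: ScanResult,
    bed_path: str | os.PathLike | None = None,
    table_path: str | os.PathLike | None = None,
) -> None:
    """Write a scan result as BED6 and/or a TSV report.

    BED rows are 0-based half-open; the name column joins the ordered member
    labels with "_" and the score is the member count.  The TSV report has
    one per-label count column per condition label plus an ordered member
    descriptor column (``label:start-end:strand``, comma-joined) and the
    cluster status.  With verbose off the result contains only PASS rows.
    """
    if bed_path is not None:
        lines = []
        for c in result.clusters:
            name = "_".join(m.label for m in c.members)
            lines.append(
                f"{c.seqname}\t{c.start - 1}\t{c.end}\t{name}\t{len(c.members)}\t."
            )
        Path(bed_path).write_text("".join(l + "\n" for l in lines))
    if table_path is not None:
        cond_labels = sorted(result.query.conditions)
        rows = []
        for c in result.clusters:
            row = {
                "seqname": c.seqname,
                "start": c.start,
                "end": c.end,
                "width": c.width,
                "n_sites": len(c.members),
            }
            for l in cond_labels:
                row[f"n_{l}"] = c.label_counts.get(l, 0)
            row["members"] = ",".join(
                f"{m.label}:{m.start}-{m.end}:{m.strand}" for m in c.members
            )
            row["status"] = c.status
            rows.append(row)
        df = pd.DataFrame(rows, columns=_report_columns(result))
        df.to_csv(table_path, sep="\t", index=False)


def write_sites_table(sites: SiteSet, path: str | os.PathLike) -> None:
    """Write sites as the labeled TSV accepted by :func:`read_table`."""
    df = pd.DataFrame(
        {
            "seqname": [s.seqname for s in sites],
            "start": [s.start for s in sites],
            "end": [s.end for s in sites],
            "strand": [s.strand for s in sites],
            "site": [s.label for s in sites],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_sites_bed(
    sites: Iterable[GenomicSite], path: str | os.PathLike
) -> None:
    """Write sites as BED6 (name = label, score 0)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.seqname}\t{s.start - 1}\t{s.end}\t{s.label}\t0\t{s.strand}\n")
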