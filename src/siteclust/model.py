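"""Core record types: a labeled genomic interval and a normalized collection of them.

All coordinates inside the package are 1-based, closed intervals: both
endpoints are occupied base pairs and ``width = end - start + 1``.  The BED
convention (0-based, half-open) is converted at the I/O boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

log = logging.getLogger(__name__)

#: Allowed strand symbols; "." means strand-unknown/unstranded.
STRANDS = ("+", "-", ".")


@dataclass(frozen=True, slots=True)
class GenomicSite:
    """One labeled, stranded genomic interval — the unit being clustered.

    Parameters
    ----------
    seqname
        Chromosome (or scaffold) identifier, compared verbatim: ``"chr7"``
        and ``"7"`` are different sequences.
    start, end
        1-based inclusive endpoints in bp; ``end >= start >= 1``.
    strand
        ``"+"``, ``"-"`` or ``"."`` (unknown).
    label
        Site category name (e.g. a transcription-factor name); the clustering
        grammar is expressed over these labels.  Must be non-empty.
    source
        Optional provenance tag, typically the input file the site came from.
    """

    seqname: str
    start: int
    end: int
    strand: str = "."
    label: str = ""
    source: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"site start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"site end ({self.end}) must be >= start ({self.start})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if not self.label:
            raise ValueError("site label must be non-empty")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def sort_key(self) -> tuple[str, int, int, str, str]:
        # Total order => deterministic downstream results.
        return (self.seqname, self.start, self.end, self.label, self.strand)


class SiteSet:
    """Normalized, position-sorted collection of :class:`GenomicSite`.

    Construction sorts by (seqname, start, end, label, strand), so the result
    of any downstream operation is independent of input record order.
    Duplicate identical sites are retained: each copy counts toward the
    clustering conditions.

    ``input_manifest`` records provenance as ``(source, format, label)``
    triples for collated file inputs; programmatically built sets may leave
    it empty.
    """

    __slots__ = ("_sites", "input_manifest")

    def __init__(
        self,
        sites: Iterable[GenomicSite],
        input_manifest: Sequence[tuple[str, str, str]] = (),
    ) -> None:
        self._sites: tuple[GenomicSite, ...] = tuple(
            sorted(sites, key=GenomicSite.sort_key)
        )
        self.input_manifest: tuple[tuple[str, str, str], ...] = tuple(input_manifest)
        self._warn_mixed_chr_styles()

    def _warn_mixed_chr_styles(self) -> None:
        # "chr7" and "7" never join; silent harmonization would be worse.
        names = {s.seqname for s in self._sites}
        with_chr = any(n.startswith("chr") for n in names)
        without = any(not n.startswith("chr") for n in names)
        if with_chr and without:
            log.warning(
                "input mixes 'chr'-prefixed and bare chromosome names; "
                "names are compared verbatim and will not be merged"
            )

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._sites)

    def __iter__(self) -> Iterator[GenomicSite]:
        return iter(self._sites)

    def __getitem__(self, i):
        return self._sites[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, SiteSet):
            return NotImplemented
        return self._sites == other._sites

    def __repr__(self) -> str:
        return f"SiteSet({len(self._sites)} sites, labels={sorted(self.labels)})"

    # -- views --------------------------------------------------------------

    @property
    def sites(self) -> tuple[GenomicSite, ...]:
        return self._sites

    @property
    def labels(self) -> set[str]:
        return {s.label for s in self._sites}

    @property
    def seqnames(self) -> list[str]:
        """Distinct seqnames in sorted order."""
        return sorted({s.seqname for s in self._sites})

    def filtered(
        self,
        seqnames: Iterable[str] | None = None,
        strand: str | None = None,
    ) -> "SiteSet":
        """Subset by seqname set and/or strand, preserving provenance."""
        seqset = set(seqnames) if seqnames is not None else None
        kept = [
            s
            for s in self._sites
            if (seqset is None or s.seqname in seqset)
            and (strand is None or s.strand == strand)
        ]
        return SiteSet(kept, self.input_manifest)
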