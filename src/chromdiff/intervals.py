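"""Genomic interval arithmetic and annotation-derived gene regions.

All coordinates are 0-based, half-open ``[start, end)``. BED-family files
are read and written natively in this convention; GFF3 is converted on
read (start − 1). Strand enters only through :func:`derive_region`, which
measures "first"/"last" from the transcriptional 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

from .errors import UsageError

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "RegionKind",
    "derive_region",
    "merge_intervals",
    "intersect_replicates",
    "annotate_peaks_to_genes",
    "overlaps",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise UsageError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise UsageError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene body with identifier and biotype.

    Exon structure is deliberately absent: every derived region is an
    interval of the body (or its upstream flank).
    """

    gene_id: str
    body: GenomicInterval
    biotype: str = "protein_coding"


class RegionKind(str, Enum):
    """Named gene sub-regions used for quantification and annotation."""

    first_1kb = "first_1kb"
    first_20pct = "first_20pct"
    last_20pct = "last_20pct"
    upstream_2kb = "upstream_2kb"
    genic = "genic"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share >= 1 bp (same chromosome)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def derive_region(
    gene: GeneModel,
    kind: RegionKind | str,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """Derive a strand-aware sub-region of a gene.

    ``first``/``last`` are measured from the 5' end: for a minus-strand
    gene the first 1 kb spans the *highest* kilobase of coordinates.
    Percent regions use ``floor(length * 0.2)`` bp. ``first_1kb`` is
    truncated to the body for genes shorter than 1 kb, and
    ``upstream_2kb`` is clipped at chromosome bounds. ``genic`` is the
    body plus its (clipped) 2-kb upstream flank.
    """
    kind = RegionKind(kind)
    body = gene.body
    minus = body.strand == "-"
    length = len(body)

    if kind is RegionKind.first_1kb:
        span = min(1000, length)
        if minus:
            return replace(body, start=body.end - span)
        return replace(body, end=body.start + span)
    if kind in (RegionKind.first_20pct, RegionKind.last_20pct):
        span = max(1, (length * 20) // 100)
        from_5prime = kind is RegionKind.first_20pct
        at_low_coord = from_5prime != minus
        if at_low_coord:
            return replace(body, end=body.start + span)
        return replace(body, start=body.end - span)
    if kind is RegionKind.upstream_2kb:
        if minus:
            hi = body.end + 2000
            if chrom_length is not None:
                hi = min(hi, chrom_length)
            return replace(body, start=body.end, end=max(hi, body.end + 1))
        lo = max(0, body.start - 2000)
        return replace(body, start=lo, end=max(body.start, lo + 1))
    if kind is RegionKind.genic:
        up = derive_region(gene, RegionKind.upstream_2kb, chrom_length)
        return replace(body, start=min(body.start, up.start), end=max(body.end, up.end))
    raise UsageError(f"unknown region kind {kind!r}")


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal sorted set of disjoint intervals covering the same bases.

    Strand is dropped (merged intervals are unstranded). Touching
    intervals (``a.end == b.start``) are coalesced: the result is the
    minimal cover.
    """
    items = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in items:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = replace(prev, end=iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def intersect_replicates(
    peaks_rep1: Iterable[GenomicInterval],
    peaks_rep2: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Replicate-concordant peaks: unions of cross-replicate overlaps.

    Every rep1/rep2 pair overlapping by >= 1 bp contributes the union of
    the two peaks; transitively overlapping unions are merged. Peaks
    without a cross-replicate partner are dropped. Symmetric in its
    arguments.
    """
    by_chrom1: dict[str, list[GenomicInterval]] = {}
    for iv in peaks_rep1:
        by_chrom1.setdefault(iv.chrom, []).append(iv)
    unions: list[GenomicInterval] = []
    for iv2 in peaks_rep2:
        for iv1 in by_chrom1.get(iv2.chrom, ()):  # fixtures are small; O(n*m) is fine
            if iv1.start < iv2.end and iv2.start < iv1.end:
                unions.append(
                    GenomicInterval(iv1.chrom, min(iv1.start, iv2.start), max(iv1.end, iv2.end))
                )
    return merge_intervals(unions)


def annotate_peaks_to_genes(
    peaks: Iterable[GenomicInterval],
    genes: Iterable[GeneModel],
    kind: RegionKind | str = RegionKind.first_1kb,
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, list[GenomicInterval]]:
    """Map each gene to the peaks overlapping its derived region.

    A peak overlapping two genes' regions annotates to both. Genes with
    no overlapping peak appear with an empty list. Biotype filtering is
    the caller's responsibility.
    """
    peaks = list(peaks)
    result: dict[str, list[GenomicInterval]] = {}
    for gene in genes:
        clen = chrom_lengths.get(gene.body.chrom) if chrom_lengths else None
        region = derive_region(gene, kind, clen)
        result[gene.gene_id] = [p for p in peaks if overlaps(p, region)]
    return result
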