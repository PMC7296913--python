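"""Readers and writers for the plain-text genomic formats the pipeline uses.

BED-family files keep their native 0-based half-open coordinates; GFF3
start coordinates are converted (−1) on read and (+1) on write so all
in-memory intervals share one convention.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyfaidx import Fasta

from .errors import DataError
from .intervals import GeneModel, GenomicInterval

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_gff3_genes",
    "write_gff3_genes",
    "write_bed12_genes",
    "read_peaks",
    "write_narrowpeak",
    "write_broadpeak",
    "write_bedgraph",
    "read_table",
    "write_table",
]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(path: str | os.PathLike, seqs: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED3/BED6; strand defaults to '.'."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise DataError(f"{path}:{ln}: BED line has fewer than 3 fields")
            strand = f[5] if len(f) >= 6 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(
    path: str | os.PathLike,
    intervals: Iterable[GenomicInterval],
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_gff3_genes(path: str | os.PathLike, feature: str = "gene") -> list[GeneModel]:
    """Read gene features from GFF3 (1-based → 0-based half-open)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != feature:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", attrs.get("gene_id", f"{f[0]}:{f[3]}"))
            biotype = attrs.get("biotype", "protein_coding")
            genes.append(
                GeneModel(gid, GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), f[6]), biotype)
            )
    return genes


def write_gff3_genes(path: str | os.PathLike, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            b = g.body
            fh.write(
                f"{b.chrom}\tchromdiff\tgene\t{b.start + 1}\t{b.end}\t.\t{b.strand}\t.\t"
                f"ID={g.gene_id};biotype={g.biotype}\n"
            )


def write_bed12_genes(path: str | os.PathLike, genes: Iterable[GeneModel]) -> None:
    """Single-block BED12 (one exon spanning the body)."""
    with open(path, "w") as fh:
        for g in genes:
            b = g.body
            fh.write(
                f"{b.chrom}\t{b.start}\t{b.end}\t{g.gene_id}\t0\t{b.strand}\t"
                f"{b.start}\t{b.end}\t0\t1\t{len(b)},\t0,\n"
            )


def read_peaks(path: str | os.PathLike) -> tuple[list[GenomicInterval], list[int | None]]:
    """Read broadPeak/narrowPeak.

    Returns ``(intervals, summits)`` where a summit is the absolute
    coordinate ``start + offset`` from narrowPeak column 10, or None for
    broadPeak rows / missing offsets (−1).
    """
    ivs: list[GenomicInterval] = []
    summits: list[int | None] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[5] if len(f) > 5 else ".")
            ivs.append(iv)
            if len(f) >= 10 and int(f[9]) >= 0:
                summits.append(iv.start + int(f[9]))
            else:
                summits.append(None)
    return ivs, summits


def _write_peaks(path, intervals, summit_offsets=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            base = (
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak{i}\t0\t.\t0\t-1\t-1"
            )
            if summit_offsets is not None:
                base += f"\t{summit_offsets[i]}"
            fh.write(base + "\n")


def write_broadpeak(path: str | os.PathLike, intervals: Iterable[GenomicInterval]) -> None:
    _write_peaks(path, list(intervals))


def write_narrowpeak(
    path: str | os.PathLike,
    intervals: Sequence[GenomicInterval],
    summits: Sequence[int],
) -> None:
    offsets = [s - iv.start for s, iv in zip(summits, intervals)]
    _write_peaks(path, intervals, offsets)


def write_bedgraph(path: str | os.PathLike, track) -> None:
    """Write a ScaledTrack as fixed-step bedGraph."""
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in track.values:
            vals = track.values[chrom]
            clen = track.chrom_lengths[chrom]
            for i, v in enumerate(vals):
                end = min((i + 1) * bs, clen)
                fh.write(f"{chrom}\t{i * bs}\t{end}\t{v:.6g}\n")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
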