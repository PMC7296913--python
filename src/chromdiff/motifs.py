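"""CTCTGYTY motif scanning, cluster detection, and REF6 co-enrichment.

The REF6 H3K27me3 demethylase binds the degenerate 8-mer CTCTGYTY
(Y = C or T). This module finds all genomic instances on both strands,
detects clusters (>= 4 motifs whose starts-to-end span fits in a 600-bp
window, overlapping clusters merged), partitions peaks and motifs by
mutual overlap, and quantifies how REF6 occupancy tracks H2Aub1 in 50-bp
windows stratified by the local motif count (motifs within 600 bp of the
bin centre).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, UsageError
from .coverage import ScaledTrack
from .intervals import GenomicInterval

__all__ = [
    "MotifHit",
    "MotifCluster",
    "MOTIF_LENGTH",
    "scan_motifs",
    "find_clusters",
    "stratify_peaks_by_motif",
    "stratify_motifs_by_mark",
    "window_table",
    "h2aub_ref6_regression",
    "motif_strata",
]

MOTIF_LENGTH = 8
_FWD = re.compile(r"(?=(CTCTG[CT]T[CT]))")
_REV = re.compile(r"(?=([AG]A[AG]CAGAG))")  # reverse complement of CTCTGYTY


@dataclass(frozen=True, order=True)
class MotifHit:
    chrom: str
    start: int  # 0-based start of the 8-mer on the forward strand
    strand: str


@dataclass(frozen=True)
class MotifCluster:
    interval: GenomicInterval
    n_motifs: int


def scan_motifs(seqs: Mapping[str, str] | str) -> list[MotifHit]:
    """All CTCTGYTY instances on both strands, sorted by coordinate.

    Overlapping matches are all reported; reverse-strand hits are given
    by their forward-strand start. N never matches.
    """
    if isinstance(seqs, str):
        seqs = {"seq": seqs}
    hits = []
    for chrom in seqs:
        s = seqs[chrom].upper()
        hits.extend(MotifHit(chrom, m.start(), "+") for m in _FWD.finditer(s))
        hits.extend(MotifHit(chrom, m.start(), "-") for m in _REV.finditer(s))
    return sorted(hits, key=lambda h: (h.chrom, h.start, h.strand))


def find_clusters(
    hits: Sequence[MotifHit],
    window: int = 600,
    min_motifs: int = 4,
) -> list[MotifCluster]:
    """Motif clusters: maximal runs of >= min_motifs hits within ``window`` bp.

    A run of sorted hits qualifies when the span from the first start to
    the last hit's end (start + 8) fits in the window. Overlapping
    cluster intervals are merged and their motif counts recomputed over
    the merged interval.
    """
    by_chrom: dict[str, list[int]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h.start)
    raw: list[GenomicInterval] = []
    for chrom, starts in by_chrom.items():
        starts = sorted(starts)
        n = len(starts)
        j = 0
        for i in range(n):
            if j < i:
                j = i
            while j + 1 < n and starts[j + 1] + MOTIF_LENGTH - starts[i] <= window:
                j += 1
            if j - i + 1 >= min_motifs:
                raw.append(GenomicInterval(chrom, starts[i], starts[j] + MOTIF_LENGTH))
    # merge overlapping cluster intervals, then recount motifs inside
    from .intervals import merge_intervals

    merged = merge_intervals(raw)
    out = []
    for iv in merged:
        starts = by_chrom[iv.chrom]
        n_in = sum(1 for s in starts if iv.start <= s < iv.end)
        out.append(MotifCluster(iv, n_in))
    return out


def _starts_by_chrom(hits: Sequence[MotifHit]) -> dict[str, np.ndarray]:
    d: dict[str, list[int]] = {}
    for h in hits:
        d.setdefault(h.chrom, []).append(h.start)
    return {c: np.sort(np.asarray(v)) for c, v in d.items()}


def stratify_peaks_by_motif(
    peaks: Sequence[GenomicInterval], hits: Sequence[MotifHit]
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Partition peaks by containing >= 1 motif start."""
    starts = _starts_by_chrom(hits)
    with_motif, without = [], []
    for p in peaks:
        s = starts.get(p.chrom)
        n = 0
        if s is not None:
            n = np.searchsorted(s, p.end, "left") - np.searchsorted(s, p.start, "left")
        (with_motif if n > 0 else without).append(p)
    return with_motif, without


def stratify_motifs_by_mark(
    hits: Sequence[MotifHit], mark_peaks: Sequence[GenomicInterval]
) -> tuple[list[MotifHit], list[MotifHit]]:
    """Partition motifs by their start lying inside a mark peak."""
    with_mark, without = [], []
    for h in hits:
        inside = any(
            p.chrom == h.chrom and p.start <= h.start < p.end for p in mark_peaks
        )
        (with_mark if inside else without).append(h)
    return with_mark, without


def window_table(
    h2aub: ScaledTrack,
    ref6: ScaledTrack,
    hits: Sequence[MotifHit],
    motif_window: int = 600,
) -> pd.DataFrame:
    """Genome-wide 50-bp window table: H2Aub1, REF6, local motif count.

    ``n_motifs_600`` counts motif starts within the ``motif_window``-bp
    interval centred on each bin's centre: [centre−300, centre+300).
    """
    if not h2aub.same_grid(ref6):
        raise UsageError("H2Aub1 and REF6 tracks are on different bin grids")
    starts = _starts_by_chrom(hits)
    half = motif_window // 2
    bs = h2aub.bin_size
    frames = []
    for chrom in sorted(h2aub.values):
        vals_h = h2aub.values[chrom]
        vals_r = ref6.values[chrom]
        bin_starts = np.arange(len(vals_h), dtype=np.int64) * bs
        centers = bin_starts + bs // 2
        s = starts.get(chrom)
        if s is None or len(s) == 0:
            nm = np.zeros(len(vals_h), dtype=int)
        else:
            nm = np.searchsorted(s, centers + half, "left") - np.searchsorted(
                s, centers - half, "left"
            )
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": bin_starts,
                    "end": np.minimum(bin_starts + bs, h2aub.chrom_lengths[chrom]),
                    "h2aub": vals_h,
                    "ref6": vals_r,
                    "n_motifs_600": nm,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def motif_strata(n_motifs: pd.Series) -> pd.Series:
    """Map motif counts onto the strata 0,1,2,3,4,'5+'."""
    return n_motifs.map(lambda n: "5+" if n >= 5 else str(int(n)))


def h2aub_ref6_regression(
    records: pd.DataFrame, stratum: str | int | None = None
) -> dict[str, float]:
    """OLS of log10(REF6) on log10(H2Aub1) within one motif-count stratum.

    ``stratum`` is one of 0..4, '5+', or None for all windows. Scaled
    counts are strictly positive by construction, so the logs are always
    defined. Returns slope, intercept, r2, p (two-sided, for the slope),
    and n.
    """
    df = records
    if stratum is not None:
        df = records[motif_strata(records["n_motifs_600"]) == str(stratum)]
    if len(df) < 3:
        raise DataError(f"stratum {stratum!r}: need >= 3 windows, have {len(df)}")
    x = np.log10(df["h2aub"].to_numpy())
    y = np.log10(df["ref6"].to_numpy())
    if np.ptp(x) < 1e-12:
        raise DataError("degenerate H2Aub1 variance in stratum")
    if np.ptp(y) < 1e-12:
        return {"slope": 0.0, "intercept": float(y[0]), "r2": 0.0, "p": 1.0, "n": len(df)}
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "n": int(len(df)),
    }
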