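"""Coverage-scaled fragment quantification.

The scaling unit throughout is the *coverage-scaled fragment count*:
``(fragments + 1) / (total base coverage in gigabases)``, where total
base coverage is the summed length of all fragments in the library.
Scaling by sequenced bases rather than fragment number makes libraries
with different fragment-length distributions comparable, and the +1
pseudocount keeps every value strictly positive (so log scales are
always defined).

Fragments are counted into every 50-bp bin (or gene region) they overlap
by at least one base — coverage-style counting, not midpoint assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DataError, UsageError
from .intervals import GeneModel, GenomicInterval, RegionKind, derive_region

__all__ = [
    "FragmentLibrary",
    "ScaledTrack",
    "scale_counts",
    "bin_track",
    "average_replicates",
    "region_counts",
    "differential_counts",
    "metagene_profile",
    "summit_profile",
]

GIGABASE = 1e9


@dataclass
class FragmentLibrary:
    """One replicate's fragment intervals, stored per chromosome.

    ``fragments`` maps chromosome → int array of shape (n, 2) with
    half-open [start, end) rows. ``strands`` optionally carries one of
    '+'/'-'/'.' per fragment (used only for 5'-shift counting in the
    differential-peak model).
    """

    library_id: str
    antibody: str
    genotype: str
    replicate: int
    fragments: dict[str, np.ndarray]
    strands: dict[str, np.ndarray] | None = None

    @property
    def total_base_coverage(self) -> int:
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self.fragments.values())
        )

    @property
    def n_fragments(self) -> int:
        return sum(len(arr) for arr in self.fragments.values())

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[GenomicInterval],
        library_id: str = "",
        antibody: str = "",
        genotype: str = "wt",
        replicate: int = 1,
    ) -> "FragmentLibrary":
        frags: dict[str, list[list[int]]] = {}
        strands: dict[str, list[str]] = {}
        for iv in intervals:
            frags.setdefault(iv.chrom, []).append([iv.start, iv.end])
            strands.setdefault(iv.chrom, []).append(iv.strand)
        return cls(
            library_id,
            antibody,
            genotype,
            replicate,
            {c: np.asarray(v, dtype=np.int64) for c, v in frags.items()},
            {c: np.asarray(v) for c, v in strands.items()},
        )


@dataclass
class ScaledTrack:
    """Per-bin coverage-scaled fragment counts over a fixed 50-bp grid.

    The grid tiles each chromosome from coordinate 0; the last bin may be
    partial. Values for a single library are strictly positive.
    """

    bin_size: int
    chrom_lengths: dict[str, int]
    values: dict[str, np.ndarray]

    def same_grid(self, other: "ScaledTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.chrom_lengths == other.chrom_lengths
        )

    def value_at(self, chrom: str, pos: int) -> float:
        """Track value of the bin containing ``pos`` (NaN outside)."""
        vals = self.values.get(chrom)
        if vals is None:
            return float("nan")
        i = pos // self.bin_size
        if pos < 0 or i >= len(vals):
            return float("nan")
        return float(vals[i])


def scale_counts(raw_count, total_base_coverage: float):
    """Coverage-scale raw fragment counts: (raw + 1) / (coverage / 1e9)."""
    if total_base_coverage <= 0:
        raise DataError("total base coverage must be > 0 for scaling")
    raw = np.asarray(raw_count, dtype=float)
    if np.any(raw < 0):
        raise UsageError("raw counts must be non-negative")
    out = (raw + 1.0) / (total_base_coverage / GIGABASE)
    return float(out) if np.isscalar(raw_count) else out


def _raw_bin_counts(frags: np.ndarray, n_bins: int, bin_size: int) -> np.ndarray:
    """Number of fragments overlapping each bin by >= 1 bp.

    Difference-array accumulation: a fragment [s, e) overlaps bins
    s//bs .. (e-1)//bs inclusive.
    """
    counts = np.zeros(n_bins + 1, dtype=np.int64)
    if len(frags):
        first = frags[:, 0] // bin_size
        last = (frags[:, 1] - 1) // bin_size
        first = np.clip(first, 0, n_bins - 1)
        last = np.clip(last, 0, n_bins - 1)
        np.add.at(counts, first, 1)
        np.add.at(counts, last + 1, -1)
    return np.cumsum(counts)[:n_bins]


def bin_track(
    lib: FragmentLibrary,
    chrom_lengths: Mapping[str, int],
    bin_size: int = 50,
) -> ScaledTrack:
    """Genome-wide scaled track at ``bin_size`` resolution."""
    if bin_size < 1:
        raise UsageError("bin_size must be >= 1")
    tbc = lib.total_base_coverage
    values = {}
    for chrom, clen in chrom_lengths.items():
        n_bins = -(-clen // bin_size)
        frags = lib.fragments.get(chrom, np.empty((0, 2), dtype=np.int64))
        values[chrom] = scale_counts(_raw_bin_counts(frags, n_bins, bin_size), tbc)
    return ScaledTrack(bin_size, dict(chrom_lengths), values)


def average_replicates(tracks: Sequence[ScaledTrack]) -> ScaledTrack:
    """Element-wise mean of replicate tracks (after scaling)."""
    if not tracks:
        raise UsageError("need at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        if not first.same_grid(t):
            raise UsageError("replicate tracks are on different bin grids")
    values = {
        chrom: np.mean([t.values[chrom] for t in tracks], axis=0)
        for chrom in first.values
    }
    return ScaledTrack(first.bin_size, dict(first.chrom_lengths), values)


def _count_overlapping(starts: np.ndarray, ends: np.ndarray, region: GenomicInterval) -> int:
    # sorted starts/ends; fragment overlaps iff start < region.end and end > region.start
    n = len(starts)
    start_after = n - np.searchsorted(starts, region.end - 1, side="right")
    end_before = np.searchsorted(ends, region.start, side="right")
    return int(n - start_after - end_before)


def region_counts(
    lib: FragmentLibrary,
    genes: Sequence[GeneModel],
    kind: RegionKind | str = RegionKind.first_1kb,
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, float]:
    """Scaled fragment count per gene region (first 1 kb / 20% ends / ...)."""
    tbc = lib.total_base_coverage
    sorted_starts = {}
    sorted_ends = {}
    for chrom, arr in lib.fragments.items():
        sorted_starts[chrom] = np.sort(arr[:, 0])
        sorted_ends[chrom] = np.sort(arr[:, 1])
    out = {}
    for gene in genes:
        clen = chrom_lengths.get(gene.body.chrom) if chrom_lengths else None
        region = derive_region(gene, kind, clen)
        starts = sorted_starts.get(region.chrom)
        raw = 0 if starts is None else _count_overlapping(starts, sorted_ends[region.chrom], region)
        out[gene.gene_id] = scale_counts(raw, tbc)
    return out


def average_region_counts(counts: Sequence[Mapping[str, float]]) -> dict[str, float]:
    """Mean of per-gene scaled counts across replicates."""
    if not counts:
        raise UsageError("need at least one replicate")
    keys = set(counts[0])
    for c in counts[1:]:
        if set(c) != keys:
            raise UsageError("replicate gene universes differ")
    return {g: float(np.mean([c[g] for c in counts])) for g in keys}


def differential_counts(
    mutant: Mapping[str, float], wt: Mapping[str, float]
) -> dict[str, float]:
    """Per-gene mutant − wild-type scaled count (replicate-averaged inputs)."""
    missing = set(mutant) ^ set(wt)
    if missing:
        raise UsageError(f"gene universes differ, e.g. {sorted(missing)[:3]}")
    return {g: mutant[g] - wt[g] for g in mutant}


def _gene_profile(
    track: ScaledTrack, gene: GeneModel, flank: int, body_bins: int
) -> np.ndarray:
    """One gene's profile: flank bins, rescaled body, flank bins (5'→3')."""
    bs = track.bin_size
    body = gene.body
    vals = track.values[body.chrom]
    n_flank = flank // bs

    def at(pos_arr):
        idx = np.floor_divide(pos_arr, bs)
        ok = (pos_arr >= 0) & (idx < len(vals))
        out = np.full(len(pos_arr), np.nan)
        out[ok] = vals[idx[ok].astype(int)]
        return out

    # body values at native bins, then linear resampling to body_bins points
    first_bin = body.start // bs
    last_bin = (body.end - 1) // bs
    native = vals[first_bin : last_bin + 1]
    if len(native) == 1:
        body_vals = np.full(body_bins, native[0])
    else:
        xp = np.linspace(0.0, 1.0, len(native))
        body_vals = np.interp(np.linspace(0.0, 1.0, body_bins), xp, native)

    up_pos = body.start - flank + bs * np.arange(n_flank) + bs // 2
    down_pos = body.end + bs * np.arange(n_flank) + bs // 2
    upstream, downstream = at(up_pos), at(down_pos)
    prof = np.concatenate([upstream, body_vals, downstream])
    if body.strand == "-":
        prof = prof[::-1]
    return prof


def metagene_profile(
    track: ScaledTrack,
    genes: Sequence[GeneModel],
    flank: int = 2000,
    body_bins: int = 100,
) -> np.ndarray:
    """Median profile across genes, bodies rescaled to ``body_bins``.

    Profiles read 5'→3' regardless of strand; flanks stay at native
    bin resolution. Positions falling off a chromosome are ignored in
    the median. Returns an array of length
    ``flank//bin_size + body_bins + flank//bin_size``.
    """
    if not genes:
        raise UsageError("need at least one gene")
    if flank < 0 or body_bins < 1:
        raise UsageError("flank must be >= 0 and body_bins >= 1")
    mat = np.vstack([_gene_profile(track, g, flank, body_bins) for g in genes])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return np.nanmedian(mat, axis=0)


def summit_profile(
    track: ScaledTrack,
    summits: Sequence[tuple[str, int]],
    half_window: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Median track value at signed offsets around peak summits.

    Returns ``(offsets, medians)`` with offsets stepping by the track's
    bin size over [−half_window, +half_window].
    """
    bs = track.bin_size
    if half_window % bs:
        raise UsageError("half_window must be a multiple of the bin size")
    offsets = np.arange(-half_window, half_window + 1, bs)
    if not summits:
        warnings.warn("empty summit list: returning empty profile")
        return offsets, np.full(len(offsets), np.nan)
    rows = np.vstack(
        [[track.value_at(chrom, pos + o) for o in offsets] for chrom, pos in summits]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return offsets, np.nanmedian(rows, axis=0)
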