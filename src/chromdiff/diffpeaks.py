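"""M-A differential enrichment between two ChIP samples.

The model follows the classic M-A normalization scheme for ChIP-seq:
for each peak, fragments from both samples are counted in a 1000-bp
window centred on the peak, M = log2 ratio and A = mean log2 intensity
are computed with a 0.5 pseudocount, a robust line M = a + b·A is fitted
on peaks *common* to both samples (assumed globally unchanged), and the
fitted trend is subtracted to give M_norm. Significance comes from an
exact two-sided binomial test on the rescaled counts under an equal-split
null. Differential peaks are then required to be replicate-concordant
(>= 1 bp overlap, same direction) and merged, and target genes are
defined by overlap of surviving "up" peaks with the first 1 kb of the
gene body, minus genes also hit by a "down" peak.

Single-end fragments enter the window counts through their shifted 5'
position (shift = half the estimated fragment length).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import DataError, UsageError
from .coverage import FragmentLibrary
from .intervals import (
    GeneModel,
    GenomicInterval,
    RegionKind,
    annotate_peaks_to_genes,
    intersect_replicates,
    merge_intervals,
)

__all__ = [
    "PeakCount",
    "DifferentialPeak",
    "compute_MA",
    "shifted_positions",
    "build_peak_counts",
    "fit_normalization",
    "normalize_and_test",
    "concordant_differential_peaks",
    "define_ubp_targets",
]

PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class PeakCount:
    """Window fragment counts for one peak region in both samples."""

    interval: GenomicInterval
    count_a: int
    count_b: int
    origin: str  # {common, unique_a, unique_b}


@dataclass(frozen=True)
class DifferentialPeak:
    interval: GenomicInterval
    M: float
    A: float
    M_norm: float
    p_value: float
    direction: str  # {up, down}
    significant: bool


def compute_MA(count_a: float, count_b: float) -> tuple[float, float]:
    """M = log2((a+½)/(b+½)); A = ½·log2((a+½)(b+½))."""
    if count_a < 0 or count_b < 0:
        raise UsageError("counts must be non-negative")
    a = count_a + PSEUDOCOUNT
    b = count_b + PSEUDOCOUNT
    return float(np.log2(a / b)), float(0.5 * np.log2(a * b))


def shifted_positions(lib: FragmentLibrary, shift: int | None = None) -> dict[str, np.ndarray]:
    """Sorted per-chromosome representative positions of fragments.

    Each fragment is reduced to its 5' end moved ``shift`` bp toward the
    fragment centre ('+': start+shift, '−': end−1−shift). With the
    default shift of half the fragment length both strands land on the
    midpoint, which is also used for unstranded fragments.
    """
    out = {}
    for chrom, arr in lib.fragments.items():
        if len(arr) == 0:
            out[chrom] = np.empty(0, dtype=np.int64)
            continue
        lengths = arr[:, 1] - arr[:, 0]
        sh = (lengths // 2) if shift is None else np.full(len(arr), shift)
        if lib.strands is not None and chrom in lib.strands:
            minus = lib.strands[chrom] == "-"
        else:
            minus = np.zeros(len(arr), dtype=bool)
        pos = np.where(minus, arr[:, 1] - 1 - sh, arr[:, 0] + sh)
        out[chrom] = np.sort(pos)
    return out


def _window_count(positions: Mapping[str, np.ndarray], iv: GenomicInterval, window: int) -> int:
    pos = positions.get(iv.chrom)
    if pos is None:
        return 0
    mid = (iv.start + iv.end) // 2
    lo, hi = mid - window // 2, mid + window // 2
    return int(np.searchsorted(pos, hi, side="left") - np.searchsorted(pos, lo, side="left"))


def build_peak_counts(
    peaks_a: Sequence[GenomicInterval],
    peaks_b: Sequence[GenomicInterval],
    lib_a: FragmentLibrary,
    lib_b: FragmentLibrary,
    window: int = 1000,
    shift_a: int | None = None,
    shift_b: int | None = None,
) -> list[PeakCount]:
    """Count fragments from both samples in a window at every peak.

    Every peak of either sample becomes its own test record (peaks are
    *not* merged across samples, so a short gained region nested in a
    broad unchanged peak keeps its own window). A peak is ``common``
    when it overlaps a peak of the other sample by >= 1 bp, otherwise
    ``unique_a``/``unique_b``.
    """
    pos_a = shifted_positions(lib_a, shift_a)
    pos_b = shifted_positions(lib_b, shift_b)

    def hits_any(iv: GenomicInterval, peaks: Sequence[GenomicInterval]) -> bool:
        return any(p.chrom == iv.chrom and p.start < iv.end and iv.start < p.end for p in peaks)

    out = []
    for iv in peaks_a:
        origin = "common" if hits_any(iv, peaks_b) else "unique_a"
        out.append(
            PeakCount(iv, _window_count(pos_a, iv, window), _window_count(pos_b, iv, window), origin)
        )
    for iv in peaks_b:
        origin = "common" if hits_any(iv, peaks_a) else "unique_b"
        out.append(
            PeakCount(iv, _window_count(pos_a, iv, window), _window_count(pos_b, iv, window), origin)
        )
    return out


def _robust_line(A: np.ndarray, M: np.ndarray) -> tuple[float, float]:
    """Huber IRLS fit of M on A; falls back to OLS when degenerate."""
    if np.ptp(M) < 1e-12:  # constant M: line is flat at that level
        return float(M[0]) if len(M) else 0.0, 0.0
    X = sm.add_constant(A)
    try:
        res = sm.RLM(M, X, M=sm.robust.norms.HuberT()).fit(maxiter=50, tol=1e-8)
        params = res.params
    except Exception:
        params = np.polyfit(A, M, 1)[::-1]
    return float(params[0]), float(params[1])


def fit_normalization(
    common_peaks: Sequence[PeakCount],
    n_simulations: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Fit the normalization line M = intercept + slope·A on common peaks.

    The fit is a Huber-weighted robust regression, stabilized by
    ``n_simulations`` bootstrap resamples of the common peaks (reported
    coefficients are the coordinate-wise medians). Set
    ``n_simulations <= 1`` for a single direct fit.
    """
    MA = np.array([compute_MA(c.count_a, c.count_b) for c in common_peaks], dtype=float)
    if len(MA) < 2 or len(np.unique(MA[:, 1])) < 2:
        raise DataError("need >= 2 common peaks with distinct A to fit normalization")
    M, A = MA[:, 0], MA[:, 1]
    if n_simulations <= 1:
        return _robust_line(A, M)
    rng = np.random.default_rng(seed)
    coefs = []
    for _ in range(n_simulations):
        idx = rng.integers(0, len(M), len(M))
        if len(np.unique(A[idx])) < 2:
            continue
        coefs.append(_robust_line(A[idx], M[idx]))
    if not coefs:
        return _robust_line(A, M)
    arr = np.asarray(coefs)
    return float(np.median(arr[:, 0])), float(np.median(arr[:, 1]))


def normalize_and_test(
    peaks: Sequence[PeakCount],
    fit: tuple[float, float],
    p_cutoff: float = 0.05,
    m_cutoff: float = 0.0,
) -> list[DifferentialPeak]:
    """Rescale M by the fitted trend and test each peak.

    M_norm = M − (intercept + slope·A). Rescaled counts (a', b') are
    recovered by solving (M_norm, A) back to count space, and the
    p-value is the exact two-sided binomial probability of a split at
    least as extreme as (round(a'), round(b')) under p = 0.5. A peak is
    significant when p < p_cutoff and |M_norm| > m_cutoff.
    """
    intercept, slope = fit
    out = []
    for pk in peaks:
        M, A = compute_MA(pk.count_a, pk.count_b)
        m_norm = M - (intercept + slope * A)
        a_prime = max(2.0 ** (A + m_norm / 2.0) - PSEUDOCOUNT, 0.0)
        b_prime = max(2.0 ** (A - m_norm / 2.0) - PSEUDOCOUNT, 0.0)
        ka, kb = round(a_prime), round(b_prime)
        n = ka + kb
        p = 1.0 if n == 0 else float(stats.binomtest(ka, n, 0.5).pvalue)
        direction = "up" if m_norm > m_cutoff else "down"
        sig = (p < p_cutoff) and (abs(m_norm) > m_cutoff)
        out.append(DifferentialPeak(pk.interval, M, A, m_norm, p, direction, sig))
    return out


def concordant_differential_peaks(
    rep1: Iterable[DifferentialPeak],
    rep2: Iterable[DifferentialPeak],
    significant_only: bool = True,
) -> list[tuple[GenomicInterval, str]]:
    """Keep peaks found in both replicate comparisons with the same direction.

    Overlap requires >= 1 bp; surviving peaks are merged (union) within
    each direction and returned with their direction label.
    """
    out: list[tuple[GenomicInterval, str]] = []
    for direction in ("up", "down"):
        sel1 = [p.interval for p in rep1 if p.direction == direction and (p.significant or not significant_only)]
        sel2 = [p.interval for p in rep2 if p.direction == direction and (p.significant or not significant_only)]
        out.extend((iv, direction) for iv in intersect_replicates(sel1, sel2))
    return out


def define_ubp_targets(
    up_peaks: Sequence[GenomicInterval],
    down_peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
) -> set[str]:
    """Target genes: gain of the mark in the first 1 kb, no loss there.

    Targets = protein-coding genes whose first 1 kb overlaps at least
    one replicate-concordant "up" peak, minus genes whose first 1 kb
    also overlaps a "down" peak.
    """
    coding = [g for g in genes if g.biotype == "protein_coding"]
    up_map = annotate_peaks_to_genes(up_peaks, coding, RegionKind.first_1kb)
    down_map = annotate_peaks_to_genes(down_peaks, coding, RegionKind.first_1kb)
    gained = {g for g, peaks in up_map.items() if peaks}
    lost = {g for g, peaks in down_map.items() if peaks}
    return gained - lost
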