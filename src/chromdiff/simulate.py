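"""Synthetic miniature study with planted ground truth.

Generates everything the downstream pipeline consumes — genome sequence
with implanted CTCTGYTY motifs and motif clusters, non-overlapping gene
models, per-replicate fragment libraries for H2Aub1 / H3K27me3 / REF6 /
H3 in wild type and mutant, "called" peak files with jittered
boundaries, a differential-expression table, and gene responsiveness
scores — together with the ground truth of every planted effect.

Planted structure:

* a subset of genes carries H2Aub1 and/or H3K27me3 (fragment rate over
  the gene body elevated ``enrichment_fold``-fold over background);
* ``n_targets`` protein-coding genes are deubiquitinase targets: in the
  mutant their first 1 kb gains H2Aub1 (rate × ``enrichment_fold``) and
  loses H3K27me3 (rate × ``k27_loss_factor``), they are transcriptionally
  upregulated (planted log2FC), and they carry an emitted mutant H2Aub1
  peak over the first 1 kb;
* per-bin REF6 fragment rates follow a power law in the realized,
  replicate-averaged H2Aub1 coverage of the same genotype with log-log
  slope ``ref6_slope`` — REF6 occupancy tracks the H2Aub1 landscape as
  it exists, which is exactly what the windowed log-log regression
  downstream estimates;
* responsiveness scores are shifted upward for H2Aub1-marked genes.

Fragment placement is a homogeneous Poisson process per constant-rate
segment; mark fragments have fixed length ``fragment_length``, REF6
fragments span exactly one 50-bp bin so the per-bin rate law is planted
without smearing. Identical config + seed gives byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import io as cio
from .coverage import FragmentLibrary, ScaledTrack, average_replicates, bin_track
from .errors import ConfigError
from .intervals import GeneModel, GenomicInterval, RegionKind, derive_region
from .motifs import MOTIF_LENGTH, MotifHit, find_clusters, scan_motifs

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "FixtureBundle",
    "generate_study",
    "generate_motif_sequence",
    "write_bundle",
    "load_bundle",
]

_BASES = np.array(list("ACGT"))
_MARGIN = 3000  # bp kept gene-free at chromosome ends


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data generator."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_250_000
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (1000, 4000)
    frac_h2aub: float = 0.20  # H2Aub1 only
    frac_k27: float = 0.20  # H3K27me3 only
    frac_both: float = 0.15
    n_targets: int = 20
    enrichment_fold: float = 8.0
    enrichment_log2_sd: float = 1.0  # per-gene spread of marked-gene folds
    background_rate: float = 0.02  # fragment starts per bp per library
    fragment_length: int = 200
    n_replicates: int = 2
    ref6_slope: float = 0.4
    ref6_depth: float = 5.0  # median REF6 fragments per 50-bp bin
    motif_density: float = 0.3  # implanted motifs per kb
    n_clusters: int = 6
    responsiveness_shift: int = 3
    k27_loss_factor: float = 0.25
    target_log2fc: float = 3.0
    lfc_noise_sd: float = 0.2
    expr_h2aub_log2_effect: float = 1.0
    expr_k27_log2_effect: float = 1.5
    peak_jitter: int = 30
    bin_size: int = 50

    def validate(self) -> None:
        if self.frac_h2aub + self.frac_k27 + self.frac_both > 1 + 1e-9:
            raise ConfigError("frac_h2aub + frac_k27 + frac_both must be <= 1")
        if self.n_targets > self.n_genes:
            raise ConfigError("n_targets must be <= n_genes")
        for name in ("background_rate", "enrichment_fold", "ref6_depth"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ConfigError("gene_length_range must satisfy 0 < lo <= hi")
        if self.n_replicates < 1 or self.n_chroms < 1 or self.n_genes < 1:
            raise ConfigError("n_replicates, n_chroms, n_genes must be >= 1")
        per_chrom = -(-self.n_genes // self.n_chroms)
        needed = per_chrom * (hi + 1) + 2 * _MARGIN
        if needed > self.chrom_length:
            raise ConfigError(
                "genes do not fit: need >= "
                f"{needed} bp per chromosome, have {self.chrom_length}"
            )


@dataclass
class GroundTruth:
    """Everything that was planted, for recovery checks downstream."""

    target_genes: set[str]
    mark_assignment: dict[str, str]  # gene -> category
    motif_positions: list[tuple[str, int, str]]  # (chrom, start, strand)
    cluster_positions: list[tuple[str, int, int]]
    planted_ref6_slope: float
    planted_de: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(
            {
                "target_genes": sorted(self.target_genes),
                "mark_assignment": dict(sorted(self.mark_assignment.items())),
                "motif_positions": sorted(self.motif_positions),
                "cluster_positions": sorted(self.cluster_positions),
                "planted_ref6_slope": self.planted_ref6_slope,
                "planted_de": dict(sorted(self.planted_de.items())),
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            set(d["target_genes"]),
            d["mark_assignment"],
            [tuple(t) for t in d["motif_positions"]],
            [tuple(t) for t in d["cluster_positions"]],
            d["planted_ref6_slope"],
            d["planted_de"],
        )


@dataclass
class FixtureBundle:
    """In-memory study fixture: inputs for every pipeline stage."""

    config: SimulationConfig
    chrom_lengths: dict[str, int]
    genome: dict[str, str]
    genes: list[GeneModel]
    libraries: dict[str, FragmentLibrary]  # key: f"{antibody}_{genotype}_rep{r}"
    peaks: dict[str, list[GenomicInterval]]  # same keys (H3 has no peaks)
    h2aub_summits: dict[str, list[tuple[str, int]]]  # genotype -> summit list
    de_table: pd.DataFrame
    responsiveness: pd.DataFrame


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, stream)))


def generate_motif_sequence(
    length: int,
    motif_density: float,
    n_clusters: int,
    rng: np.random.Generator,
    cluster_window: int = 600,
    cluster_size: int = 4,
) -> tuple[str, list[MotifHit]]:
    """Random sequence with implanted CTCTGYTY instances and clusters.

    Returns the sequence and *all* motif hits found by rescanning it —
    including chance background matches — so recorded positions always
    equal a naive scan of the returned sequence.
    """
    n_single = int(round(motif_density * length / 1000))
    needed = n_single + n_clusters * cluster_size
    if needed * MOTIF_LENGTH * 2 > length:
        raise ConfigError(
            f"cannot place {needed} motifs of {MOTIF_LENGTH} bp in {length} bp"
        )
    seq = _BASES[rng.integers(0, 4, length)]
    occupied = np.zeros(length, dtype=bool)

    def implant(pos: int) -> None:
        y1, y2 = _BASES[[1, 3]][rng.integers(0, 2, 2)]  # C or T
        motif = f"CTCTG{y1}T{y2}"
        if rng.integers(0, 2):  # place on the minus strand
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            motif = "".join(comp[b] for b in reversed(motif))
        seq[pos : pos + MOTIF_LENGTH] = list(motif)
        occupied[pos : pos + MOTIF_LENGTH] = True

    def free(pos: int) -> bool:
        return (
            0 <= pos
            and pos + MOTIF_LENGTH <= length
            and not occupied[pos : pos + MOTIF_LENGTH].any()
        )

    # clusters first: cluster_size motifs whose span fits in cluster_window
    span = cluster_window - MOTIF_LENGTH
    for _ in range(n_clusters):
        for _attempt in range(200):
            anchor = int(rng.integers(_MARGIN, max(length - cluster_window - _MARGIN, _MARGIN + 1)))
            offsets = np.sort(rng.choice(span // MOTIF_LENGTH, cluster_size, replace=False))
            positions = [anchor + int(o) * MOTIF_LENGTH for o in offsets]
            if all(free(p) for p in positions):
                for p in positions:
                    implant(p)
                break
        else:
            raise ConfigError("could not place a motif cluster (sequence too dense)")
    for _ in range(n_single):
        for _attempt in range(200):
            pos = int(rng.integers(0, length - MOTIF_LENGTH + 1))
            if free(pos):
                implant(pos)
                break
        else:
            raise ConfigError("could not place a motif (sequence too dense)")

    sequence = "".join(seq)
    return sequence, scan_motifs({"scan": sequence})


def _place_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    genes = []
    gid = 0
    lo, hi = cfg.gene_length_range
    for chrom, n_c in zip(chroms, per_chrom):
        lengths = rng.integers(lo, hi + 1, n_c)
        usable = cfg.chrom_length - 2 * _MARGIN - int(lengths.sum()) - n_c
        if usable < 0:
            raise ConfigError("genes do not fit on chromosome")
        cuts = np.sort(rng.integers(0, usable + 1, n_c))
        cum = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        for i in range(n_c):
            start = _MARGIN + int(cuts[i]) + int(cum[i]) + i
            strand = "+" if rng.integers(0, 2) else "-"
            biotype = "protein_coding" if rng.random() > 0.05 else "other"
            gid += 1
            genes.append(
                GeneModel(
                    f"g{gid:04d}",
                    GenomicInterval(chrom, start, start + int(lengths[i]), strand),
                    biotype,
                )
            )
    return genes


def _rate_segments(
    chrom_len: int, base: float, regions: list[tuple[int, int, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant rate field: background plus multiplicative regions."""
    bounds = {0, chrom_len}
    for s, e, _ in regions:
        bounds.add(max(0, s))
        bounds.add(min(chrom_len, e))
    edges = np.array(sorted(bounds))
    rates = np.full(len(edges) - 1, base)
    for s, e, mult in regions:
        sel = (edges[:-1] >= s) & (edges[1:] <= e)
        rates[sel] *= mult
    return edges, rates


def _poisson_fragments(
    edges: np.ndarray,
    rates: np.ndarray,
    frag_len: int,
    chrom_len: int,
    rng: np.random.Generator,
) -> np.ndarray:
    starts_all = []
    for (s, e), rate in zip(zip(edges[:-1], edges[1:]), rates):
        n = rng.poisson(rate * (e - s))
        if n:
            starts_all.append(rng.integers(s, e, n))
    if not starts_all:
        return np.empty((0, 2), dtype=np.int64)
    starts = np.sort(np.concatenate(starts_all))
    starts = np.clip(starts, 0, chrom_len - frag_len)
    return np.stack([starts, starts + frag_len], axis=1).astype(np.int64)


def _make_library(
    cfg: SimulationConfig,
    key: str,
    antibody: str,
    genotype: str,
    replicate: int,
    region_mults: dict[str, list[tuple[int, int, float]]],
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
) -> FragmentLibrary:
    frags = {}
    strands = {}
    for chrom, clen in chrom_lengths.items():
        edges, rates = _rate_segments(clen, cfg.background_rate, region_mults.get(chrom, []))
        arr = _poisson_fragments(edges, rates, cfg.fragment_length, clen, rng)
        frags[chrom] = arr
        strands[chrom] = np.where(rng.integers(0, 2, len(arr)), "+", "-")
    return FragmentLibrary(key, antibody, genotype, replicate, frags, strands)


def _jitter_peaks(
    intervals: Sequence[GenomicInterval],
    jitter: int,
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    out = []
    for iv in intervals:
        ds, de = rng.integers(-jitter, jitter + 1, 2)
        s = max(0, iv.start + int(ds))
        e = min(chrom_lengths[iv.chrom], iv.end + int(de))
        if e <= s:
            e = s + 1
        out.append(GenomicInterval(iv.chrom, s, e))
    return sorted(out)


def _ref6_library(
    cfg: SimulationConfig,
    key: str,
    genotype: str,
    replicate: int,
    h2aub_track: ScaledTrack,
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
) -> FragmentLibrary:
    """REF6 fragments: per-bin Poisson with a power-law link to H2Aub1.

    lambda_bin + 1 = C * h2aub_bin ** ref6_slope, with C set so the
    genome-median bin has ``ref6_depth`` expected fragments. The +1 on
    the left cancels the +1 pseudocount of downstream coverage scaling,
    so the *measured* per-bin expectation follows the power law exactly.
    Fragments span exactly their bin, so downstream bin counts reproduce
    the planted rates without cross-bin smearing.
    """
    bs = h2aub_track.bin_size
    all_vals = np.concatenate([h2aub_track.values[c] for c in sorted(h2aub_track.values)])
    c_const = (cfg.ref6_depth + 1.0) / float(np.median(all_vals)) ** cfg.ref6_slope
    frags = {}
    strands = {}
    for chrom in sorted(chrom_lengths):
        vals = h2aub_track.values[chrom]
        lam = np.maximum(c_const * vals**cfg.ref6_slope - 1.0, 0.0)
        counts = rng.poisson(lam)
        starts = np.repeat(np.arange(len(vals), dtype=np.int64) * bs, counts)
        ends = np.minimum(starts + bs, chrom_lengths[chrom])
        frags[chrom] = np.stack([starts, ends], axis=1)
        strands[chrom] = np.full(len(starts), ".")
    return FragmentLibrary(key, "ref6", genotype, replicate, frags, strands)


def generate_study(cfg: SimulationConfig) -> tuple[FixtureBundle, GroundTruth]:
    """Generate the full synthetic study. Deterministic in config + seed."""
    cfg.validate()
    chrom_lengths = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)}

    # genome with implanted motifs
    genome = {}
    motif_hits: list[MotifHit] = []
    clusters_per_chrom = [cfg.n_clusters // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_clusters % cfg.n_chroms):
        clusters_per_chrom[i] += 1
    for i, chrom in enumerate(sorted(chrom_lengths)):
        seq, hits = generate_motif_sequence(
            cfg.chrom_length, cfg.motif_density, clusters_per_chrom[i], _rng(cfg, 10 + i)
        )
        genome[chrom] = seq
        motif_hits.extend(MotifHit(chrom, h.start, h.strand) for h in hits)
    clusters = find_clusters(motif_hits)

    genes = _place_genes(cfg, _rng(cfg, 1))

    # mark assignment and planted targets
    rng_marks = _rng(cfg, 2)
    order = list(rng_marks.permutation(len(genes)))
    n_both = int(round(cfg.frac_both * len(genes)))
    n_h = int(round(cfg.frac_h2aub * len(genes)))
    n_k = int(round(cfg.frac_k27 * len(genes)))
    mark_assignment = {}
    for rank, idx in enumerate(order):
        if rank < n_both:
            cat = "both"
        elif rank < n_both + n_h:
            cat = "h2aub_only"
        elif rank < n_both + n_h + n_k:
            cat = "k27_only"
        else:
            cat = "not_marked"
        mark_assignment[genes[idx].gene_id] = cat
    coding = [g for g in genes if g.biotype == "protein_coding"]
    target_idx = rng_marks.choice(len(coding), cfg.n_targets, replace=False)
    targets = {coding[i].gene_id for i in target_idx}

    h2aub_genes = [g for g in genes if mark_assignment[g.gene_id] in ("both", "h2aub_only")]
    k27_genes = [g for g in genes if mark_assignment[g.gene_id] in ("both", "k27_only")]
    first_kb = {g.gene_id: derive_region(g, RegionKind.first_1kb) for g in genes}

    # per-gene enrichment folds: ChIP enrichment varies continuously across
    # genes, which is also what identifies the M~A normalization trend
    def gene_folds(gs, rng):
        return {
            g.gene_id: float(
                cfg.enrichment_fold * 2.0 ** rng.normal(0.0, cfg.enrichment_log2_sd)
            )
            for g in gs
        }

    h2aub_folds = gene_folds(h2aub_genes, rng_marks)
    k27_folds = gene_folds(k27_genes, rng_marks)

    def body_regions(gs, folds):
        d: dict[str, list[tuple[int, int, float]]] = {}
        for g in gs:
            d.setdefault(g.body.chrom, []).append((g.body.start, g.body.end, folds[g.gene_id]))
        return d

    def add_first_kb(d, gene_ids, mult):
        for gid in sorted(gene_ids):
            r = first_kb[gid]
            d.setdefault(r.chrom, []).append((r.start, r.end, mult))
        return d

    libraries: dict[str, FragmentLibrary] = {}
    peaks: dict[str, list[GenomicInterval]] = {}
    stream = 100
    for genotype in ("wt", "mutant"):
        # H2Aub1: marked bodies enriched; mutant targets gain in first 1 kb
        regions = body_regions(h2aub_genes, h2aub_folds)
        if genotype == "mutant":
            add_first_kb(regions, targets, cfg.enrichment_fold)
        for rep in range(1, cfg.n_replicates + 1):
            key = f"h2aub_{genotype}_rep{rep}"
            libraries[key] = _make_library(
                cfg, key, "h2aub", genotype, rep, regions, chrom_lengths, _rng(cfg, stream)
            )
            stream += 1
            truth_peaks = [g.body for g in h2aub_genes]
            if genotype == "mutant":
                truth_peaks = truth_peaks + [first_kb[gid] for gid in sorted(targets)]
            peaks[key] = _jitter_peaks(truth_peaks, cfg.peak_jitter, chrom_lengths, _rng(cfg, stream))
            stream += 1
        # H3K27me3: marked bodies enriched; mutant targets lose in first 1 kb
        regions = body_regions(k27_genes, k27_folds)
        if genotype == "mutant":
            add_first_kb(regions, targets, cfg.k27_loss_factor)
        for rep in range(1, cfg.n_replicates + 1):
            key = f"k27_{genotype}_rep{rep}"
            libraries[key] = _make_library(
                cfg, key, "k27", genotype, rep, regions, chrom_lengths, _rng(cfg, stream)
            )
            stream += 1
            peaks[key] = _jitter_peaks(
                [g.body for g in k27_genes], cfg.peak_jitter, chrom_lengths, _rng(cfg, stream)
            )
            stream += 1
        # H3 control: flat background, one library per genotype
        key = f"h3_{genotype}_rep1"
        libraries[key] = _make_library(
            cfg, key, "h3", genotype, 1, {}, chrom_lengths, _rng(cfg, stream)
        )
        stream += 1

    # REF6 coupled to the realized replicate-averaged H2Aub1 landscape
    h2aub_summits: dict[str, list[tuple[str, int]]] = {}
    for genotype in ("wt", "mutant"):
        tracks = [
            bin_track(libraries[f"h2aub_{genotype}_rep{r}"], chrom_lengths, cfg.bin_size)
            for r in range(1, cfg.n_replicates + 1)
        ]
        avg = average_replicates(tracks)
        for rep in range(1, cfg.n_replicates + 1):
            key = f"ref6_{genotype}_rep{rep}"
            libraries[key] = _ref6_library(
                cfg, key, genotype, rep, avg, chrom_lengths, _rng(cfg, stream)
            )
            stream += 1
            peaks[key] = _jitter_peaks(
                [first_kb[g.gene_id] for g in h2aub_genes],
                cfg.peak_jitter,
                chrom_lengths,
                _rng(cfg, stream),
            )
            stream += 1
        # narrow-mode H2Aub1 summits (replicates pooled): first-1-kb centres
        h2aub_summits[genotype] = sorted(
            (r.chrom, (r.start + r.end) // 2)
            for r in (first_kb[g.gene_id] for g in h2aub_genes)
        )

    de_table, planted_de = _de_table(cfg, genes, mark_assignment, targets, _rng(cfg, 3))
    responsiveness = _responsiveness(cfg, genes, mark_assignment, _rng(cfg, 4))

    truth = GroundTruth(
        target_genes=targets,
        mark_assignment=mark_assignment,
        motif_positions=[(h.chrom, h.start, h.strand) for h in motif_hits],
        cluster_positions=[
            (c.interval.chrom, c.interval.start, c.interval.end) for c in clusters
        ],
        planted_ref6_slope=cfg.ref6_slope,
        planted_de=planted_de,
    )
    bundle = FixtureBundle(
        cfg, chrom_lengths, genome, genes, libraries, peaks, h2aub_summits,
        de_table, responsiveness,
    )
    return bundle, truth


def _de_table(cfg, genes, mark_assignment, targets, rng):
    """Planted differential expression with a z-test on replicate counts."""
    rows = []
    planted = {}
    n_reps = 3
    for g in genes:
        marked = mark_assignment[g.gene_id]
        base = float(
            np.exp(rng.normal(np.log(50), 1.0))
            * 2.0 ** (
                cfg.expr_h2aub_log2_effect * (marked in ("both", "h2aub_only"))
                - cfg.expr_k27_log2_effect * (marked in ("both", "k27_only"))
            )
        )
        lfc = cfg.target_log2fc if g.gene_id in targets else 0.0
        planted[g.gene_id] = lfc
        wt_counts = rng.poisson(base, n_reps)
        mut_counts = rng.poisson(base * 2.0**lfc, n_reps)
        lw, lm = np.log1p(wt_counts), np.log1p(mut_counts)
        se = float(np.sqrt(lw.var(ddof=1) / n_reps + lm.var(ddof=1) / n_reps))
        z = 0.0 if se == 0 else (lm.mean() - lw.mean()) / se
        from scipy import stats as sps

        p = float(2 * sps.norm.sf(abs(z)))
        detected = wt_counts.sum() + mut_counts.sum() > 0
        cpm_pass = bool((wt_counts > 1).sum() >= 2 or (mut_counts > 1).sum() >= 2)
        obs_lfc = lfc + float(rng.normal(0, cfg.lfc_noise_sd)) if detected else 0.0
        rows.append(
            {
                "gene_id": g.gene_id,
                "log2FC": obs_lfc,
                "p": p,
                "baseMean": base,
                "detected": detected,
                "cpm_pass": cpm_pass,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df[["gene_id", "log2FC", "p_adj", "baseMean", "detected", "cpm_pass"]], planted


def _responsiveness(cfg, genes, mark_assignment, rng):
    rows = []
    for g in genes:
        score = int(rng.poisson(2))
        if mark_assignment[g.gene_id] in ("both", "h2aub_only"):
            score += cfg.responsiveness_shift
        rows.append({"gene_id": g.gene_id, "score": score})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk fixture layout


def write_bundle(bundle: FixtureBundle, truth: GroundTruth, outdir: str | os.PathLike) -> None:
    """Write the whole fixture as plain-text files under ``outdir``."""
    outdir = str(outdir)
    os.makedirs(os.path.join(outdir, "fragments"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "peaks"), exist_ok=True)
    cio.write_fasta(os.path.join(outdir, "genome.fa"), bundle.genome)
    cio.write_gff3_genes(os.path.join(outdir, "genes.gff3"), bundle.genes)
    cio.write_bed12_genes(os.path.join(outdir, "genes.bed12"), bundle.genes)
    for key in sorted(bundle.libraries):
        lib = bundle.libraries[key]
        with open(os.path.join(outdir, "fragments", f"{key}.bed"), "w") as fh:
            for chrom in sorted(lib.fragments):
                arr = lib.fragments[chrom]
                strands = lib.strands[chrom] if lib.strands else ["."] * len(arr)
                for (s, e), st in zip(arr, strands):
                    fh.write(f"{chrom}\t{s}\t{e}\tfrag\t0\t{st}\n")
    for key in sorted(bundle.peaks):
        cio.write_broadpeak(os.path.join(outdir, "peaks", f"{key}.broadPeak"), bundle.peaks[key])
    for genotype, summits in sorted(bundle.h2aub_summits.items()):
        ivs = [GenomicInterval(c, max(0, p - 250), p + 250) for c, p in summits]
        cio.write_narrowpeak(
            os.path.join(outdir, "peaks", f"h2aub_{genotype}_narrow.narrowPeak"),
            ivs,
            [p for _, p in summits],
        )
    cio.write_table(os.path.join(outdir, "de_table.tsv"), bundle.de_table)
    cio.write_table(os.path.join(outdir, "responsiveness.tsv"), bundle.responsiveness)
    with open(os.path.join(outdir, "chrom_sizes.tsv"), "w") as fh:
        for chrom in sorted(bundle.chrom_lengths):
            fh.write(f"{chrom}\t{bundle.chrom_lengths[chrom]}\n")
    with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
        fh.write(truth.to_json())
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(asdict(bundle.config), fh, indent=1, sort_keys=True)


def load_bundle(indir: str | os.PathLike) -> FixtureBundle:
    """Load a fixture directory written by :func:`write_bundle`."""
    indir = str(indir)
    with open(os.path.join(indir, "config.json")) as fh:
        raw = json.load(fh)
    raw["gene_length_range"] = tuple(raw["gene_length_range"])
    cfg = SimulationConfig(**raw)
    chrom_lengths = {}
    with open(os.path.join(indir, "chrom_sizes.tsv")) as fh:
        for line in fh:
            c, l = line.split()
            chrom_lengths[c] = int(l)
    genome = cio.read_fasta(os.path.join(indir, "genome.fa"))
    genes = cio.read_gff3_genes(os.path.join(indir, "genes.gff3"))
    libraries = {}
    fragdir = os.path.join(indir, "fragments")
    for fn in sorted(os.listdir(fragdir)):
        key = fn[:-4]
        antibody, genotype, rep = key.rsplit("_", 2)
        libraries[key] = FragmentLibrary.from_intervals(
            cio.read_bed(os.path.join(fragdir, fn)),
            key,
            antibody,
            genotype,
            int(rep.replace("rep", "")),
        )
    peaks = {}
    summits: dict[str, list[tuple[str, int]]] = {}
    peakdir = os.path.join(indir, "peaks")
    for fn in sorted(os.listdir(peakdir)):
        path = os.path.join(peakdir, fn)
        if fn.endswith(".narrowPeak"):
            ivs, sm = cio.read_peaks(path)
            genotype = fn.replace("h2aub_", "").replace("_narrow.narrowPeak", "")
            summits[genotype] = [(iv.chrom, s) for iv, s in zip(ivs, sm) if s is not None]
        else:
            peaks[fn.rsplit(".", 1)[0]], _ = cio.read_peaks(path)
    de_table = cio.read_table(os.path.join(indir, "de_table.tsv"))
    responsiveness = cio.read_table(os.path.join(indir, "responsiveness.tsv"))
    return FixtureBundle(
        cfg, chrom_lengths, genome, genes, libraries, peaks, summits, de_table, responsiveness
    )


def bundle_checksum(outdir: str | os.PathLike) -> str:
    """SHA256 over every file in a fixture directory (sorted paths)."""
    h = hashlib.sha256()
    for root, _dirs, files in sorted(os.walk(str(outdir))):
        for fn in sorted(files):
            path = os.path.join(root, fn)
            h.update(os.path.relpath(path, str(outdir)).encode())
            with open(path, "rb") as fh:
                h.update(fh.read())
    return h.hexdigest()
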