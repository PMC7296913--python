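"""End-to-end orchestration of the integration analysis.

Stages run in dependency order on a study fixture (on disk or in
memory): scaled tracks → replicate-concordant mark peaks → gene
categorization → M-A differential H2Aub1 peaks → deubiquitinase-target
definition → H3K27me3 per-gene differentials and PRC1-dependency → motif
scan / clusters / windowed REF6 regression → statistics. All outputs are
plain text and a rerun on identical inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import io as cio
from .coverage import (
    average_region_counts,
    average_replicates,
    bin_track,
    differential_counts,
    metagene_profile,
    region_counts,
    summit_profile,
)
from .diffpeaks import (
    build_peak_counts,
    concordant_differential_peaks,
    define_ubp_targets,
    fit_normalization,
    normalize_and_test,
)
from .errors import ConfigError, DataError
from .intervals import GenomicInterval, RegionKind, intersect_replicates
from .marks import call_mark_presence, categorize, classify_prc1_dependency, category_fraction
from .motifs import find_clusters, h2aub_ref6_regression, motif_strata, scan_motifs, window_table
from .simulate import FixtureBundle, load_bundle
from .stats import (
    ancova_emm,
    chisq_updown,
    de_filter,
    hypergeometric_enrichment,
    mann_whitney,
    responsiveness_by_category,
)

logger = logging.getLogger("chromdiff")

__all__ = ["PipelineParams", "run_pipeline", "run_pipeline_dir"]


@dataclass
class PipelineParams:
    """All analysis parameters, surfaced with their standard defaults."""

    bin_size: int = 50
    manorm_window: int = 1000
    n_simulations: int = 100
    p_cutoff: float = 0.05
    m_cutoff: float = 0.0
    lfc_cutoff: float = 1.0
    bonferroni_m: int = 6
    motif_window: int = 600
    min_motifs: int = 4
    metagene_flank: int = 2000
    metagene_body_bins: int = 100
    summit_half_window: int = 1000
    seed: int = 0


def _iv_list(pairs):
    return [{"chrom": iv.chrom, "start": iv.start, "end": iv.end, "direction": d} for iv, d in pairs]


def run_pipeline(
    bundle: FixtureBundle,
    params: PipelineParams | None = None,
    outdir: str | os.PathLike | None = None,
) -> dict:
    """Run every stage on an in-memory fixture; return the summary dict.

    When ``outdir`` is given, per-stage tables and a machine-readable
    ``summary.json`` are written there.
    """
    params = params or PipelineParams()
    cl = bundle.chrom_lengths
    n_reps = bundle.config.n_replicates
    if n_reps < 2:
        raise ConfigError("replicate concordance requires >= 2 replicates")
    coding = [g for g in bundle.genes if g.biotype == "protein_coding"]
    summary: dict = {"params": asdict(params)}

    # --- stage 1: scaled tracks (per condition, replicate-averaged) ----
    logger.info("stage tracks: binning %d libraries", len(bundle.libraries))
    tracks = {}
    for antibody in ("h2aub", "k27", "ref6"):
        for genotype in ("wt", "mutant"):
            reps = [
                bin_track(bundle.libraries[f"{antibody}_{genotype}_rep{r}"], cl, params.bin_size)
                for r in range(1, n_reps + 1)
            ]
            tracks[f"{antibody}_{genotype}"] = average_replicates(reps)

    # --- stage 2: real peaks and gene categories (wild type) -----------
    real_peaks = {}
    for antibody in ("h2aub", "k27"):
        real_peaks[antibody] = intersect_replicates(
            bundle.peaks[f"{antibody}_wt_rep1"], bundle.peaks[f"{antibody}_wt_rep2"]
        )
    h2aub_pres = call_mark_presence(real_peaks["h2aub"], coding)
    k27_pres = call_mark_presence(real_peaks["k27"], coding)
    mark_table = categorize(h2aub_pres, k27_pres)
    cat_counts = mark_table["category"].value_counts().to_dict()
    summary["category_counts"] = {k: int(cat_counts.get(k, 0)) for k in
                                  ("not_marked", "h2aub_only", "both", "k27_only")}
    logger.info("stage categories: %s", summary["category_counts"])

    # --- stage 3: M-A differential H2Aub1 peaks and targets ------------
    per_rep = []
    for r in range(1, n_reps + 1):
        counts = build_peak_counts(
            bundle.peaks[f"h2aub_mutant_rep{r}"],
            bundle.peaks[f"h2aub_wt_rep{r}"],
            bundle.libraries[f"h2aub_mutant_rep{r}"],
            bundle.libraries[f"h2aub_wt_rep{r}"],
            window=params.manorm_window,
        )
        common = [c for c in counts if c.origin == "common"]
        fit = fit_normalization(common, params.n_simulations, seed=params.seed)
        per_rep.append(
            normalize_and_test(counts, fit, params.p_cutoff, params.m_cutoff)
        )
    concordant = concordant_differential_peaks(per_rep[0], per_rep[1])
    up = [iv for iv, d in concordant if d == "up"]
    down = [iv for iv, d in concordant if d == "down"]
    targets = define_ubp_targets(up, down, coding)
    mark_table["is_target"] = [g in targets for g in mark_table.index]
    summary["n_diff_peaks_up"] = len(up)
    summary["n_diff_peaks_down"] = len(down)
    summary["n_targets"] = len(targets)
    summary["target_frac_k27"] = (
        category_fraction(targets, mark_table, "k27") if targets else None
    )
    logger.info("stage targets: %d up, %d down peaks, %d targets", len(up), len(down), len(targets))

    # --- stage 4: per-gene H3K27me3 differential (mutant − wt) ---------
    k27_diff = {}
    for kind in (RegionKind.first_1kb, RegionKind.first_20pct, RegionKind.last_20pct):
        per_geno = {}
        for genotype in ("wt", "mutant"):
            reps = [
                region_counts(bundle.libraries[f"k27_{genotype}_rep{r}"], coding, kind, cl)
                for r in range(1, n_reps + 1)
            ]
            per_geno[genotype] = average_region_counts(reps)
        k27_diff[kind.value] = differential_counts(per_geno["mutant"], per_geno["wt"])
    diff1kb = k27_diff["first_1kb"]
    t_vals = [diff1kb[g] for g in sorted(targets)]
    nt_vals = [diff1kb[g] for g in sorted(set(diff1kb) - targets)]
    if t_vals and nt_vals:
        _, p_mw = mann_whitney(t_vals, nt_vals)
        summary["k27_diff_first1kb"] = {
            "median_targets": float(np.median(t_vals)),
            "median_non_targets": float(np.median(nt_vals)),
            "mw_p_bonferroni": min(1.0, p_mw * params.bonferroni_m),
        }

    # --- stage 5: PRC1 dependency from K27-loss differential peaks -----
    k27_per_rep = []
    for r in range(1, n_reps + 1):
        counts = build_peak_counts(
            bundle.peaks[f"k27_mutant_rep{r}"],
            bundle.peaks[f"k27_wt_rep{r}"],
            bundle.libraries[f"k27_mutant_rep{r}"],
            bundle.libraries[f"k27_wt_rep{r}"],
            window=params.manorm_window,
        )
        common = [c for c in counts if c.origin == "common"]
        fit = fit_normalization(common, params.n_simulations, seed=params.seed)
        k27_per_rep.append(normalize_and_test(counts, fit, params.p_cutoff, params.m_cutoff))
    k27_concordant = concordant_differential_peaks(k27_per_rep[0], k27_per_rep[1])
    k27_down = [iv for iv, d in k27_concordant if d == "down"]
    prc1 = classify_prc1_dependency(k27_pres, k27_down, coding)
    mark_table["prc1_class"] = [prc1[g] for g in mark_table.index]
    summary["prc1_class_counts"] = {
        k: int(v) for k, v in sorted(pd.Series(prc1).value_counts().items())
    }

    # --- stage 6: motifs, clusters, REF6 co-enrichment -----------------
    hits = scan_motifs(bundle.genome)
    clusters = find_clusters(hits, params.motif_window, params.min_motifs)
    summary["n_motifs"] = len(hits)
    summary["n_motif_clusters"] = len(clusters)
    wtab = window_table(tracks["h2aub_wt"], tracks["ref6_wt"], hits, params.motif_window)
    regression = {"all": h2aub_ref6_regression(wtab)}
    for stratum in ("0", "1", "2", "3", "4", "5+"):
        try:
            regression[stratum] = h2aub_ref6_regression(wtab, stratum)
        except DataError:
            regression[stratum] = None
    summary["h2aub_ref6_regression"] = regression
    offsets, prof = summit_profile(
        tracks["ref6_wt"], bundle.h2aub_summits["wt"], params.summit_half_window
    )
    summary["ref6_at_h2aub_summits"] = {
        "center": float(prof[len(prof) // 2]),
        "edge": float(np.nanmean([prof[0], prof[-1]])),
    }

    # --- stage 7: statistics -------------------------------------------
    de_up, de_down = de_filter(bundle.de_table, params.lfc_cutoff, params.p_cutoff)
    chi2, chi_p = chisq_updown(len(de_up), len(de_down)) if (de_up or de_down) else (0.0, 1.0)
    summary["de"] = {"n_up": len(de_up), "n_down": len(de_down), "chi2": chi2, "chi2_p": chi_p}
    universe = {g.gene_id for g in coding}
    if targets and de_up:
        enr = hypergeometric_enrichment(targets & universe, de_up & universe, universe)
        summary["target_upregulated_overlap"] = {
            "fold": enr.fold,
            "p": enr.p_value,
            "n_overlap": enr.n_overlap,
            "expected": enr.expected,
        }
    expr = dict(zip(bundle.de_table["gene_id"], bundle.de_table["baseMean"]))
    expr = {g: expr[g] for g in mark_table.index if g in expr}
    emms, contrasts = ancova_emm(
        expr,
        {g: bool(mark_table.loc[g, "h2aub"]) for g in expr},
        {g: bool(mark_table.loc[g, "k27"]) for g in expr},
        params.bonferroni_m,
    )
    summary["ancova_emm"] = {
        f"{e.factor}_{e.level}": round(e.emm, 6) for e in emms
    }
    scores = dict(zip(bundle.responsiveness["gene_id"], bundle.responsiveness["score"]))
    summary["responsiveness"] = responsiveness_by_category(scores, mark_table, params.bonferroni_m)

    # --- stage 8: metagene profiles per category -----------------------
    metagenes = {}
    for cat in ("not_marked", "h2aub_only", "both", "k27_only"):
        ids = set(mark_table.index[mark_table["category"] == cat])
        gs = [g for g in coding if g.gene_id in ids]
        if gs:
            prof = metagene_profile(
                tracks["h2aub_wt"], gs, params.metagene_flank, params.metagene_body_bins
            )
            metagenes[cat] = prof
            summary.setdefault("metagene_body_mean", {})[cat] = float(
                np.nanmean(prof[params.metagene_flank // params.bin_size : -params.metagene_flank // params.bin_size or None])
            )

    summary["target_genes"] = sorted(targets)

    if outdir is not None:
        _write_outputs(outdir, summary, mark_table, concordant, k27_diff, wtab, clusters, metagenes)
    return summary


def _write_outputs(outdir, summary, mark_table, concordant, k27_diff, wtab, clusters, metagenes):
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    mt = mark_table.reset_index()
    cio.write_table(os.path.join(outdir, "gene_marks.tsv"), mt)
    with open(os.path.join(outdir, "diff_peaks.bed"), "w") as fh:
        for iv, d in sorted(concordant, key=lambda t: (t[0].chrom, t[0].start)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{d}\t0\t.\n")
    kd = pd.DataFrame(k27_diff)
    kd.index.name = "gene_id"
    cio.write_table(os.path.join(outdir, "k27_differential.tsv"), kd.reset_index().sort_values("gene_id"))
    wtab.assign(stratum=motif_strata(wtab["n_motifs_600"])).to_csv(
        os.path.join(outdir, "window_table.tsv"), sep="\t", index=False, float_format="%.6g"
    )
    with open(os.path.join(outdir, "motif_clusters.bed"), "w") as fh:
        for c in clusters:
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\tcluster\t{c.n_motifs}\t.\n"
            )
    for cat, prof in sorted(metagenes.items()):
        pd.DataFrame({"position": range(len(prof)), "median": prof}).to_csv(
            os.path.join(outdir, f"metagene_{cat}.tsv"), sep="\t", index=False, float_format="%.6g"
        )
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(type(o))


def run_pipeline_dir(
    study_dir: str | os.PathLike,
    outdir: str | os.PathLike,
    params: PipelineParams | None = None,
) -> dict:
    """Load a fixture directory, validate inputs, run all stages."""
    study_dir = str(study_dir)
    for required in ("genome.fa", "genes.gff3", "de_table.tsv", "responsiveness.tsv"):
        if not os.path.exists(os.path.join(study_dir, required)):
            raise DataError(f"missing input file: {os.path.join(study_dir, required)}")
    bundle = load_bundle(study_dir)
    for antibody in ("h2aub", "k27", "ref6"):
        for genotype in ("wt", "mutant"):
            for r in range(1, bundle.config.n_replicates + 1):
                key = f"{antibody}_{genotype}_rep{r}"
                if key not in bundle.libraries:
                    raise DataError(f"missing replicate fragment library: {key}")
    return run_pipeline(bundle, params, outdir)
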