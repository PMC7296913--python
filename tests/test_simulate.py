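"""Synthetic study generator: validity, determinism, and planted effects."""

import numpy as np
import pytest

from chromdiff.errors import ConfigError
from chromdiff.intervals import RegionKind, derive_region
from chromdiff.motifs import find_clusters, scan_motifs
from chromdiff.simulate import (
    SimulationConfig,
    bundle_checksum,
    generate_motif_sequence,
    generate_study,
    write_bundle,
)
from conftest import SMALL_CONFIG


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides, fragment",
        [
            (dict(frac_h2aub=0.5, frac_k27=0.4, frac_both=0.3), "frac"),
            (dict(n_targets=500), "n_targets"),
            (dict(background_rate=0.0), "background_rate"),
            (dict(gene_length_range=(0, 100)), "gene_length_range"),
            (dict(chrom_length=10_000), "fit"),
        ],
    )
    def test_violations_named(self, overrides, fragment):
        cfg = SimulationConfig(**overrides)
        with pytest.raises(ConfigError, match=fragment):
            cfg.validate()


class TestMotifSequence:
    def test_recorded_hits_equal_naive_rescan(self):
        rng = np.random.default_rng(50)
        seq, hits = generate_motif_sequence(30_000, 0.5, 2, rng)
        rescanned = scan_motifs({"scan": seq})
        assert [(h.start, h.strand) for h in hits] == [
            (h.start, h.strand) for h in rescanned
        ]

    def test_requested_clusters_present(self):
        rng = np.random.default_rng(51)
        _, hits = generate_motif_sequence(40_000, 0.2, 3, rng)
        assert len(find_clusters(hits)) >= 3

    def test_zero_density_only_chance_matches(self):
        rng = np.random.default_rng(52)
        seq, hits = generate_motif_sequence(20_000, 0.0, 0, rng)
        assert [(h.start, h.strand) for h in hits] == [
            (h.start, h.strand) for h in scan_motifs({"scan": seq})
        ]

    def test_infeasible_density_rejected(self):
        rng = np.random.default_rng(53)
        with pytest.raises(ConfigError):
            generate_motif_sequence(500, 1000.0, 0, rng)


class TestStudyGeneration:
    def test_no_targets_config(self):
        cfg = SimulationConfig(**{**SMALL_CONFIG, "n_targets": 0})
        _, truth = generate_study(cfg)
        assert truth.target_genes == set()

    def test_determinism_byte_identical(self, tmp_path):
        cfg1 = SimulationConfig(**SMALL_CONFIG)
        cfg2 = SimulationConfig(**SMALL_CONFIG)
        b1, t1 = generate_study(cfg1)
        b2, t2 = generate_study(cfg2)
        write_bundle(b1, t1, tmp_path / "run1")
        write_bundle(b2, t2, tmp_path / "run2")
        assert bundle_checksum(tmp_path / "run1") == bundle_checksum(tmp_path / "run2")

    def test_genes_non_overlapping(self, small_study):
        bundle, _ = small_study
        by_chrom = {}
        for g in bundle.genes:
            by_chrom.setdefault(g.body.chrom, []).append(g.body)
        for ivs in by_chrom.values():
            ivs = sorted(ivs, key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start

    def test_ground_truth_motifs_match_genome_rescan(self, small_study):
        bundle, truth = small_study
        rescanned = [(h.chrom, h.start, h.strand) for h in scan_motifs(bundle.genome)]
        assert sorted(truth.motif_positions) == rescanned

    def test_clusters_contain_at_least_four_motifs(self, small_study):
        _, truth = small_study
        assert len(truth.cluster_positions) >= SMALL_CONFIG["n_clusters"]
        starts = {(c, s) for c, s, _ in truth.motif_positions}
        for chrom, lo, hi in truth.cluster_positions:
            inside = [s for c, s in starts if c == chrom and lo <= s < hi]
            assert len(inside) >= 4

    def test_targets_have_emitted_up_peak_in_first_kb(self, small_study):
        bundle, truth = small_study
        genes = {g.gene_id: g for g in bundle.genes}
        mut_peaks = bundle.peaks["h2aub_mutant_rep1"]
        for gid in truth.target_genes:
            fk = derive_region(genes[gid], RegionKind.first_1kb)
            assert any(
                p.chrom == fk.chrom and p.start < fk.end and fk.start < p.end
                for p in mut_peaks
            )

    def test_planted_h2aub_gain_at_targets(self, small_study):
        """Independent interval-count check of the planted differential."""
        bundle, truth = small_study
        genes = {g.gene_id: g for g in bundle.genes}

        def mean_scaled_diff(gene_ids):
            diffs = []
            for gid in gene_ids:
                fk = derive_region(genes[gid], RegionKind.first_1kb)
                per_geno = {}
                for genotype in ("wt", "mutant"):
                    vals = []
                    for rep in (1, 2):
                        lib = bundle.libraries[f"h2aub_{genotype}_rep{rep}"]
                        arr = lib.fragments[fk.chrom]
                        raw = int(
                            ((arr[:, 0] < fk.end) & (arr[:, 1] > fk.start)).sum()
                        )
                        vals.append((raw + 1) / (lib.total_base_coverage / 1e9))
                    per_geno[genotype] = np.mean(vals)
                diffs.append(per_geno["mutant"] - per_geno["wt"])
            return float(np.mean(diffs))

        targets = sorted(truth.target_genes)
        non_targets = sorted(set(genes) - truth.target_genes)[: len(targets) * 3]
        assert mean_scaled_diff(targets) > mean_scaled_diff(non_targets)

    def test_k27_loss_at_targets(self, small_study):
        bundle, truth = small_study
        from chromdiff.coverage import average_region_counts, differential_counts, region_counts

        coding = [g for g in bundle.genes if g.biotype == "protein_coding"]
        per_geno = {
            genotype: average_region_counts(
                [
                    region_counts(bundle.libraries[f"k27_{genotype}_rep{r}"], coding, "first_1kb")
                    for r in (1, 2)
                ]
            )
            for genotype in ("wt", "mutant")
        }
        diff = differential_counts(per_geno["mutant"], per_geno["wt"])
        t = [diff[g] for g in sorted(truth.target_genes) if g in diff]
        nt = [diff[g] for g in diff if g not in truth.target_genes]
        assert np.median(t) < np.median(nt)

    def test_dose_response_monotone(self):
        """Mean planted target gain increases with enrichment_fold."""
        means = []
        for fold in (2.0, 4.0, 8.0):
            cfg = SimulationConfig(**{**SMALL_CONFIG, "enrichment_fold": fold})
            bundle, truth = generate_study(cfg)
            genes = {g.gene_id: g for g in bundle.genes}
            diffs = []
            for gid in sorted(truth.target_genes):
                fk = derive_region(genes[gid], RegionKind.first_1kb)
                per_geno = {}
                for genotype in ("wt", "mutant"):
                    lib = bundle.libraries[f"{'h2aub'}_{genotype}_rep1"]
                    arr = lib.fragments[fk.chrom]
                    raw = int(((arr[:, 0] < fk.end) & (arr[:, 1] > fk.start)).sum())
                    per_geno[genotype] = (raw + 1) / (lib.total_base_coverage / 1e9)
                diffs.append(per_geno["mutant"] - per_geno["wt"])
            means.append(np.mean(diffs))
        assert means[0] < means[1] < means[2]

    def test_responsiveness_shifted_for_h2aub_genes(self, small_study):
        bundle, truth = small_study
        scores = dict(zip(bundle.responsiveness["gene_id"], bundle.responsiveness["score"]))
        h2aub = [
            scores[g] for g, cat in truth.mark_assignment.items() if cat in ("both", "h2aub_only")
        ]
        rest = [
            scores[g] for g, cat in truth.mark_assignment.items() if cat not in ("both", "h2aub_only")
        ]
        assert np.median(h2aub) > np.median(rest)
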