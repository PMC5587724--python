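"""Synthetic-data generator: determinism and ground-truth fidelity."""

import numpy as np
import pandas as pd
import pytest

from ribolife import annotation as ann
from ribolife import ribo, simulate, stats


class TestDeterminism:
    def test_identical_bundle_bytes_for_same_seed(self, tmp_path):
        cfg = simulate.SimulationConfig(seed=1, n_genes=15, n_replicates=1,
                                        footprint_reads=5000, library_size=20_000)
        simulate.simulate_all(cfg, tmp_path / "a")
        simulate.simulate_all(cfg, tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_different_seed_changes_genome(self):
        g1, _, _ = simulate.generate_genome_annotation(
            simulate.SimulationConfig(seed=1, n_genes=5))
        g2, _, _ = simulate.generate_genome_annotation(
            simulate.SimulationConfig(seed=2, n_genes=5))
        assert g1[simulate.CHROM] != g2[simulate.CHROM]


class TestGenomeAnnotation:
    def test_planted_uorfs_equal_exhaustive_scan(self, small_sim):
        cfg, genome, transcripts, truth = small_sim
        for t in transcripts:
            scanned = ann.predict_uorfs(t, genome)
            planted = truth.uorfs_by_gene[t.gene_id]
            assert [(u.start_codon, u.interval, u.truncated) for u in scanned] == \
                   [(u.start_codon, u.interval, u.truncated) for u in planted]

    def test_uorf_counts_within_configured_range(self, small_sim):
        cfg, genome, transcripts, truth = small_sim
        lo, hi = cfg.n_uorfs_range
        for gid, us in truth.uorfs_by_gene.items():
            assert lo - hi <= len(us) <= hi  # short UTRs may truncate planting
            assert len(us) <= hi

    def test_planted_motif_is_best_promoter_hit(self):
        from ribolife import chip
        cfg = simulate.SimulationConfig(
            seed=9, n_genes=12,
            motif_plant_spec=[("G0003", "gcn4", 250), ("G0007", "rap1", 400)],
            chip_peak_spec=[("G0003", 250, 10.0)],
            utr_len_override={"G0003": 100, "G0007": 100},
        )
        genome, ts, truth = simulate.generate_genome_annotation(cfg)
        by_id = {t.gene_id: t for t in ts}
        for rec in truth.motif_positions:
            gene = by_id[rec["gene_id"]]
            pwm = chip.pwm_from_consensus(rec["motif"], cfg.motif_sequences[rec["motif"]])
            w = ann.promoter_window(gene, 1000, len(genome[simulate.CHROM]))
            hit = chip.promoter_motif_hit(gene, w, genome, pwm)
            assert hit.position == -rec["upstream_offset"]
            assert hit.strand == "+"
            assert hit.score > 0.9 * pwm.max_score

    def test_planted_summit_recorded_relative_to_start(self):
        cfg = simulate.SimulationConfig(
            seed=10, n_genes=8,
            chip_peak_spec=[("G0002", 300, 8.0)],
            utr_len_override={"G0002": 100},
        )
        genome, ts, truth = simulate.generate_genome_annotation(cfg)
        (rec,) = truth.peak_summits
        gene = {t.gene_id: t for t in ts}["G0002"]
        if gene.strand == "+":
            assert gene.cds[0] - rec["summit"] == 300
        else:
            assert rec["summit"] - (gene.cds[1] - 1) == 300

    def test_ground_truth_json_written(self, tmp_path):
        cfg = simulate.SimulationConfig(seed=3, n_genes=5, n_replicates=1,
                                        footprint_reads=2000, library_size=5000)
        truth = simulate.simulate_all(cfg, tmp_path)
        assert (tmp_path / "ground_truth.json").exists()
        genes, genome = ann.read_annotation(tmp_path / "annotation.gff3",
                                            tmp_path / "genome.fa")
        assert len(genes) == 5


class TestExpressionCounts:
    def test_null_case_conditions_agree(self):
        cfg = simulate.SimulationConfig(seed=4, n_genes=200, nb_dispersion=1e-9,
                                        library_size=500_000)
        _, _, truth = simulate.generate_genome_annotation(cfg)
        mrna, _ = simulate.simulate_expression_counts(truth, cfg)
        norm = stats.normalized_counts(mrna)
        a = norm[mrna.samples_of("wild_type")].mean(axis=1)
        b = norm[mrna.samples_of("long_lived")].mean(axis=1)
        big = a > 200
        assert np.allclose(np.log2(b[big] / a[big]), 0.0, atol=0.25)

    def test_sample_totals_near_library_size(self):
        cfg = simulate.SimulationConfig(seed=5, n_genes=100, library_size=100_000)
        _, _, truth = simulate.generate_genome_annotation(cfg)
        mrna, ribo_cm = simulate.simulate_expression_counts(truth, cfg)
        w = np.array([truth.expression_weight[g] for g in cfg.gene_ids()])
        mu = cfg.library_size * w
        sd_total = np.sqrt(np.sum(mu + cfg.nb_dispersion * mu ** 2))
        for cm in (mrna, ribo_cm):
            totals = cm.counts.sum(axis=0)
            assert (abs(totals - cfg.library_size) < 4 * sd_total).all()

    def test_planted_foldchange_recovered(self):
        cfg = simulate.SimulationConfig(
            seed=6, n_genes=400, library_size=400 * 500, expression_sigma=0.0,
            nb_dispersion=0.05,
            gene_sets={"up": [f"G{i:04d}" for i in range(40)]},
            fold_change_spec={"up": 1.0},
        )
        _, _, truth = simulate.generate_genome_annotation(cfg)
        mrna, _ = simulate.simulate_expression_counts(truth, cfg)
        fc = stats.fold_changes(mrna, "wild_type", "long_lived")
        planted = fc.loc[[f"G{i:04d}" for i in range(40)], "log2fc"]
        # NB standard error of a log2 mean difference at mean mu, n reps
        mu, n, disp = 500.0, cfg.n_replicates, cfg.nb_dispersion
        se = np.sqrt(2 / n * (1 / mu + disp)) / np.log(2)
        hits = np.abs(planted - 1.0) < 2 * se
        assert hits.mean() >= 0.9


class TestFootprints:
    def test_full_frame_purity_all_frame_zero(self):
        cfg = simulate.SimulationConfig(seed=7, n_genes=15, frame_purity=1.0,
                                        footprint_reads=60_000)
        genome, ts, truth = simulate.generate_genome_annotation(cfg)
        fp = simulate.simulate_footprints(ts, truth, cfg, "wild_type", 1)
        calib = ribo.infer_psite_offsets(fp, ts)
        for c in calib.values():
            assert c.accepted
            assert c.frame_fractions[0] > 0.999

    def test_uniform_frames_at_one_third(self):
        cfg = simulate.SimulationConfig(seed=8, n_genes=15, frame_purity=1 / 3,
                                        footprint_reads=100_000)
        genome, ts, truth = simulate.generate_genome_annotation(cfg)
        fp = simulate.simulate_footprints(ts, truth, cfg, "wild_type", 1)
        calib = ribo.infer_psite_offsets(fp, ts)
        for c in calib.values():
            assert max(abs(f - 1 / 3) for f in c.frame_fractions) < 0.02

    def test_lower_utr_occupancy_lowers_ratio_direction(self, small_sim):
        cfg, genome, ts, truth = small_sim
        rc = {}
        for cond in ("wild_type", "long_lived"):
            fp = simulate.simulate_footprints(ts, truth, cfg, cond, 1)
            calib = ribo.infer_psite_offsets(fp, ts)
            rc[cond] = ribo.count_regions(fp, calib, ts, truth.uorfs_by_gene)
        r_wt = (rc["wild_type"]["utr5_norm"] / rc["wild_type"]["cds_norm"]).median()
        r_ll = (rc["long_lived"]["utr5_norm"] / rc["long_lived"]["cds_norm"]).median()
        assert r_ll < r_wt

    def test_missing_condition_factor_raises(self, small_sim):
        cfg, genome, ts, truth = small_sim
        with pytest.raises(ValueError):
            simulate.simulate_footprints(ts, truth, cfg, "no_such_condition", 1)


class TestChipCoverage:
    def test_planted_bump_argmax_near_summit(self):
        cfg = simulate.SimulationConfig(
            seed=11, n_genes=10,
            chip_peak_spec=[("G0004", 250, 10.0)],
            utr_len_override={"G0004": 100},
        )
        genome, ts, truth = simulate.generate_genome_annotation(cfg)
        chip_cov, input_cov = simulate.simulate_chip_coverage(genome, truth, cfg)
        from ribolife.chip import call_peaks
        peaks = call_peaks(chip_cov, input_cov)
        assert len(peaks) == 1
        assert abs(peaks[0].summit - truth.peak_summits[0]["summit"]) <= 10

    def test_no_planted_peaks_none_called(self):
        cfg = simulate.SimulationConfig(seed=12, n_genes=10)
        genome, ts, truth = simulate.generate_genome_annotation(cfg)
        chip_cov, input_cov = simulate.simulate_chip_coverage(genome, truth, cfg)
        from ribolife.chip import call_peaks
        assert call_peaks(chip_cov, input_cov) == []


class TestConfigValidation:
    def test_bad_frame_purity_rejected(self):
        with pytest.raises(ValueError):
            simulate.SimulationConfig(frame_purity=0.1).validate()

    def test_motif_offset_inside_utr_rejected(self):
        cfg = simulate.SimulationConfig(
            motif_plant_spec=[("G0001", "gcn4", 50)],
            utr_len_override={"G0001": 100},
        )
        with pytest.raises(ValueError):
            cfg.validate()
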