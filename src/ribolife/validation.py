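"""Planted-truth benchmark scenarios.

Each function builds synthetic data with known ground truth, runs the
relevant analysis path end to end, and reports how well the planted
signal is recovered. These scenarios double as the package's acceptance
checks and as worked examples of the expected statistical behaviour
(power, level, exactness) at desk-scale problem sizes.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import ribo, simulate, stats, uorf_ratio
from .lifespan import percent_increase


def _seed(base: int, i: int) -> int:
    return (base * 1009 + i) % (2 ** 31)


# ---------------------------------------------------------------------------
# Lifespan worked example
# ---------------------------------------------------------------------------

def lifespan_worked_example() -> float:
    """Percent lifespan increase for mean divisions 28.48 vs 19.6."""
    return percent_increase(28.48, 19.6)


# ---------------------------------------------------------------------------
# P-site calibration
# ---------------------------------------------------------------------------

def psite_offset_recovery(n_seeds: int = 20, base_seed: int = 0) -> float:
    """Fraction of seeds recovering every planted offset exactly.

    Five read lengths with offsets {28:12, 29:12, 30:13, 31:13, 32:13},
    frame purity 0.7; a seed counts as recovered only if all five
    lengths are accepted with the exact planted offset.
    """
    ok = 0
    for i in range(n_seeds):
        cfg = simulate.SimulationConfig(
            seed=_seed(base_seed, i), n_genes=40, footprint_reads=100_000,
            frame_purity=0.7,
        )
        genome, ts, truth = simulate.generate_genome_annotation(cfg)
        fp = simulate.simulate_footprints(ts, truth, cfg, "wild_type", 1)
        calib = ribo.infer_psite_offsets(fp, ts)
        ok += all(
            calib[L].accepted and calib[L].offset == d
            for L, d in truth.psite_offsets.items()
        )
    return ok / n_seeds


# ---------------------------------------------------------------------------
# uORF skipping
# ---------------------------------------------------------------------------

def _skipping_config(seed: int, factor: float) -> simulate.SimulationConfig:
    return simulate.SimulationConfig(
        seed=seed, n_genes=360, n_replicates=3, footprint_reads=300_000,
        expression_sigma=0.4, n_uorfs_range=(1, 3),
        utr_occupancy_factor={"wild_type": 1.0, "long_lived": factor},
    )


def _ratio_pairs(cfg: simulate.SimulationConfig, numerator: str = "utr5"):
    genome, ts, truth = simulate.generate_genome_annotation(cfg)
    aggs = {}
    for cond in cfg.conditions:
        rcs = []
        calib = None
        for rep in range(1, cfg.n_replicates + 1):
            fp = simulate.simulate_footprints(ts, truth, cfg, cond, rep)
            if calib is None:
                calib = ribo.infer_psite_offsets(fp, ts)
            rcs.append(ribo.count_regions(fp, calib, ts, truth.uorfs_by_gene))
        aggs[cond] = ribo.aggregate_replicates(rcs)
    return uorf_ratio.utr_cds_ratio(
        aggs["long_lived"], aggs["wild_type"], "long_lived", "wild_type",
        numerator_kind=numerator,
    )


def uorf_skipping_power(n_seeds: int = 20, base_seed: int = 0) -> Dict[str, float]:
    """Detection of a planted 0.4x 5'UTR-occupancy drop.

    Returns the fraction of seeds where the two-sided rank test rejects
    at p < 0.01 with a negative median log2 shift, plus the mean number
    of genes passing the >50-read inclusion filter.
    """
    hits, included = 0, []
    for i in range(n_seeds):
        pairs = _ratio_pairs(_skipping_config(_seed(base_seed, i), 0.4))
        _, p, shift = uorf_ratio.compare_ratio_distributions(pairs)
        hits += (p < 0.01) and (shift < 0)
        included.append(len(pairs))
    return {
        "rejection_rate": hits / n_seeds,
        "mean_included_genes": float(np.mean(included)),
    }


def uorf_skipping_null_level(n_seeds: int = 40, base_seed: int = 0) -> float:
    """Rejection rate at alpha = 0.05 with no planted occupancy change."""
    hits = 0
    for i in range(n_seeds):
        pairs = _ratio_pairs(_skipping_config(_seed(base_seed, 500 + i), 1.0))
        _, p, _ = uorf_ratio.compare_ratio_distributions(pairs)
        hits += p < 0.05
    return hits / n_seeds


def outlier_ranking(n_seeds: int = 20, base_seed: int = 0) -> float:
    """A single gene with a 5x UTR-density drop should rank first.

    Null background (no global occupancy change); one highly expressed,
    long-5'UTR gene gets a 0.2x UTR-density factor, emulating a
    GCN4-like outlier. Returns the fraction of seeds where that gene
    has the largest |log2 ratio shift| among included genes.
    """
    outlier = "G0010"
    hits = 0
    for i in range(n_seeds):
        cfg = simulate.SimulationConfig(
            seed=_seed(base_seed, 900 + i), n_genes=150, n_replicates=3,
            footprint_reads=120_000, expression_sigma=0.4, n_uorfs_range=(1, 3),
            utr_occupancy_factor={"wild_type": 1.0, "long_lived": 1.0},
            gene_utr_factor={outlier: 0.2},
            gene_expression_boost={outlier: 3.0},
            utr_len_override={outlier: 300},
        )
        pairs = _ratio_pairs(cfg)
        ranked = uorf_ratio.rank_extreme_genes(pairs)
        hits += len(ranked) > 0 and ranked.index[0] == outlier
    return hits / n_seeds


# ---------------------------------------------------------------------------
# Statistical primitives vs oracles
# ---------------------------------------------------------------------------

def mwu_enumeration_agreement(base_seed: int = 0) -> float:
    """Fraction of small tie-free inputs where the U test equals the
    exhaustive-enumeration oracle (all sizes with n_a + n_b <= 10)."""
    rng = np.random.default_rng(base_seed)
    total, ok = 0, 0
    for n1 in range(1, 10):
        for n2 in range(1, 10):
            if n1 + n2 > 10:
                continue
            for _ in range(5):
                a = rng.normal(size=n1)
                b = rng.normal(size=n2)
                u, p = stats.mann_whitney_u(a, b)
                u_ref, p_ref = _mwu_brute(a, b)
                total += 1
                ok += (u == u_ref) and math.isclose(p, p_ref, abs_tol=1e-12)
    return ok / total


def _mwu_brute(a: np.ndarray, b: np.ndarray) -> Tuple[float, float]:
    pooled = np.sort(np.concatenate([a, b]))
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(a)
    u_obs = sum(rank[v] for v in a) - n1 * (n1 + 1) / 2
    us = [
        sum(c) - n1 * (n1 + 1) / 2
        for c in itertools.combinations(range(1, len(pooled) + 1), n1)
    ]
    n_le = sum(u <= u_obs for u in us)
    n_ge = sum(u >= u_obs for u in us)
    return u_obs, min(1.0, 2 * min(n_le, n_ge) / len(us))


def bh_oracle_agreement(n_vectors: int = 50, base_seed: int = 0) -> float:
    """Fraction of random p-vectors where BH matches hand-applied step-up."""
    rng = np.random.default_rng(base_seed + 1)
    ok = 0
    for _ in range(n_vectors):
        p = rng.random(int(rng.integers(1, 60)))
        q = stats.bh_fdr(p)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        ref = np.empty(m)
        running = np.inf
        for r in range(m, 0, -1):
            i = order[r - 1]
            running = min(running, p[i] * m / r)
            ref[i] = min(running, 1.0)
        ok += np.allclose(q, ref)
    return ok / n_vectors


# ---------------------------------------------------------------------------
# Fold-change recovery
# ---------------------------------------------------------------------------

def fold_change_recovery(base_seed: int = 0) -> Dict[str, float]:
    """NB simulation at mean 500, dispersion 0.05, n = 3, 100 planted
    genes with log2FC = 1 among 1000; returns the mean estimate."""
    planted = [f"G{i:04d}" for i in range(100)]
    cfg = simulate.SimulationConfig(
        seed=_seed(base_seed, 7), n_genes=1000, n_replicates=3,
        library_size=1000 * 500, expression_sigma=0.0, nb_dispersion=0.05,
        gene_sets={"planted": planted}, fold_change_spec={"planted": 1.0},
    )
    _, _, truth = simulate.generate_genome_annotation(cfg)
    mrna, _ = simulate.simulate_expression_counts(truth, cfg)
    fc = stats.fold_changes(mrna, "wild_type", "long_lived")
    est = fc.loc[planted, "log2fc"]
    return {"mean_log2fc_estimate": float(est.mean())}


def regulation_gate_examples() -> bool:
    """The three canonical classification-rule examples hold."""
    return (
        stats.classify_regulation(math.log2(2.5), 0.005) == "up"
        and stats.classify_regulation(math.log2(1.9), 0.001) == "unchanged"
        and stats.classify_regulation(math.log2(3.0), 0.02) == "unchanged"
    )


# ---------------------------------------------------------------------------
# ChIP geometry
# ---------------------------------------------------------------------------

def chip_summit_recovery(n_seeds: int = 5, base_seed: int = 0) -> float:
    """Maximum |called - planted| summit distance (nt) over seeds."""
    from .chip import call_peaks

    worst = 0
    for i in range(n_seeds):
        cfg = simulate.SimulationConfig(
            seed=_seed(base_seed, 40 + i), n_genes=20,
            chip_peak_spec=[("G0003", 250, 10.0), ("G0009", 400, 10.0),
                            ("G0015", 600, 10.0)],
            utr_len_override={"G0003": 100, "G0009": 100, "G0015": 100},
        )
        genome, ts, truth = simulate.generate_genome_annotation(cfg)
        chip_cov, input_cov = simulate.simulate_chip_coverage(genome, truth, cfg)
        peaks = call_peaks(chip_cov, input_cov)
        planted = sorted(rec["summit"] for rec in truth.peak_summits)
        if len(peaks) != len(planted):
            return float("inf")
        called = sorted(p.summit for p in peaks)
        worst = max(worst, max(abs(c - t) for c, t in zip(called, planted)))
    return float(worst)


def promoter_partition_exact() -> bool:
    """unique/ambiguous/unassigned partition on a divergent-promoter fixture."""
    from .annotation import PromoterWindow
    from .chip import Peak, assign_peaks_to_genes

    promoters = [
        PromoterWindow("solo", "chr1", "+", (4000, 5000), 1000),
        PromoterWindow("left", "chr1", "-", (9000, 10_000), 1000),
        PromoterWindow("right", "chr1", "+", (9400, 10_400), 1000),
    ]
    peaks = [
        Peak("chr1", 4700, 4800, 4750, 5.0),      # unique -> solo
        Peak("chr1", 9600, 9700, 9650, 5.0),      # shared divergent -> ambiguous
        Peak("chr1", 20_000, 20_100, 20_050, 5.0),  # unassigned
    ]
    annotated, targets = assign_peaks_to_genes(peaks, promoters)
    kinds = [p.ambiguity for p in annotated]
    return kinds == ["unique", "ambiguous", "unassigned"] and targets == ["solo"]


def pwm_brute_force_agreement(n_sequences: int = 3, base_seed: int = 0) -> bool:
    """Max-site scan equals brute-force window scoring on 2-kb sequences,
    and is invariant under reverse complementation."""
    from .annotation import revcomp
    from .chip import PWM, scan_pwm

    rng = np.random.default_rng(base_seed + 2)
    for t in range(n_sequences):
        K = int(rng.integers(6, 14))
        pwm = PWM(f"m{t}", rng.dirichlet(np.ones(4), size=K).T)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        hit = scan_pwm(seq, pwm)
        lo = pwm.log_odds
        idx = {b: i for i, b in enumerate("ACGTN")}
        best = -np.inf
        for strand in "+-":
            for w in range(2000 - K + 1):
                site = seq[w: w + K] if strand == "+" else revcomp(seq[w: w + K])
                s = sum(lo[idx[b], i] for i, b in enumerate(site))
                best = max(best, s)
        if not math.isclose(hit.score, best, abs_tol=1e-9):
            return False
        if not math.isclose(hit.score, scan_pwm(revcomp(seq), pwm).score, abs_tol=1e-9):
            return False
    return True


# ---------------------------------------------------------------------------
# End-to-end demo
# ---------------------------------------------------------------------------

def demo_recovery(workdir, seed: int = 42) -> Dict[str, object]:
    """Run the synthetic demo end to end and check planted-effect recovery."""
    import json
    from pathlib import Path

    import pandas as pd

    from .pipeline import PipelineConfig, make_demo, run_pipeline

    workdir = Path(workdir)
    config_path = make_demo(seed, workdir)
    cfg = PipelineConfig.from_yaml(config_path)
    manifest = run_pipeline(cfg)
    stages = manifest["stages"]
    truth = json.loads((workdir / "inputs" / "ground_truth.json").read_text())

    out: Dict[str, object] = {
        "all_stages_ok": all(s["status"] == "ok" for s in stages.values()),
        "ratio_p": stages["ratios"]["utr5_p"],
        "ratio_median_shift": stages["ratios"]["utr5_median_log2_shift"],
        "outlier_ranked_first": stages["ratios"]["utr5_top_gene"] == "G0040",
    }
    heat = pd.read_csv(Path(cfg.outdir) / "geneset_mean_log2fc.tsv", sep="\t", index_col=0)
    out["rp_set_mean_log2fc"] = float(heat.loc["ribosomal_proteins", "long_lived"])
    out["rp_set_vs_rest_p"] = stages["genesets"]["tests"]["ribosomal_proteins"]["p"]

    targets = pd.read_csv(Path(cfg.outdir) / "chip_targets.tsv", sep="\t")
    planted = {rec["gene_id"]: rec["summit"] for rec in truth["peak_summits"]}
    unique = targets[targets["ambiguity"] == "unique"]
    out["chip_targets_match_planted"] = set(unique["gene_id"]) == set(planted)
    if out["chip_targets_match_planted"]:
        errs = [abs(int(r["summit"]) - planted[r["gene_id"]]) for _, r in unique.iterrows()]
        out["chip_max_summit_error"] = max(errs)
        expected_cfg = {
            "G0045": "rap1_upstream_of_gcn4", "G0046": "rap1_upstream_of_gcn4",
            "G0047": "rap1_upstream_of_gcn4", "G0048": "gcn4_upstream_of_rap1",
            "G0049": "gcn4_upstream_of_rap1", "G0050": "gcn4_upstream_of_rap1",
        }
        got = dict(zip(unique["gene_id"], unique["configuration"]))
        out["chip_configurations_correct"] = got == expected_cfg
    lsum = pd.read_csv(Path(cfg.outdir) / "lifespan_summary.tsv", sep="\t")
    oe = lsum[lsum["strain"] == "gcn4_oe"].iloc[0]
    out["lifespan_percent_increase"] = float(oe["percent_increase_vs_ref"])
    out["lifespan_p"] = float(oe["p_value"])
    return out


def demo_reproducible(root, seed: int = 42) -> bool:
    """Two demo + run-all executions produce byte-identical trees."""
    import os
    from pathlib import Path

    from .pipeline import PipelineConfig, make_demo, run_pipeline

    root = Path(root)
    cwd = os.getcwd()
    try:
        for name in ("r1", "r2"):
            d = root / name
            d.mkdir(parents=True, exist_ok=True)
            os.chdir(d)
            cfg = PipelineConfig.from_yaml(make_demo(seed, "demo"))
            run_pipeline(cfg)
    finally:
        os.chdir(cwd)
    files1 = sorted(p.relative_to(root / "r1")
                    for p in (root / "r1").rglob("*") if p.is_file())
    files2 = sorted(p.relative_to(root / "r2")
                    for p in (root / "r2").rglob("*") if p.is_file())
    if files1 != files2:
        return False
    return all(
        (root / "r1" / rel).read_bytes() == (root / "r2" / rel).read_bytes()
        for rel in files1
    )
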