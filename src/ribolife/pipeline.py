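"""End-to-end orchestration: demo generation, staged run, manifest.

``make_demo`` writes a fully synthetic input bundle (genome, annotation,
count matrices, footprint libraries, ChIP tracks, PWMs, gene sets,
lifespan table) plus a pipeline config; ``run_pipeline`` executes the
analysis stages in order, writing one TSV per product and a JSON run
manifest with parameters and output checksums. Stages whose inputs are
absent are marked skipped; with ``resume=True`` stages whose outputs
already exist are not recomputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import chip as chip_mod
from . import genesets as gs
from . import lifespan as ls
from . import ribo, simulate, stats, uorf_ratio

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration for a pipeline run."""

    outdir: str = "results"
    seed: int = 0
    genome_fasta: Optional[str] = None
    annotation_gff3: Optional[str] = None
    mrna_counts: Optional[str] = None
    ribo_counts: Optional[str] = None
    footprint_libraries: Dict[str, List[str]] = field(default_factory=dict)
    chip_track: Optional[str] = None
    input_track: Optional[str] = None
    pwm_files: Dict[str, str] = field(default_factory=dict)
    gene_sets_gmt: Optional[str] = None
    lifespan_tsv: Optional[str] = None
    reference_condition: str = "wild_type"
    treatment_condition: str = "long_lived"
    lifespan_reference: str = "wild_type"
    promoter_window: int = 1000
    uorf_min_length: int = 0
    candidate_offsets: List[int] = field(default_factory=lambda: list(range(9, 16)))
    min_start_reads: int = 500
    min_reads: int = 50
    pseudocount: float = 0.5
    min_total_count: int = 10
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.01
    min_set_size: int = 10
    peak_window: int = 150
    peak_step: int = 25
    peak_min_fold: float = 4.0
    peak_min_pois_p: float = 1e-5
    motif_threshold_fraction: float = 0.6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def make_demo(seed: int, outdir: str | Path) -> Path:
    """Write a synthetic demo input bundle and its pipeline config.

    The demo emulates the qualitative structure of the study: a
    wild-type and a long-lived condition with globally reduced 5'UTR
    occupancy (uORF skipping), a repressed translation-machinery gene
    set, one GCN4-architecture gene carrying four uORFs with a strong
    additional 5'UTR-density drop, promoters of planted targets carrying
    Gcn4/Rap1 sites in both relative orders with matching ChIP peaks,
    and lifespan assays for a wild-type and an overexpression strain.
    """
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    n_genes = 60
    ids = [f"G{i:04d}" for i in range(n_genes)]
    rp_set = ids[0:12]
    init_set = ids[12:22]
    gcn4_like = "G0040"
    activated = ["G0045", "G0046", "G0047"]   # Gcn4 downstream of Rap1
    repressed = ["G0048", "G0049", "G0050"]   # Gcn4 upstream of Rap1
    motif_spec: List[Tuple[str, str, int]] = []
    peak_spec: List[Tuple[str, int, float]] = []
    for g in activated:
        motif_spec += [(g, "gcn4", 250), (g, "rap1", 450)]
        peak_spec.append((g, 250, 12.0))
    for g in repressed:
        motif_spec += [(g, "gcn4", 600), (g, "rap1", 200)]
        peak_spec.append((g, 600, 12.0))

    sim = simulate.SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        n_replicates=3,
        library_size=150_000,
        footprint_reads=100_000,
        expression_sigma=0.6,
        conditions=("wild_type", "long_lived"),
        utr_occupancy_factor={"wild_type": 1.0, "long_lived": 0.4},
        gene_sets={"ribosomal_proteins": rp_set, "initiation_factors": init_set},
        fold_change_spec={"ribosomal_proteins": -1.5, "G0030": 2.0},
        nb_dispersion=0.02,  # replicate correlations in tight yeast designs
        n_uorfs_range=(1, 3),
        uorf_counts={gcn4_like: 4},
        gene_utr_factor={gcn4_like: 0.2},
        gene_expression_boost={gcn4_like: 4.0},
        utr_len_override={gcn4_like: 350, **{g: 100 for g in activated + repressed}},
        motif_plant_spec=motif_spec,
        chip_peak_spec=peak_spec,
    )
    simulate.simulate_all(sim, inputs)
    for name, consensus in sim.motif_sequences.items():
        chip_mod.write_pwm_tab(
            chip_mod.pwm_from_consensus(name, consensus), inputs / f"{name}.pwm"
        )

    cfg = PipelineConfig(
        outdir=str(outdir / "results"),
        seed=seed,
        genome_fasta=str(inputs / "genome.fa"),
        annotation_gff3=str(inputs / "annotation.gff3"),
        mrna_counts=str(inputs / "mrna_counts.tsv"),
        ribo_counts=str(inputs / "ribo_counts.tsv"),
        footprint_libraries={
            cond: [str(inputs / f"footprints_{cond}_rep{r}.tsv") for r in (1, 2, 3)]
            for cond in ("wild_type", "long_lived")
        },
        chip_track=str(inputs / "chip.bedgraph"),
        input_track=str(inputs / "input.bedgraph"),
        pwm_files={n: str(inputs / f"{n}.pwm") for n in sim.motif_sequences},
        gene_sets_gmt=str(inputs / "gene_sets.gmt"),
        lifespan_tsv=str(inputs / "lifespan.tsv"),
        reference_condition="wild_type",
        treatment_condition="long_lived",
        lifespan_reference="wild_type",
    )
    config_path = outdir / "config.yaml"
    cfg.to_yaml(config_path)
    return config_path


def run_pipeline(config: PipelineConfig, resume: bool = False) -> Dict:
    """Execute all stages; return the run manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {"seed": config.seed, "stages": {}, "parameters": dataclasses.asdict(config)}
    state: Dict = {}

    stages = [
        ("annotate", _stage_annotate),
        ("calibrate", _stage_calibrate),
        ("count", _stage_count),
        ("ratios", _stage_ratios),
        ("de", _stage_de),
        ("te", _stage_te),
        ("genesets", _stage_genesets),
        ("chip", _stage_chip),
        ("lifespan", _stage_lifespan),
    ]
    for name, fn in stages:
        try:
            record = fn(config, out, state, resume)
        except _SkipStage as exc:
            logger.info("stage %s skipped: %s", name, exc)
            manifest["stages"][name] = {"status": "skipped", "reason": str(exc)}
            continue
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, out)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        record["status"] = "ok"
        record["outputs"] = {
            f: _sha256(out / f) for f in record.get("files", [])
        }
        record.pop("files", None)
        manifest["stages"][name] = record
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: Dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


class _SkipStage(Exception):
    pass


def _require(cond: bool, reason: str) -> None:
    if not cond:
        raise _SkipStage(reason)


def _stage_annotate(config: PipelineConfig, out: Path, state: Dict, resume: bool) -> Dict:
    _require(bool(config.genome_fasta and config.annotation_gff3), "no annotation inputs")
    genes, genome = ann.read_annotation(config.annotation_gff3, config.genome_fasta)
    uorfs = {
        g.gene_id: ann.predict_uorfs(g, genome, min_length=config.uorf_min_length)
        for g in genes
        if g.utr5 is not None
    }
    promoters = [
        ann.promoter_window(g, config.promoter_window, len(genome[g.chrom])) for g in genes
    ]
    ann.uorfs_to_bed(genes, uorfs, out / "uorfs.bed")
    ann.promoters_to_bed(promoters, out / "promoters.bed")
    state.update(genes=genes, genome=genome, uorfs=uorfs, promoters=promoters)
    return {
        "n_genes": len(genes),
        "n_uorf_genes": sum(1 for u in uorfs.values() if u),
        "files": ["uorfs.bed", "promoters.bed"],
    }


def _stage_calibrate(config: PipelineConfig, out: Path, state: Dict, resume: bool) -> Dict:
    _require(bool(config.footprint_libraries), "no footprint libraries")
    _require("genes" in state, "annotation stage did not run")
    calib_by_lib: Dict[str, ribo.CalibrationSet] = {}
    files = []
    for cond, paths in config.footprint_libraries.items():
        for p in paths:
            fp = ribo.PositionalCounts.from_tsv(p)
            calib = ribo.infer_psite_offsets(
                fp, state["genes"], config.candidate_offsets, config.min_start_reads
            )
            calib_by_lib[fp.library_id] = calib
            fname = f"psite_calibration_{fp.library_id}.tsv"
            ribo.calibration_to_frame(calib).to_csv(out / fname, sep="\t", index=False)
            files.append(fname)
    state["calibrations"] = calib_by_lib
    return {"n_libraries": len(calib_by_lib), "files": files}


def _stage_count(config: PipelineConfig, out: Path, state: Dict, resume: bool) -> Dict:
    _require("calibrations" in state, "calibration stage did not run")
    agg_by_cond: Dict[str, pd.DataFrame] = {}
    files = []
    for cond, paths in config.footprint_libraries.items():
        per_lib = []
        for p in paths:
            fp = ribo.PositionalCounts.from_tsv(p)
            rc = ribo.count_regions(
                fp, state["calibrations"][fp.library_id], state["genes"], state["uorfs"]
            )
            fname = f"region_counts_{fp.library_id}.tsv"
            rc.to_csv(out / fname, sep="\t")
            files.append(fname)
            per_lib.append(rc)
        agg = ribo.aggregate_replicates(per_lib)
        fname = f"region_counts_{cond}_aggregated.tsv"
        agg.to_csv(out / fname, sep="\t")
        files.append(fname)
        agg_by_cond[cond] = agg
    state["aggregated"] = agg_by_cond
    return {"conditions": sorted(agg_by_cond), "files": files}


def _stage_ratios(config: PipelineConfig, out: Path, state: Dict, resume: bool) -> Dict:
    _require("aggregated" in state, "region counting did not run")
    agg = state["aggregated"]
    a, b = config.treatment_condition, config.reference_condition
    _require(a in agg and b in agg, f"conditions {a}/{b} not counted")
    record: Dict = {"files": []}
    for kind in ("utr5", "uorf"):
        pairs = uorf_ratio.utr_cds_ratio(
            agg[a], agg[b], a, b, min_reads=config.min_reads, numerator_kind=kind
        )
        fname = f"ratios_{kind}.tsv"
        pairs.to_csv(out / fname, sep="\t")
        record["files"].append(fname)
        record[f"n_included_{kind}"] = int(len(pairs))
        if len(pairs) >= 10:
            u, p, shift = uorf_ratio.compare_ratio_distributions(pairs)
            record[f"{kind}_U"] = float(u)
            record[f"{kind}_p"] = float(p)
            record[f"{kind}_median_log2_shift"] = float(shift)
            ranked = uorf_ratio.rank_extreme_genes(pairs)
            fname = f"ratio_ranking_{kind}.tsv"
            ranked.to_csv(out / fname, sep="\t")
            record["files"].append(fname)
            record[f"{kind}_top_gene"] = str(ranked.index[0])
    state["ratio_record"] = record
    return record


def _stage_de(config: PipelineConfig, out: Path, state: Dict, resume: bool) -> Dict:
    _require(bool(config.mrna_counts), "no mRNA count matrix")
    record: Dict = {"files": []}
    for assay, path in (("mrna", config.mrna_counts), ("ribo", config.ribo_counts)):
        if not path:
            continue
        cm = stats.CountMatrix.from_tsv(path)
        fc = stats.fold_changes(
            cm,
            config.reference_condition,
            config.treatment_condition,
            pseudocount=config.pseudocount,
            min_total=config.min_total_count,
            fc_threshold=config.fc_threshold,
            fdr_threshold=config.fdr_threshold,
        )
        fname = f"fold_changes_{assay}.tsv"
        fc.to_csv(out / fname, sep="\t")
        record["files"].append(fname)
        record[f"n_up_{assay}"] = int((fc["status"] == stats.STATUS_UP).sum())
        record[f"n_down_{assay}"] = int((fc["status"] == stats.STATUS_DOWN).sum())
        state[f"fc_{assay}"] = fc
    return record


def _stage_te(config: PipelineConfig, out: Path, state: Dict, resume: bool) -> Dict:
    _require("fc_mrna" in state and "fc_ribo" in state, "need both mRNA and Ribo fold-changes")
    te = stats.translation_efficiency(state["fc_ribo"], state["fc_mrna"])
    te.to_csv(out / "translation_efficiency.tsv", sep="\t")
    state["te"] = te
    return {"n_genes": int(len(te)), "files": ["translation_efficiency.tsv"]}


def _stage_genesets(config: PipelineConfig, out: Path, state: Dict, resume: bool) -> Dict:
    _require(bool(config.gene_sets_gmt), "no gene-set GMT")
    _require("fc_mrna" in state, "fold-change stage did not run")
    sets = gs.read_gmt(config.gene_sets_gmt)
    fc_by_strain = {config.treatment_condition: state["fc_mrna"]}
    matrix = gs.heatmap_matrix(fc_by_strain, sets, min_size=config.min_set_size)
    matrix.to_csv(out / "geneset_mean_log2fc.tsv", sep="\t")
    record: Dict = {"files": ["geneset_mean_log2fc.tsv"], "tests": {}}
    for s in sets:
        try:
            u, p = gs.set_vs_rest_test(state["fc_mrna"], s)
            record["tests"][s.set_id] = {"U": float(u), "p": float(p)}
        except ValueError:
            continue
    return record


def _stage_chip(config: PipelineConfig, out: Path, state: Dict, resume: bool) -> Dict:
    _require(bool(config.chip_track and config.input_track), "no ChIP tracks")
    _require("promoters" in state, "annotation stage did not run")
    genome = state["genome"]
    lengths = {c: len(s) for c, s in genome.items()}
    chip_cov = chip_mod.read_bedgraph(config.chip_track, lengths)
    input_cov = chip_mod.read_bedgraph(config.input_track, lengths)
    peaks = chip_mod.call_peaks(
        chip_cov, input_cov,
        window=config.peak_window, step=config.peak_step,
        min_fold=config.peak_min_fold, min_pois_p=config.peak_min_pois_p,
    )
    peaks, targets = chip_mod.assign_peaks_to_genes(peaks, state["promoters"])
    chip_mod.write_narrowpeak(peaks, out / "peaks.narrowPeak")
    by_id = {g.gene_id: g for g in state["genes"]}
    pwms = {
        name: chip_mod.read_pwm_tab(path, motif_id=name)
        for name, path in config.pwm_files.items()
    }
    rows = []
    for p in peaks:
        row = {
            "chrom": p.chrom, "start": p.start, "end": p.end, "summit": p.summit,
            "enrichment": p.enrichment, "ambiguity": p.ambiguity,
            "gene_id": p.assigned_gene or "",
        }
        if p.assigned_gene:
            gene = by_id[p.assigned_gene]
            row["summit_to_start"] = chip_mod.summit_distance_to_start(p, gene)
            window = ann.promoter_window(gene, config.promoter_window, lengths[gene.chrom])
            hits = {
                name: chip_mod.promoter_motif_hit(gene, window, genome, pwm)
                for name, pwm in pwms.items()
            }
            for name, hit in hits.items():
                row[f"{name}_score"] = hit.score
                row[f"{name}_position"] = hit.position
                row[f"{name}_strand"] = hit.strand
            if {"gcn4", "rap1"} <= set(hits):
                row["configuration"] = chip_mod.classify_configuration(
                    hits["gcn4"], hits["rap1"],
                    chip_mod.default_hit_threshold(pwms["gcn4"], config.motif_threshold_fraction),
                    chip_mod.default_hit_threshold(pwms["rap1"], config.motif_threshold_fraction),
                )
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(out / "chip_targets.tsv", sep="\t", index=False)
    state["chip_table"] = table
    return {
        "n_peaks": len(peaks),
        "n_unique_targets": len(targets),
        "files": ["peaks.narrowPeak", "chip_targets.tsv"],
    }


def _stage_lifespan(config: PipelineConfig, out: Path, state: Dict, resume: bool) -> Dict:
    _require(bool(config.lifespan_tsv), "no lifespan table")
    assays = ls.read_lifespan_tsv(config.lifespan_tsv)
    ref = config.lifespan_reference
    _require(ref in assays, f"reference strain {ref!r} absent")
    rows = []
    for strain in sorted(assays):
        a = assays[strain]
        row = {"strain": strain, "n_cells": a.n, "mean_divisions": ls.mean_lifespan(a)}
        if strain != ref:
            row["percent_increase_vs_ref"] = ls.percent_increase(
                ls.mean_lifespan(a), ls.mean_lifespan(assays[ref])
            )
            u, p = ls.lifespan_test(a, assays[ref])
            row["U"], row["p_value"] = u, p
        rows.append(row)
        ls.survival_curve(a).to_csv(out / f"survival_{strain}.tsv", sep="\t", index=False)
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "lifespan_summary.tsv", sep="\t", index=False)
    state["lifespan_summary"] = summary
    return {
        "strains": sorted(assays),
        "files": ["lifespan_summary.tsv"] + [f"survival_{s}.tsv" for s in sorted(assays)],
    }
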