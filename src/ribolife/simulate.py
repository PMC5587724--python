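"""Synthetic multi-omics data with known ground truth.

Generates every input the pipeline consumes — genome + annotation with
planted uORFs and promoter motifs, negative-binomial mRNA/footprint
count matrices with planted fold-changes, positional footprint 5'-end
tables with planted P-site offsets and 3-nt periodicity, ChIP/input
coverage with Gaussian-shaped peaks over planted summits, and
replicative-lifespan division counts — so that every analysis stage can
be validated against what was planted.

Construction notes: synthetic 5'UTR backgrounds are drawn from {A,C,T}
(and the base before each planted start codon is forced to C), so the
planted ATG/GTG/TTG uORFs are provably the only ORF starts in a UTR and
the ground-truth record coincides with an exhaustive scan. Promoters are
scrubbed of chance occurrences of the planted motif consensi before
planting, so the planted site is the best match in its promoter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._rng import substream
from .annotation import (
    START_CODONS,
    TranscriptModel,
    UorfModel,
    revcomp,
    write_annotation,
    write_fasta,
)
from .ribo import POSITIONAL_COLUMNS, PositionalCounts
from .stats import CountMatrix

logger = logging.getLogger(__name__)

CHROM = "chrSim"

DEFAULT_OFFSETS = {28: 12, 29: 12, 30: 13, 31: 13, 32: 13}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data.

    Defaults emulate a two-condition yeast ribosome-profiling design:
    three biological replicates per condition, 28-32 nt footprints with
    canonical 12-13 nt P-site offsets, overdispersed NB counts, and a
    long-lived condition in which 5'UTR/uORF ribosome occupancy drops to
    0.4x of wild type (generalized uORF skipping).
    """

    seed: int = 0
    n_genes: int = 100
    n_replicates: int = 3
    library_size: int = 200_000          # expected mRNA/footprint-CDS counts per library
    footprint_reads: int = 100_000       # positional footprint 5'-end records per library
    nb_dispersion: float = 0.05
    expression_sigma: float = 1.0        # log-normal spread of per-gene expression (0 = equal)
    psite_offset_by_length: Dict[int, int] = field(default_factory=lambda: dict(DEFAULT_OFFSETS))
    length_probs: Optional[Dict[int, float]] = None  # default uniform over lengths
    frame_purity: float = 0.7
    start_codon_boost: float = 0.08      # fraction of CDS footprints at the initiation codon
    conditions: Tuple[str, str] = ("wild_type", "long_lived")
    utr_occupancy_factor: Dict[str, float] = field(
        default_factory=lambda: {"wild_type": 1.0, "long_lived": 0.4}
    )
    utr_base_density: float = 0.5        # 5'UTR per-nt footprint density relative to CDS
    uorf_share: float = 0.8              # fraction of UTR footprints inside the uORF union
    gene_utr_factor: Dict[str, float] = field(default_factory=dict)  # extra, non-reference cond.
    gene_expression_boost: Dict[str, float] = field(default_factory=dict)
    utr_len_override: Dict[str, int] = field(default_factory=dict)
    gene_sets: Dict[str, List[str]] = field(default_factory=dict)
    fold_change_spec: Dict[str, float] = field(default_factory=dict)  # set/gene -> log2FC
    ribo_fold_change_spec: Optional[Dict[str, float]] = None          # default: same as mRNA
    utr_len_range: Tuple[int, int] = (50, 300)
    n_uorfs_range: Tuple[int, int] = (0, 4)
    uorf_counts: Dict[str, int] = field(default_factory=dict)  # per-gene override
    cds_codon_range: Tuple[int, int] = (100, 400)
    utr3_len: int = 100
    promoter_len: int = 1000
    intergenic_gap: int = 400
    motif_sequences: Dict[str, str] = field(
        default_factory=lambda: {"gcn4": "TGACTCA", "rap1": "ACACCCATACATT"}
    )
    motif_plant_spec: List[Tuple[str, str, int]] = field(default_factory=list)
    chip_peak_spec: List[Tuple[str, int, float]] = field(default_factory=list)
    chip_base_depth: float = 5.0
    chip_peak_sd: float = 75.0
    lifespan_means: Dict[str, float] = field(
        default_factory=lambda: {"wild_type": 19.6, "gcn4_oe": 28.48}
    )
    lifespan_n: Dict[str, int] = field(
        default_factory=lambda: {"wild_type": 28, "gcn4_oe": 30}
    )
    lifespan_shape: float = 6.0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_replicates <= 0 or self.library_size <= 0:
            raise ValueError("counts must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not (1 / 3 - 1e-9 <= self.frame_purity <= 1.0 + 1e-9):
            raise ValueError("frame_purity must lie in [1/3, 1]")
        for cond in self.conditions:
            if cond not in self.utr_occupancy_factor:
                raise ValueError(f"utr_occupancy_factor missing condition {cond!r}")
        for gid, name, off in self.motif_plant_spec:
            motif = self.motif_sequences.get(name)
            if motif is None:
                raise ValueError(f"unknown motif {name!r}")
            utr_len = self.utr_len_override.get(gid)
            if utr_len is None:
                raise ValueError(
                    f"gene {gid} with a planted motif needs utr_len_override "
                    "(offsets are anchored at the CDS start)"
                )
            if not (utr_len + len(motif) <= off <= self.promoter_len + utr_len):
                raise ValueError(
                    f"motif offset {off} for {gid} must lie upstream of the 5'UTR "
                    f"(length {utr_len}) and within the promoter block"
                )

    def gene_ids(self) -> List[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """What was planted, for validation of every downstream stage."""

    transcripts: List[TranscriptModel] = field(default_factory=list)
    uorfs_by_gene: Dict[str, List[UorfModel]] = field(default_factory=dict)
    motif_positions: List[Dict] = field(default_factory=list)
    peak_summits: List[Dict] = field(default_factory=list)
    expression_weight: Dict[str, float] = field(default_factory=dict)
    mrna_log2fc: Dict[str, float] = field(default_factory=dict)
    ribo_log2fc: Dict[str, float] = field(default_factory=dict)
    psite_offsets: Dict[int, int] = field(default_factory=dict)
    utr_occupancy_factor: Dict[str, float] = field(default_factory=dict)
    gene_utr_factor: Dict[str, float] = field(default_factory=dict)
    lifespan_means: Dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "uorfs": {
                g: [
                    {"start_codon": u.start_codon, "start": u.interval[0],
                     "end": u.interval[1], "truncated": u.truncated}
                    for u in us
                ]
                for g, us in self.uorfs_by_gene.items()
            },
            "motif_positions": self.motif_positions,
            "peak_summits": self.peak_summits,
            "expression_weight": self.expression_weight,
            "mrna_log2fc": self.mrna_log2fc,
            "ribo_log2fc": self.ribo_log2fc,
            "psite_offsets": {str(k): v for k, v in self.psite_offsets.items()},
            "utr_occupancy_factor": self.utr_occupancy_factor,
            "gene_utr_factor": self.gene_utr_factor,
            "lifespan_means": self.lifespan_means,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------

_ACGT = np.array(list("ACGT"))
_ACT = np.array(list("ACT"))

_SAFE_CODONS = [  # {A,C,T}^3 minus the TAA stop: no G, hence no starts/other stops
    a + b + c
    for a in "ACT" for b in "ACT" for c in "ACT"
    if a + b + c != "TAA"
]
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _random_seq(rng: np.random.Generator, n: int, alphabet: np.ndarray = _ACGT) -> str:
    return "".join(alphabet[rng.integers(0, len(alphabet), size=n)])


def _scrub_motifs(seq: str, motifs: Sequence[str], rng: np.random.Generator) -> str:
    """Mutate chance occurrences of any motif (either strand) away."""
    patterns = set()
    for m in motifs:
        patterns.add(m)
        patterns.add(revcomp(m))
    chars = list(seq)
    changed = True
    while changed:
        changed = False
        s = "".join(chars)
        for pat in patterns:
            i = s.find(pat)
            if i >= 0:
                j = i + len(pat) // 2
                alt = [b for b in "ACGT" if b != chars[j]]
                chars[j] = alt[rng.integers(0, 3)]
                changed = True
                break
    return "".join(chars)


def _make_utr5(
    rng: np.random.Generator, length: int, n_uorfs: int
) -> Tuple[str, List[Tuple[str, int, int]]]:
    """A 5'UTR with exactly the planted uORFs as ORF starts.

    Returns (sequence, [(start_codon, rel_start, rel_end), ...]) with
    intervals including the stop codon, relative to the UTR 5' end.
    """
    uorfs: List[Tuple[str, int, int]] = []
    pieces: List[str] = []
    pos = 0
    remaining = length
    for _ in range(n_uorfs):
        start = START_CODONS[rng.integers(0, len(START_CODONS))]
        n_body = int(rng.integers(1, 6))
        ulen = 3 * (2 + n_body)
        # 1 nt guard before the start codon keeps junctions start-free
        gap = int(rng.integers(1, 8))
        if gap + ulen + 3 > remaining:
            break
        gap_seq = _random_seq(rng, gap, _ACT)
        gap_seq = gap_seq[:-1] + "C"  # guard base before the start codon
        body = "".join(_SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), n_body))
        pieces.append(gap_seq)
        pos += gap
        uorfs.append((start, pos, pos + ulen))
        pieces.append(start + body + "TAA")
        pos += ulen
        remaining = length - pos
    pieces.append(_random_seq(rng, length - pos, _ACT))
    return "".join(pieces), uorfs


def generate_genome_annotation(
    config: SimulationConfig,
) -> Tuple[Dict[str, str], List[TranscriptModel], GroundTruth]:
    """Lay out genes on one chromosome with planted uORFs and motifs."""
    config.validate()
    rng = substream(config.seed, "annotation")
    truth = GroundTruth(
        psite_offsets=dict(config.psite_offset_by_length),
        utr_occupancy_factor=dict(config.utr_occupancy_factor),
        gene_utr_factor=dict(config.gene_utr_factor),
        lifespan_means=dict(config.lifespan_means),
    )
    motif_by_gene: Dict[str, List[Tuple[str, int]]] = {}
    for gid, name, off in config.motif_plant_spec:
        motif_by_gene.setdefault(gid, []).append((name, off))

    blocks: List[str] = []
    transcripts: List[TranscriptModel] = []
    offset = 0
    all_motifs = list(config.motif_sequences.values())
    for gid in config.gene_ids():
        strand = "+" if rng.random() < 0.5 else "-"
        utr5_len = config.utr_len_override.get(gid, int(rng.integers(*config.utr_len_range)))
        n_uorfs = config.uorf_counts.get(
            gid, int(rng.integers(config.n_uorfs_range[0], config.n_uorfs_range[1] + 1))
        )
        n_codons = int(rng.integers(*config.cds_codon_range))
        cds_len = 3 * n_codons

        promoter = _scrub_motifs(_random_seq(rng, config.promoter_len), all_motifs, rng)
        for name, off in motif_by_gene.get(gid, []):
            # offset is measured from the CDS start; the 5'UTR sits between
            # the promoter block and the CDS, so shift by the UTR length
            motif = config.motif_sequences[name]
            p0 = config.promoter_len + utr5_len - off
            promoter = promoter[:p0] + motif + promoter[p0 + len(motif):]
        utr5, planted = _make_utr5(rng, utr5_len, n_uorfs)
        cds = "ATG" + "".join(
            _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)
        ) + "TAA"
        utr3 = _random_seq(rng, config.utr3_len)
        gap = _random_seq(rng, config.intergenic_gap)

        sense = promoter + utr5 + cds + utr3
        Lb = len(sense)
        p_iv = (0, config.promoter_len)
        u5_iv = (config.promoter_len, config.promoter_len + utr5_len)
        cds_iv = (u5_iv[1], u5_iv[1] + cds_len)
        u3_iv = (cds_iv[1], cds_iv[1] + config.utr3_len)

        def to_genomic(iv: Tuple[int, int]) -> Tuple[int, int]:
            if strand == "+":
                return (offset + iv[0], offset + iv[1])
            return (offset + Lb - iv[1], offset + Lb - iv[0])

        block_seq = sense if strand == "+" else revcomp(sense)
        blocks.append(block_seq)
        blocks.append(gap)

        t = TranscriptModel(
            gene_id=gid, chrom=CHROM, strand=strand,
            cds=to_genomic(cds_iv), utr5=to_genomic(u5_iv), utr3=to_genomic(u3_iv),
        )
        transcripts.append(t)
        truth.uorfs_by_gene[gid] = [
            UorfModel(gid, sc, (s, e), False) for sc, s, e in planted
        ]
        for name, off in motif_by_gene.get(gid, []):
            site_sense_start = config.promoter_len + utr5_len - off
            g_iv = to_genomic((site_sense_start, site_sense_start + len(config.motif_sequences[name])))
            truth.motif_positions.append(
                {"gene_id": gid, "motif": name, "upstream_offset": off,
                 "genomic_start": g_iv[0], "genomic_end": g_iv[1], "strand": strand}
            )
        offset += Lb + len(gap)

    genome = {CHROM: "".join(blocks)}
    by_id = {t.gene_id: t for t in transcripts}
    for gid, off, mult in config.chip_peak_spec:
        t = by_id[gid]
        summit = t.cds[0] - off if t.strand == "+" else t.cds[1] - 1 + off
        if not (0 <= summit < len(genome[CHROM])):
            raise ValueError(f"planted summit for {gid} outside chromosome")
        truth.peak_summits.append({"gene_id": gid, "summit": summit, "multiplier": float(mult)})

    w = np.exp(rng.normal(0.0, config.expression_sigma, size=config.n_genes))
    for i, gid in enumerate(config.gene_ids()):
        w[i] *= config.gene_expression_boost.get(gid, 1.0)
    w /= w.sum()
    truth.expression_weight = dict(zip(config.gene_ids(), map(float, w)))
    truth.mrna_log2fc, truth.ribo_log2fc = _resolve_fold_changes(config)
    truth.transcripts = transcripts
    return genome, transcripts, truth


def _resolve_fold_changes(config: SimulationConfig) -> Tuple[Dict[str, float], Dict[str, float]]:
    ids = set(config.gene_ids())

    def resolve(spec: Dict[str, float]) -> Dict[str, float]:
        out = {g: 0.0 for g in ids}
        for key, lfc in spec.items():
            members = config.gene_sets.get(key, [key] if key in ids else None)
            if members is None:
                raise ValueError(f"fold_change_spec key {key!r} is neither a set nor a gene")
            for g in members:
                out[g] = float(lfc)
        return out

    mrna = resolve(config.fold_change_spec)
    ribo = (
        resolve(config.ribo_fold_change_spec)
        if config.ribo_fold_change_spec is not None
        else dict(mrna)
    )
    return mrna, ribo


# ---------------------------------------------------------------------------
# Expression count matrices
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion < 1e-8:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    lam = rng.gamma(r, mu / r)
    return rng.poisson(lam)


def simulate_expression_counts(
    truth: GroundTruth, config: SimulationConfig
) -> Tuple[CountMatrix, CountMatrix]:
    """NB gene x sample count matrices for the mRNA and footprint assays."""
    rng = substream(config.seed, "expression")
    ids = config.gene_ids()
    w = np.array([truth.expression_weight[g] for g in ids])
    ref_cond = config.conditions[0]
    out = []
    for lfc_map in (truth.mrna_log2fc, truth.ribo_log2fc):
        lfc = np.array([lfc_map[g] for g in ids])
        cols, conds = {}, {}
        for cond in config.conditions:
            mult = np.power(2.0, lfc) if cond != ref_cond else np.ones_like(lfc)
            p = w * mult
            mu = config.library_size * p / p.sum()
            for r in range(config.n_replicates):
                sample = f"{cond}_rep{r + 1}"
                cols[sample] = _nb_draw(rng, mu, config.nb_dispersion)
                conds[sample] = cond
        df = pd.DataFrame(cols, index=pd.Index(ids, name="gene_id"))
        out.append(CountMatrix(df, conds))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Positional footprints
# ---------------------------------------------------------------------------

def simulate_footprints(
    transcripts: Sequence[TranscriptModel],
    truth: GroundTruth,
    config: SimulationConfig,
    condition: str,
    replicate: int = 1,
    n_reads: Optional[int] = None,
) -> PositionalCounts:
    """One library of footprint 5'-end counts with planted P-site geometry.

    Footprint 5' ends are placed so that 5'end + offset(length) lands on
    a codon frame-0 position with probability ``frame_purity`` (the rest
    split over frames 1/2). 5'UTR density is the CDS per-nt density
    scaled by ``utr_base_density`` times the condition's occupancy factor
    (times any per-gene factor in non-reference conditions); a
    ``uorf_share`` fraction of UTR mass falls in the uORF union.
    """
    if condition not in config.utr_occupancy_factor:
        raise ValueError(f"no utr_occupancy_factor for condition {condition!r}")
    lengths = sorted(config.psite_offset_by_length)
    if not lengths:
        raise ValueError("psite_offset_by_length is empty")
    rng = substream(config.seed, "footprints", condition, replicate)
    n_reads = int(n_reads if n_reads is not None else config.footprint_reads)
    cond_factor = config.utr_occupancy_factor[condition]
    ref_cond = config.conditions[0]

    if config.length_probs:
        lp = np.array([config.length_probs.get(L, 0.0) for L in lengths], dtype=float)
        lp /= lp.sum()
    else:
        lp = np.full(len(lengths), 1.0 / len(lengths))
    offsets = np.array([config.psite_offset_by_length[L] for L in lengths])

    ids = [t.gene_id for t in transcripts]
    w = np.array([truth.expression_weight[g] for g in ids])
    ribo_lfc = np.array([truth.ribo_log2fc[g] for g in ids])
    expr = w * (np.power(2.0, ribo_lfc) if condition != ref_cond else 1.0)
    cds_mass = np.array([t.cds_len for t in transcripts], dtype=float)
    gene_f = np.array(
        [
            config.gene_utr_factor.get(g, 1.0) if condition != ref_cond else 1.0
            for g in ids
        ]
    )
    utr_mass = (
        np.array([t.utr5_len for t in transcripts], dtype=float)
        * config.utr_base_density * cond_factor * gene_f
    )
    gene_mass = expr * (cds_mass + utr_mass)
    n_per_gene = rng.multinomial(n_reads, gene_mass / gene_mass.sum())

    frame_p = np.array(
        [config.frame_purity, (1 - config.frame_purity) / 2, (1 - config.frame_purity) / 2]
    )
    rows_pos: List[np.ndarray] = []
    rows_len: List[np.ndarray] = []
    strands: List[str] = []
    chroms: List[str] = []
    for gi, t in enumerate(transcripts):
        n_g = int(n_per_gene[gi])
        if n_g == 0:
            continue
        p_utr = utr_mass[gi] / (utr_mass[gi] + cds_mass[gi])
        n_utr = rng.binomial(n_g, p_utr)
        n_cds = n_g - n_utr
        tx_pos = []
        if n_cds:
            codons = rng.integers(0, t.cds_len // 3, size=n_cds)
            # initiation peak: a fixed share of CDS footprints at codon 0
            codons[rng.random(n_cds) < config.start_codon_boost] = 0
            frames = rng.choice(3, size=n_cds, p=frame_p)
            cds_rel = codons * 3 + frames
            if t.strand == "+":
                tx_pos.append(t.cds[0] + cds_rel)
            else:
                tx_pos.append(t.cds[1] - 1 - cds_rel)
        if n_utr:
            utr_rel = _sample_utr_positions(
                rng, t, truth.uorfs_by_gene.get(t.gene_id, []), n_utr,
                config.uorf_share, frame_p,
            )
            if t.strand == "+":
                tx_pos.append(t.utr5[0] + utr_rel)
            else:
                tx_pos.append(t.utr5[1] - 1 - utr_rel)
        psites = np.concatenate(tx_pos)
        li = rng.choice(len(lengths), size=n_g, p=lp)
        d = offsets[li]
        five_prime = psites - d if t.strand == "+" else psites + d
        rows_pos.append(five_prime)
        rows_len.append(np.array(lengths)[li])
        strands.append(t.strand)
        chroms.append(t.chrom)

    frames_df = pd.DataFrame(
        {
            "chrom": np.repeat(chroms, [len(x) for x in rows_pos]),
            "pos": np.concatenate(rows_pos),
            "strand": np.repeat(strands, [len(x) for x in rows_pos]),
            "length": np.concatenate(rows_len),
        }
    )
    agg = (
        frames_df.groupby(["chrom", "pos", "strand", "length"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    lib_id = f"{condition}_rep{replicate}"
    return PositionalCounts(lib_id, agg[POSITIONAL_COLUMNS])


def _sample_utr_positions(
    rng: np.random.Generator,
    t: TranscriptModel,
    uorfs: List[UorfModel],
    n: int,
    uorf_share: float,
    frame_p: np.ndarray,
) -> np.ndarray:
    """Transcript-relative positions within the 5'UTR (0 = UTR 5' end)."""
    utr_len = t.utr5_len
    if not uorfs:
        return rng.integers(0, utr_len, size=n)
    n_in = rng.binomial(n, uorf_share)
    out = [rng.integers(0, utr_len, size=n - n_in)]
    if n_in:
        lens = np.array([u.interval[1] - u.interval[0] for u in uorfs], dtype=float)
        ui = rng.choice(len(uorfs), size=n_in, p=lens / lens.sum())
        starts = np.array([u.interval[0] for u in uorfs])
        ncod = (lens // 3).astype(int)
        codons = (rng.random(n_in) * ncod[ui]).astype(int)
        frames = rng.choice(3, size=n_in, p=frame_p)
        pos = starts[ui] + codons * 3 + frames
        out.append(np.minimum(pos, utr_len - 1))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# ChIP coverage
# ---------------------------------------------------------------------------

def simulate_chip_coverage(
    genome: Dict[str, str], truth: GroundTruth, config: SimulationConfig
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """(ChIP, input) per-base coverage with Gaussian bumps at planted summits."""
    rng = substream(config.seed, "chip")
    chip: Dict[str, np.ndarray] = {}
    inp: Dict[str, np.ndarray] = {}
    for chrom, seq in genome.items():
        L = len(seq)
        base = rng.poisson(config.chip_base_depth, size=L).astype(float)
        kernel = np.ones(51) / 51.0
        inp[chrom] = np.convolve(base, kernel, mode="same")
        signal = np.ones(L)
        x = np.arange(L, dtype=float)
        for rec in truth.peak_summits:
            s = rec["summit"]
            lo, hi = max(0, s - 600), min(L, s + 600)
            signal[lo:hi] += rec["multiplier"] * np.exp(
                -((x[lo:hi] - s) ** 2) / (2 * config.chip_peak_sd ** 2)
            )
        chip[chrom] = rng.poisson(config.chip_base_depth * signal).astype(float)
    return chip, inp


# ---------------------------------------------------------------------------
# Lifespan
# ---------------------------------------------------------------------------

def simulate_lifespan(config: SimulationConfig) -> pd.DataFrame:
    """Per-cell division counts per strain (discretized gamma)."""
    rng = substream(config.seed, "lifespan")
    rows = []
    for strain in sorted(config.lifespan_means):
        mean = config.lifespan_means[strain]
        n = int(config.lifespan_n[strain]) if isinstance(config.lifespan_n, dict) else int(config.lifespan_n)
        draws = rng.gamma(config.lifespan_shape, mean / config.lifespan_shape, size=n)
        divisions = np.maximum(np.rint(draws).astype(int), 0)
        for i, d in enumerate(divisions):
            rows.append({"strain": strain, "cell_id": f"{strain}_{i + 1}", "divisions": int(d)})
    return pd.DataFrame(rows, columns=["strain", "cell_id", "divisions"])


# ---------------------------------------------------------------------------
# Full input bundle
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Write every pipeline input (plus ground truth) into ``outdir``."""
    from .chip import write_bedgraph  # local import to avoid a cycle
    from .genesets import GeneSet, write_gmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, transcripts, truth = generate_genome_annotation(config)
    write_fasta(genome, outdir / "genome.fa")
    write_annotation(transcripts, outdir / "annotation.gff3")

    mrna, ribo = simulate_expression_counts(truth, config)
    mrna.to_tsv(outdir / "mrna_counts.tsv")
    ribo.to_tsv(outdir / "ribo_counts.tsv")

    for cond in config.conditions:
        for r in range(1, config.n_replicates + 1):
            fp = simulate_footprints(transcripts, truth, config, cond, r)
            fp.to_tsv(outdir / f"footprints_{cond}_rep{r}.tsv")

    chip, inp = simulate_chip_coverage(genome, truth, config)
    write_bedgraph(chip, outdir / "chip.bedgraph")
    write_bedgraph(inp, outdir / "input.bedgraph")

    simulate_lifespan(config).to_csv(outdir / "lifespan.tsv", sep="\t", index=False)

    if config.gene_sets:
        write_gmt(
            [GeneSet(k, k, list(v)) for k, v in config.gene_sets.items()],
            outdir / "gene_sets.gmt",
        )
    truth.to_json(outdir / "ground_truth.json")
    return truth
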