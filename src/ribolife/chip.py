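"""ChIP enrichment, promoter target assignment and PWM motif scoring.

Peaks are called with a windowed Poisson enrichment test of ChIP over
depth-scaled input coverage (a deliberately simple caller; externally
called peaks can be imported as narrowPeak/BED and used instead). Peak
summits falling inside exactly one 1-kb promoter window define unique
gene targets; summits shared by divergent promoters are ambiguous and
excluded. Promoters are scored with position weight matrices as the
maximum log-odds site score over all windows on both strands
(Patser-style max-site promoter score).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import PromoterWindow, TranscriptModel, promoter_sequence, revcomp

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_INDEX["N"] = 4


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    enrichment: float
    assigned_gene: Optional[str] = None
    ambiguity: str = "unassigned"  # unique | ambiguous | unassigned

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError("summit must lie within the peak interval")
        if self.enrichment <= 0:
            raise ValueError("enrichment must be positive")


# ---------------------------------------------------------------------------
# Coverage I/O
# ---------------------------------------------------------------------------

def write_bedgraph(tracks: Dict[str, np.ndarray], path: str | Path) -> None:
    """Run-length-encoded bedGraph (0-based half-open)."""
    frames = []
    for chrom in sorted(tracks):
        vals = np.asarray(tracks[chrom], dtype=float)
        if vals.size == 0:
            continue
        change = np.flatnonzero(np.diff(vals)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(vals)]])
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "value": vals[starts]}
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", header=False, index=False, float_format="%g")


def read_bedgraph(
    path: str | Path, chrom_lengths: Optional[Dict[str, int]] = None
) -> Dict[str, np.ndarray]:
    """Expand a bedGraph into per-base float arrays."""
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "value"], comment="#")
    out: Dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom"):
        L = int(sub["end"].max())
        if chrom_lengths and chrom in chrom_lengths:
            L = max(L, chrom_lengths[chrom])
        arr = np.zeros(L)
        order = np.argsort(sub["start"].to_numpy(), kind="mergesort")
        s = sub["start"].to_numpy()[order]
        e = sub["end"].to_numpy()[order]
        v = sub["value"].to_numpy(dtype=float)[order]
        if s[0] == 0 and e[-1] == L and (s[1:] == e[:-1]).all():
            arr = np.repeat(v, e - s)  # contiguous cover: fully vectorized
        else:
            for a, b, val in zip(s, e, v):
                arr[a:b] = val
        out[str(chrom)] = arr
    return out


# ---------------------------------------------------------------------------
# Peak calling and assignment
# ---------------------------------------------------------------------------

def call_peaks(
    chip: Dict[str, np.ndarray],
    control: Dict[str, np.ndarray],
    window: int = 150,
    step: int = 25,
    min_fold: float = 4.0,
    min_pois_p: float = 1e-5,
) -> List[Peak]:
    """Windowed Poisson enrichment peak caller.

    Sliding windows where the ChIP count exceeds ``min_fold`` times the
    depth-scaled input expectation AND the Poisson upper-tail p-value is
    below ``min_pois_p`` are merged when overlapping; the summit is the
    position of maximal ChIP-minus-scaled-input within the merged region.
    """
    if set(chip) != set(control):
        raise ValueError("chip and input tracks cover different chromosomes")
    chip_total = sum(float(np.sum(v)) for v in chip.values())
    ctrl_total = sum(float(np.sum(v)) for v in control.values())
    if ctrl_total <= 0:
        raise ValueError("zero-depth input track")
    scale = chip_total / ctrl_total
    peaks: List[Peak] = []
    for chrom in sorted(chip):
        c = np.asarray(chip[chrom], dtype=float)
        b = np.asarray(control[chrom], dtype=float) * scale
        if len(c) != len(b):
            raise ValueError(f"track length mismatch on {chrom}")
        L = len(c)
        if L < window:
            continue
        csum_c = np.concatenate([[0.0], np.cumsum(c)])
        csum_b = np.concatenate([[0.0], np.cumsum(b)])
        starts = np.arange(0, L - window + 1, step)
        wc = csum_c[starts + window] - csum_c[starts]
        wb = np.maximum(csum_b[starts + window] - csum_b[starts], 1e-9)
        pvals = sps.poisson.sf(wc - 1, wb)
        sig = (wc > min_fold * wb) & (pvals < min_pois_p)
        if not sig.any():
            continue
        # smooth the enrichment profile before summit localization; raw
        # per-base Poisson noise would scatter the argmax tens of nt
        k = np.exp(-0.5 * (np.arange(-75, 76) / 25.0) ** 2)
        diff = np.convolve(c - b, k / k.sum(), mode="same")
        # merge overlapping significant windows into regions
        region_start = None
        region_end = None
        for s in starts[sig]:
            if region_start is None:
                region_start, region_end = s, s + window
            elif s <= region_end:
                region_end = s + window
            else:
                peaks.append(_make_peak(chrom, region_start, region_end, diff, csum_c, csum_b))
                region_start, region_end = s, s + window
        peaks.append(_make_peak(chrom, region_start, region_end, diff, csum_c, csum_b))
    return peaks


def _make_peak(
    chrom: str, start: int, end: int, diff: np.ndarray,
    csum_c: np.ndarray, csum_b: np.ndarray,
) -> Peak:
    summit = start + int(np.argmax(diff[start:end]))
    obs = csum_c[end] - csum_c[start]
    exp = max(csum_b[end] - csum_b[start], 1e-9)
    return Peak(chrom, int(start), int(end), summit, float(obs / exp))


def assign_peaks_to_genes(
    peaks: Sequence[Peak], promoters: Sequence[PromoterWindow]
) -> Tuple[List[Peak], List[str]]:
    """Assign each peak summit to the promoter window(s) containing it.

    A summit in exactly one window yields a unique target; in two or
    more (divergent promoters) the peak is ambiguous and excluded from
    the target list; in none it stays unassigned.
    """
    targets: List[str] = []
    for p in peaks:
        hits = [
            w.gene_id
            for w in promoters
            if w.chrom == p.chrom and w.interval[0] <= p.summit < w.interval[1]
        ]
        if len(hits) == 1:
            p.assigned_gene, p.ambiguity = hits[0], "unique"
            targets.append(hits[0])
        elif len(hits) > 1:
            p.assigned_gene, p.ambiguity = None, "ambiguous"
        else:
            p.assigned_gene, p.ambiguity = None, "unassigned"
    return list(peaks), targets


def summit_distance_to_start(peak: Peak, gene: TranscriptModel) -> int:
    """Signed summit-to-CDS-start distance in nt (positive = upstream)."""
    if gene.strand == "+":
        return gene.cds[0] - peak.summit
    return peak.summit - gene.cds[1]


# ---------------------------------------------------------------------------
# narrowPeak import/export
# ---------------------------------------------------------------------------

def read_narrowpeak(path: str | Path) -> List[Peak]:
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "signalValue", "pValue", "qValue", "peak"]
    df = pd.read_csv(path, sep="\t", names=cols)
    out = []
    for _, r in df.iterrows():
        offset = int(r["peak"]) if int(r["peak"]) >= 0 else (int(r["end"]) - int(r["start"])) // 2
        out.append(
            Peak(str(r["chrom"]), int(r["start"]), int(r["end"]),
                 int(r["start"]) + offset, max(float(r["signalValue"]), 1e-9))
        )
    return out


def write_narrowpeak(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i + 1}\t0\t.\t"
                f"{p.enrichment:.4f}\t-1\t-1\t{p.summit - p.start}\n"
            )


# ---------------------------------------------------------------------------
# PWM scoring
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """Position frequency matrix over {A,C,G,T} with log-odds scoring.

    ``freqs`` has shape (4, K) in base order A,C,G,T; columns are
    renormalized to sum to 1 after adding ``pseudocount``. The site score
    is sum_i log2(f[w_i, i] / bg[w_i]); N bases contribute the
    background-weighted mean, which is 0 for normalized columns.
    """

    motif_id: str
    freqs: np.ndarray
    pseudocount: float = 0.01
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape[0] != 4:
            raise ValueError("freqs must be 4 x K (A,C,G,T rows)")
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,) or (self.background <= 0).any():
            raise ValueError("background must be 4 positive values")
        self.background = self.background / self.background.sum()
        f = self.freqs + self.pseudocount
        self.freqs = f / f.sum(axis=0, keepdims=True)

    @property
    def length(self) -> int:
        return self.freqs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """5 x K matrix (A,C,G,T,N rows) of log2 odds."""
        lo = np.log2(self.freqs / self.background[:, None])
        n_row = np.zeros((1, self.length))  # sum_b bg_b * f/bg = sum f = 1
        return np.vstack([lo, n_row])

    @property
    def max_score(self) -> float:
        return float(np.log2(self.freqs / self.background[:, None]).max(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        rc = PWM.__new__(PWM)
        rc.motif_id = self.motif_id
        rc.pseudocount = self.pseudocount
        rc.background = self.background[::-1] / self.background[::-1].sum()
        rc.freqs = self.freqs[::-1, ::-1]
        return rc

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=0))


@dataclass
class MotifHit:
    motif_id: str
    score: float
    position: int  # window start within the scanned sequence
    strand: str
    gene_id: Optional[str] = None


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, 4) for b in seq.upper()], dtype=np.int8)


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    K = log_odds.shape[1]
    n = len(codes) - K + 1
    if n <= 0:
        return np.array([])
    scores = np.zeros(n)
    for i in range(K):
        scores += log_odds[codes[i: n + i], i]
    return scores


def scan_pwm(seq: str, pwm: PWM) -> MotifHit:
    """Best-scoring PWM site over all windows on both strands.

    A window on the minus strand is scored on the reverse complement of
    the subsequence. Ties break to the leftmost position, then to the
    plus strand.
    """
    if len(seq) < pwm.length:
        raise ValueError("sequence shorter than the motif")
    codes = _encode(seq)
    lo = pwm.log_odds
    fwd = _window_scores(codes, lo)
    # minus-strand window at w == scoring the revcomp PWM on the forward seq
    rc_lo = np.vstack([pwm.log_odds[:4][::-1, ::-1], np.zeros((1, pwm.length))])
    rev = _window_scores(codes, rc_lo)
    best = None
    for strand, scores in (("+", fwd), ("-", rev)):
        w = int(np.argmax(scores))
        cand = (scores[w], -w, 0 if strand == "+" else -1, strand)
        if best is None or cand[:3] > best[:3]:
            best = cand
    score, neg_w, _, strand = best
    return MotifHit(pwm.motif_id, float(score), -neg_w, strand)


def promoter_motif_hit(
    gene: TranscriptModel,
    window: PromoterWindow,
    genome: Dict[str, str],
    pwm: PWM,
) -> MotifHit:
    """Max-site hit in a gene's promoter, positioned relative to CDS start.

    The promoter is scanned in sense orientation; the hit position is
    the site start relative to the CDS start (negative = upstream).
    """
    seq = promoter_sequence(window, genome)
    hit = scan_pwm(seq, pwm)
    hit.position = hit.position - len(seq)
    hit.gene_id = gene.gene_id
    return hit


def classify_configuration(
    gcn4_hit: Optional[MotifHit],
    rap1_hit: Optional[MotifHit],
    gcn4_threshold: float,
    rap1_threshold: float,
) -> str:
    """Relative order of the best Gcn4 and Rap1 sites in a promoter.

    A hit counts as present when its score reaches the per-motif
    threshold. Positions are CDS-start-relative (negative upstream); the
    site with the more negative position is upstream of the other.
    """
    has_gcn4 = gcn4_hit is not None and gcn4_hit.score >= gcn4_threshold
    has_rap1 = rap1_hit is not None and rap1_hit.score >= rap1_threshold
    if has_gcn4 and has_rap1:
        if rap1_hit.position < gcn4_hit.position:
            return "rap1_upstream_of_gcn4"
        return "gcn4_upstream_of_rap1"
    if has_gcn4 or has_rap1:
        return "single"
    return "none"


def default_hit_threshold(pwm: PWM, fraction: float = 0.6) -> float:
    """Presence cutoff: a fraction of the maximum achievable score."""
    return fraction * pwm.max_score


# ---------------------------------------------------------------------------
# PWM file formats
# ---------------------------------------------------------------------------

def read_pwm_tab(path: str | Path, motif_id: Optional[str] = None,
                 pseudocount: float = 0.0) -> PWM:
    """Plain tab format: 4 rows labelled A/C/G/T, one column per position.

    Files written by :func:`write_pwm_tab` hold already-normalized
    frequencies, so no pseudocount is added by default; pass one when
    reading raw count/frequency matrices that may contain zeros.
    """
    rows: Dict[str, List[float]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0].rstrip(":|") in BASES:
                rows[parts[0].rstrip(":|")] = [float(x) for x in parts[1:]]
    if set(rows) != set(BASES):
        raise ValueError(f"expected A/C/G/T rows in {path}")
    mat = np.array([rows[b] for b in BASES])
    return PWM(motif_id or Path(path).stem, mat, pseudocount=pseudocount)


def write_pwm_tab(pwm: PWM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# motif {pwm.motif_id}\n")
        for i, b in enumerate(BASES):
            fh.write(b + "\t" + "\t".join(f"{v:.6f}" for v in pwm.freqs[i]) + "\n")


def read_pwm_meme(path: str | Path, pseudocount: float = 0.0) -> List[PWM]:
    """MEME minimal motif format (letter-probability matrices)."""
    pwms: List[PWM] = []
    name = None
    rows: List[List[float]] = []
    in_matrix = False

    def flush():
        nonlocal rows, name, in_matrix
        if name is not None and rows:
            mat = np.array(rows).T  # rows are positions x ACGT
            pwms.append(PWM(name, mat, pseudocount=pseudocount))
        rows, in_matrix = [], False

    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.startswith("MOTIF"):
                flush()
                name = s.split()[1]
            elif s.startswith("letter-probability"):
                in_matrix = True
            elif in_matrix:
                parts = s.split()
                if len(parts) == 4:
                    rows.append([float(x) for x in parts])
                else:
                    in_matrix = False
    flush()
    if not pwms:
        raise ValueError(f"no motifs found in {path}")
    return pwms


def pwm_from_consensus(motif_id: str, consensus: str, weight: float = 0.94,
                       pseudocount: float = 0.01) -> PWM:
    """A sharply peaked PWM from a consensus string (synthetic motifs)."""
    K = len(consensus)
    mat = np.full((4, K), (1 - weight) / 3)
    for i, b in enumerate(consensus.upper()):
        mat[_BASE_INDEX[b], i] = weight
    return PWM(motif_id, mat, pseudocount=pseudocount)
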