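"""Ribosome footprint P-site calibration and region counting.

A footprint's P-site is its 5' end plus a read-length-specific offset.
Per length, the offset is chosen as the candidate that places the most
P-sites exactly on annotated start codons; the length is accepted only
when the in-CDS P-sites show 3-nt periodicity (frame 0 strictly larger
than frames 1 and 2). Accepted-length P-sites are then counted into
5'UTR / CDS / uORF regions per gene, with positions shared by
same-strand overlapping genes discarded (the region-level analogue of
counting uniquely mapped reads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, UorfModel, uorf_genomic_interval

logger = logging.getLogger(__name__)

POSITIONAL_COLUMNS = ["chrom", "pos", "strand", "length", "count"]


@dataclass
class PositionalCounts:
    """Sparse per-(chrom, 5'-end position, strand, read length) counts.

    For minus-strand reads ``pos`` is the rightmost genomic coordinate
    (the biological 5' end).
    """

    library_id: str
    df: pd.DataFrame  # columns: chrom, pos, strand, length, count

    def __post_init__(self) -> None:
        missing = set(POSITIONAL_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (self.df["count"] < 1).any():
            raise ValueError("counts must be >= 1")

    @property
    def total(self) -> int:
        return int(self.df["count"].sum())

    def to_tsv(self, path: str | Path) -> None:
        self.df[POSITIONAL_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, library_id: Optional[str] = None) -> "PositionalCounts":
        df = pd.read_csv(path, sep="\t")
        return cls(library_id or Path(path).stem, df)


@dataclass
class PsiteCalibration:
    """Calibration result for one read length."""

    length: int
    offset: Optional[int]
    frame_fractions: Tuple[float, float, float]
    accepted: bool
    reason: str = ""

    def __post_init__(self) -> None:
        f = self.frame_fractions
        if self.offset is not None and abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("frame fractions must sum to 1")


CalibrationSet = Dict[int, PsiteCalibration]


def calibration_to_frame(calib: CalibrationSet) -> pd.DataFrame:
    rows = [
        {
            "length": c.length,
            "offset": c.offset,
            "f0": c.frame_fractions[0],
            "f1": c.frame_fractions[1],
            "f2": c.frame_fractions[2],
            "accepted": c.accepted,
            "reason": c.reason,
        }
        for c in sorted(calib.values(), key=lambda c: c.length)
    ]
    return pd.DataFrame(rows)


def _psite_positions(df: pd.DataFrame, offset: int) -> np.ndarray:
    """P-site genomic coordinate: 5'end + offset (+) / 5'end - offset (-)."""
    sign = np.where(df["strand"].to_numpy() == "+", 1, -1)
    return df["pos"].to_numpy() + sign * offset


class _GenomeIndex:
    """Per-(chrom, strand) base-resolution lookup of gene regions.

    Positions covered by two same-strand genes are marked ambiguous and
    excluded from all counting.
    """

    NONE, AMBIG = -1, -2
    R_NONE, R_UTR5, R_CDS = 0, 1, 2

    def __init__(
        self,
        genes: Sequence[TranscriptModel],
        uorfs_by_gene: Optional[Dict[str, List[UorfModel]]] = None,
    ):
        if not genes:
            raise ValueError("empty annotation")
        self.genes = list(genes)
        self.gene_ids = [g.gene_id for g in self.genes]
        lengths: Dict[str, int] = {}
        for g in self.genes:
            hi = max(g.cds[1], (g.utr5 or g.cds)[1], (g.utr3 or g.cds)[1])
            lengths[g.chrom] = max(lengths.get(g.chrom, 0), hi + 1)
        self.gene_at: Dict[Tuple[str, str], np.ndarray] = {}
        self.region_at: Dict[Tuple[str, str], np.ndarray] = {}
        self.in_uorf: Dict[Tuple[str, str], np.ndarray] = {}
        for chrom, L in lengths.items():
            for strand in "+-":
                key = (chrom, strand)
                self.gene_at[key] = np.full(L, self.NONE, dtype=np.int32)
                self.region_at[key] = np.zeros(L, dtype=np.int8)
                self.in_uorf[key] = np.zeros(L, dtype=bool)
        for gi, g in enumerate(self.genes):
            key = (g.chrom, g.strand)
            garr, rarr = self.gene_at[key], self.region_at[key]
            for iv, rcode in ((g.utr5, self.R_UTR5), (g.cds, self.R_CDS)):
                if iv is None:
                    continue
                s, e = iv
                seg = garr[s:e]
                clash = seg != self.NONE
                seg[~clash] = gi
                seg[clash] = self.AMBIG
                rarr[s:e][~clash] = rcode
                rarr[s:e][clash] = self.R_NONE
            if uorfs_by_gene:
                for u in uorfs_by_gene.get(g.gene_id, []):
                    us, ue = uorf_genomic_interval(g, u)
                    self.in_uorf[key][us:ue] = True

    def lookup(self, chrom: str, strand: str, pos: np.ndarray):
        key = (chrom, strand)
        if key not in self.gene_at:
            n = len(pos)
            return (
                np.full(n, self.NONE, dtype=np.int32),
                np.zeros(n, dtype=np.int8),
                np.zeros(n, dtype=bool),
            )
        garr = self.gene_at[key]
        valid = (pos >= 0) & (pos < len(garr))
        gid = np.full(len(pos), self.NONE, dtype=np.int32)
        reg = np.zeros(len(pos), dtype=np.int8)
        uo = np.zeros(len(pos), dtype=bool)
        pv = pos[valid]
        gid[valid] = garr[pv]
        reg[valid] = self.region_at[key][pv]
        uo[valid] = self.in_uorf[key][pv]
        return gid, reg, uo


def infer_psite_offsets(
    fp: PositionalCounts,
    genes: Sequence[TranscriptModel],
    candidate_offsets: Iterable[int] = range(9, 16),
    min_start_reads: int = 500,
) -> CalibrationSet:
    """Infer per-length P-site offsets from start-codon alignment.

    For each read length the offset is the candidate maximizing the
    number of reads whose P-site lands exactly on an annotated CDS start
    (ties: smallest offset). Frame fractions are then computed over all
    CDS-internal P-sites; the length is accepted iff frame 0 strictly
    dominates both other frames. Lengths with fewer than
    ``min_start_reads`` start-proximal footprints are left uncalibrated.
    """
    if not genes:
        raise ValueError("empty annotation")
    candidates = sorted(set(int(d) for d in candidate_offsets))
    starts: Dict[Tuple[str, str], set] = {}
    for g in genes:
        starts.setdefault((g.chrom, g.strand), set()).add(g.cds_start_genomic)
    start_sets = {k: np.array(sorted(v)) for k, v in starts.items()}
    index = _GenomeIndex(genes)

    out: CalibrationSet = {}
    for length, sub in fp.df.groupby("length"):
        counts = sub["count"].to_numpy()
        hit_by_offset = {}
        for d in candidates:
            psites = _psite_positions(sub, d)
            hits = np.zeros(len(sub), dtype=bool)
            for (chrom, strand), arr in start_sets.items():
                sel = (sub["chrom"].to_numpy() == chrom) & (sub["strand"].to_numpy() == strand)
                if sel.any():
                    idx = np.searchsorted(arr, psites[sel])
                    idx = np.clip(idx, 0, len(arr) - 1)
                    hits[sel] = arr[idx] == psites[sel]
            hit_by_offset[d] = counts[hits].sum()
        near_start_total = int(sum(hit_by_offset.values()))
        if near_start_total < min_start_reads:
            out[int(length)] = PsiteCalibration(
                int(length), None, (0.0, 0.0, 0.0), False, "insufficient data"
            )
            continue
        best = max(candidates, key=lambda d: (hit_by_offset[d], -d))
        frames = _frame_fractions(sub, best, index)
        f0, f1, f2 = frames
        accepted = f0 > f1 and f0 > f2
        out[int(length)] = PsiteCalibration(
            int(length), best, frames, accepted,
            "" if accepted else "no 3-nt periodicity",
        )
    return out


FRAME_START_MARGIN = 15  # nt of CDS 5' end excluded from periodicity stats


def _frame_fractions(
    sub: pd.DataFrame, offset: int, index: _GenomeIndex
) -> Tuple[float, float, float]:
    """Frame fractions over CDS-internal P-sites.

    The first ``FRAME_START_MARGIN`` nt of each CDS are excluded: the
    initiation pileup otherwise leaks asymmetrically across frames when
    candidate offsets are shifted against the true one.
    """
    psites = _psite_positions(sub, offset)
    counts = sub["count"].to_numpy()
    frame_counts = np.zeros(3)
    for (chrom, strand), _ in index.gene_at.items():
        sel = (sub["chrom"].to_numpy() == chrom) & (sub["strand"].to_numpy() == strand)
        if not sel.any():
            continue
        gid, reg, _ = index.lookup(chrom, strand, psites[sel])
        in_cds = (reg == _GenomeIndex.R_CDS) & (gid >= 0)
        if not in_cds.any():
            continue
        pv = psites[sel][in_cds]
        cv = counts[sel][in_cds]
        gv = gid[in_cds]
        for gi in np.unique(gv):
            g = index.genes[gi]
            pp = pv[gv == gi]
            cc = cv[gv == gi]
            rel = pp - g.cds[0] if g.strand == "+" else g.cds[1] - 1 - pp
            keep = rel >= FRAME_START_MARGIN
            np.add.at(frame_counts, rel[keep] % 3, cc[keep])
    total = frame_counts.sum()
    if total == 0:
        return (0.0, 0.0, 0.0)
    f = frame_counts / total
    return (float(f[0]), float(f[1]), float(f[2]))


REGION_COLUMNS = [
    "utr5_raw", "cds_raw", "uorf_raw", "utr5_norm", "cds_norm", "uorf_norm",
]


def count_regions(
    fp: PositionalCounts,
    calib: CalibrationSet,
    genes: Sequence[TranscriptModel],
    uorfs_by_gene: Optional[Dict[str, List[UorfModel]]] = None,
) -> pd.DataFrame:
    """Count accepted-length P-sites into per-gene 5'UTR/CDS/uORF regions.

    Normalized columns are counts per million accepted-length footprints
    in the library. A P-site inside the uORF union also increments the
    5'UTR count (uORFs lie within the 5'UTR).
    """
    accepted = {L: c.offset for L, c in calib.items() if c.accepted}
    if not accepted:
        raise ValueError("no accepted read length in calibration")
    for L in fp.df["length"].unique():
        if int(L) not in calib:
            raise RuntimeError(f"no calibration entry for present read length {L}")
    index = _GenomeIndex(genes, uorfs_by_gene)
    n_genes = len(index.genes)
    utr5 = np.zeros(n_genes)
    cds = np.zeros(n_genes)
    uorf = np.zeros(n_genes)
    library_total = 0
    for length, sub in fp.df.groupby("length"):
        if int(length) not in accepted:
            continue
        library_total += int(sub["count"].sum())
        psites = _psite_positions(sub, accepted[int(length)])
        counts = sub["count"].to_numpy()
        for (chrom, strand) in {(c, s) for c, s in zip(sub["chrom"], sub["strand"])}:
            sel = (sub["chrom"].to_numpy() == chrom) & (sub["strand"].to_numpy() == strand)
            gid, reg, uo = index.lookup(chrom, strand, psites[sel])
            cv = counts[sel]
            ok = gid >= 0
            np.add.at(utr5, gid[ok & (reg == _GenomeIndex.R_UTR5)],
                      cv[ok & (reg == _GenomeIndex.R_UTR5)])
            np.add.at(cds, gid[ok & (reg == _GenomeIndex.R_CDS)],
                      cv[ok & (reg == _GenomeIndex.R_CDS)])
            in_uorf = ok & (reg == _GenomeIndex.R_UTR5) & uo
            np.add.at(uorf, gid[in_uorf], cv[in_uorf])
    scale = 1e6 / library_total if library_total else 0.0
    df = pd.DataFrame(
        {
            "utr5_raw": utr5,
            "cds_raw": cds,
            "uorf_raw": uorf,
            "utr5_norm": utr5 * scale,
            "cds_norm": cds * scale,
            "uorf_norm": uorf * scale,
        },
        index=pd.Index(index.gene_ids, name="gene_id"),
    )
    df.attrs["library_id"] = fp.library_id
    df.attrs["library_total"] = library_total
    return df


def aggregate_replicates(region_counts: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Sum raw and library-normalized region counts across replicates."""
    if not region_counts:
        raise ValueError("no replicates to aggregate")
    out = region_counts[0][REGION_COLUMNS].copy()
    for rc in region_counts[1:]:
        if not rc.index.equals(out.index):
            rc = rc.reindex(out.index, fill_value=0.0)
        out = out + rc[REGION_COLUMNS]
    return out
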