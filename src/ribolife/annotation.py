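"""Genome / transcript annotation handling.

Yeast-style single-exon transcript models: a CDS flanked by optional
5'/3' UTRs on one chromosome. All coordinates are 0-based half-open
internally; GFF3 I/O converts from/to the 1-based inclusive convention,
BED export stays 0-based half-open.

Beyond parsing, this module derives the two annotation products the
downstream analyses need: fixed-width promoter windows upstream of CDS
starts (used for ChIP peak assignment and motif scanning) and candidate
upstream open reading frames (uORFs) in 5'UTRs, defined as ORFs starting
with ATG, GTG or TTG and running to the first in-frame stop codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


Interval = Tuple[int, int]  # half-open [start, end)


class AnnotationError(ValueError):
    """Raised on malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class TranscriptModel:
    """One gene's genomic layout.

    ``utr5``/``utr3`` are ``None`` for genes without annotated UTRs.
    On the minus strand the 5'UTR lies to the *right* of the CDS in
    genomic coordinates.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    cds: Interval
    utr5: Optional[Interval] = None
    utr3: Optional[Interval] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        s, e = self.cds
        if e <= s:
            raise AnnotationError(f"{self.gene_id}: empty CDS {self.cds}")

    @property
    def cds_len(self) -> int:
        return self.cds[1] - self.cds[0]

    @property
    def utr5_len(self) -> int:
        return 0 if self.utr5 is None else self.utr5[1] - self.utr5[0]

    @property
    def cds_start_genomic(self) -> int:
        """Genomic coordinate of the first base of the start codon."""
        return self.cds[0] if self.strand == "+" else self.cds[1] - 1


@dataclass(frozen=True)
class UorfModel:
    """A candidate upstream ORF, in transcript-relative 5'UTR coordinates.

    ``interval`` is half-open relative to the 5'UTR start (position 0 =
    first UTR base in transcript orientation) and includes the stop codon
    when one was found. ``truncated`` marks candidates whose first
    in-frame stop lies beyond the UTR end (the ORF continues into the
    main CDS) or whose extension hit an ambiguous (N) codon.
    """

    parent_gene: str
    start_codon: str
    interval: Interval
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.start_codon not in START_CODONS:
            raise AnnotationError(f"bad start codon {self.start_codon!r}")
        if self.interval[0] < 0 or self.interval[1] <= self.interval[0]:
            raise AnnotationError(f"bad uORF interval {self.interval}")
        if not self.truncated and (self.interval[1] - self.interval[0]) % 3 != 0:
            raise AnnotationError("non-truncated uORF length must be divisible by 3")


@dataclass(frozen=True)
class PromoterWindow:
    """The W nucleotides upstream of a CDS start (strand-aware, clipped)."""

    gene_id: str
    chrom: str
    strand: str
    interval: Interval
    W: int

    def __len__(self) -> int:
        return self.interval[1] - self.interval[0]


# ---------------------------------------------------------------------------
# FASTA / GFF3 I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Dict[str, str]:
    """Read a genome FASTA into {chrom: uppercase sequence}."""
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise AnnotationError(f"no sequences in {path}")
    return genome


def write_fasta(genome: Dict[str, str], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    del width  # Biopython's writer wraps at 60; kept for signature stability


def _parse_attributes(attr: str) -> Dict[str, str]:
    out = {}
    for item in attr.strip().split(";"):
        if not item:
            continue
        key, _, val = item.partition("=")
        out[key] = val
    return out


def read_annotation(
    gff3_path: str | Path, fasta_path: str | Path
) -> Tuple[List[TranscriptModel], Dict[str, str]]:
    """Read transcript models and genome; validate and convert coordinates.

    GFF3 ``CDS``, ``five_prime_UTR`` and ``three_prime_UTR`` features are
    grouped by their ``Parent`` (or ``ID``) gene. 1-based inclusive
    coordinates become 0-based half-open. Genes whose CDS length is not a
    multiple of 3 are reported and skipped.
    """
    genome = read_fasta(fasta_path)
    feats: Dict[str, Dict[str, object]] = {}
    bad_seqids = set()
    with open(gff3_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise AnnotationError(f"malformed GFF3 line: {line!r}")
            seqid, _, ftype, start, end, _, strand, _, attr = cols
            if ftype not in ("gene", "CDS", "five_prime_UTR", "three_prime_UTR"):
                continue
            if seqid not in genome:
                bad_seqids.add(seqid)
                continue
            attrs = _parse_attributes(attr)
            gid = attrs.get("Parent") or attrs.get("ID")
            if gid is None:
                raise AnnotationError(f"feature without ID/Parent: {line!r}")
            rec = feats.setdefault(gid, {"chrom": seqid, "strand": strand})
            iv = (int(start) - 1, int(end))  # 1-based incl -> 0-based half-open
            if ftype == "CDS":
                rec["cds"] = iv
            elif ftype == "five_prime_UTR":
                rec["utr5"] = iv
            elif ftype == "three_prime_UTR":
                rec["utr3"] = iv
    if bad_seqids:
        raise AnnotationError(
            "GFF3 seqids absent from FASTA: " + ", ".join(sorted(bad_seqids))
        )
    transcripts: List[TranscriptModel] = []
    for gid, rec in feats.items():
        if "cds" not in rec:
            continue
        cds = rec["cds"]
        if (cds[1] - cds[0]) % 3 != 0:
            logger.warning(
                "skipping %s: CDS length %d not divisible by 3", gid, cds[1] - cds[0]
            )
            continue
        transcripts.append(
            TranscriptModel(
                gene_id=gid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                cds=cds,
                utr5=rec.get("utr5"),
                utr3=rec.get("utr3"),
            )
        )
    transcripts.sort(key=lambda t: (t.chrom, t.cds[0], t.gene_id))
    return transcripts, genome


def write_annotation(
    transcripts: Iterable[TranscriptModel],
    gff3_path: str | Path,
    source: str = "ribolife",
) -> None:
    """Write transcript models as GFF3 (1-based inclusive)."""
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.cds[0], t.gene_id)):
            span = [t.cds[0], t.cds[1]]
            for iv in (t.utr5, t.utr3):
                if iv is not None:
                    span[0] = min(span[0], iv[0])
                    span[1] = max(span[1], iv[1])

            def row(ftype: str, iv: Interval, attrs: str) -> str:
                return (
                    f"{t.chrom}\t{source}\t{ftype}\t{iv[0] + 1}\t{iv[1]}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )

            fh.write(row("gene", tuple(span), f"ID={t.gene_id}"))
            fh.write(row("CDS", t.cds, f"ID={t.gene_id}.cds;Parent={t.gene_id}"))
            if t.utr5 is not None:
                fh.write(row("five_prime_UTR", t.utr5, f"ID={t.gene_id}.utr5;Parent={t.gene_id}"))
            if t.utr3 is not None:
                fh.write(row("three_prime_UTR", t.utr3, f"ID={t.gene_id}.utr3;Parent={t.gene_id}"))


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def promoter_window(
    gene: TranscriptModel, W: int = 1000, chrom_length: Optional[int] = None
) -> PromoterWindow:
    """The ``W`` nt upstream of the CDS start, clipped to the chromosome."""
    if W <= 0:
        raise ValueError("W must be positive")
    if gene.strand == "+":
        start, end = max(0, gene.cds[0] - W), gene.cds[0]
    else:
        start, end = gene.cds[1], gene.cds[1] + W
        if chrom_length is not None:
            end = min(end, chrom_length)
    return PromoterWindow(gene.gene_id, gene.chrom, gene.strand, (start, end), W)


def promoter_sequence(window: PromoterWindow, genome: Dict[str, str]) -> str:
    """Sense-strand promoter sequence (5'->3' toward the start codon)."""
    seq = genome[window.chrom][window.interval[0]: window.interval[1]]
    return seq if window.strand == "+" else revcomp(seq)


# ---------------------------------------------------------------------------
# uORF prediction
# ---------------------------------------------------------------------------

def utr5_sequence(gene: TranscriptModel, genome: Dict[str, str]) -> str:
    """Sense-strand 5'UTR sequence of a gene ('' when absent)."""
    if gene.utr5 is None:
        return ""
    seq = genome[gene.chrom][gene.utr5[0]: gene.utr5[1]]
    return seq if gene.strand == "+" else revcomp(seq)


def predict_uorfs(
    gene: TranscriptModel, genome: Dict[str, str], min_length: int = 0
) -> List[UorfModel]:
    """All candidate uORFs in the gene's 5'UTR.

    Every ATG/GTG/TTG opens a candidate, which is extended codon-wise to
    the first in-frame TAA/TAG/TGA. Candidates without a stop inside the
    UTR (or hitting an N-containing codon) are emitted ``truncated`` with
    the interval clipped to the UTR. Nested/overlapping candidates are
    all kept; ``min_length`` filters on interval length in nt.
    """
    utr = utr5_sequence(gene, genome)
    n = len(utr)
    out: List[UorfModel] = []
    for s in range(n - 2):
        codon = utr[s: s + 3]
        if codon not in START_CODONS:
            continue
        end = None
        truncated = False
        pos = s
        while True:
            if pos + 3 > n:
                end, truncated = n, True
                break
            c = utr[pos: pos + 3]
            if "N" in c:
                end, truncated = pos, True
                break
            if c in STOP_CODONS:
                end = pos + 3
                break
            pos += 3
        if truncated and end <= s:
            continue  # N immediately after (or at) the start codon
        if end - s < min_length:
            continue
        out.append(UorfModel(gene.gene_id, codon, (s, end), truncated))
    out.sort(key=lambda u: (u.interval[0], u.interval[1]))
    return out


def uorf_genomic_interval(gene: TranscriptModel, uorf: UorfModel) -> Interval:
    """Map a transcript-relative uORF interval onto genomic coordinates."""
    if gene.utr5 is None:
        raise AnnotationError(f"{gene.gene_id} has no 5'UTR")
    s, e = uorf.interval
    if gene.strand == "+":
        return (gene.utr5[0] + s, gene.utr5[0] + e)
    return (gene.utr5[1] - e, gene.utr5[1] - s)


# ---------------------------------------------------------------------------
# BED export
# ---------------------------------------------------------------------------

def uorfs_to_bed(
    genes: Iterable[TranscriptModel], uorfs_by_gene: Dict[str, List[UorfModel]], path: str | Path
) -> None:
    """Write predicted uORFs as BED6 (genomic coordinates)."""
    by_id = {g.gene_id: g for g in genes}
    with open(path, "w") as fh:
        for gid in sorted(uorfs_by_gene):
            gene = by_id[gid]
            for i, u in enumerate(uorfs_by_gene[gid]):
                gs, ge = uorf_genomic_interval(gene, u)
                name = f"{gid}.uORF{i + 1}" + (".trunc" if u.truncated else "")
                fh.write(f"{gene.chrom}\t{gs}\t{ge}\t{name}\t0\t{gene.strand}\n")


def promoters_to_bed(windows: Iterable[PromoterWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(
                f"{w.chrom}\t{w.interval[0]}\t{w.interval[1]}\t{w.gene_id}.promoter\t0\t{w.strand}\n"
            )
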