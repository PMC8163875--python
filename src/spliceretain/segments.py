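"""Intron segments from genome annotation.

A *segment* is one annotated intron together with its two flanking exons.
Segments are the unit of everything downstream: junction-read counting,
retention scoring and splice-site sequence analysis.  Coordinates are kept
0-based half-open internally; GFF3/GTF input (1-based inclusive) is converted
on read.  All sequence fields (donor/acceptor dinucleotides, the first K
intron nucleotides, the 5' exon terminal triplet) are reported on the coding
strand, i.e. reverse-complemented for minus-strand genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import gffutils
import pyfaidx

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: minimum intron length a segment may have
MIN_INTRON_LENGTH = 4


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class CoordinateError(ValueError):
    """An annotated feature falls outside its chromosome."""


@dataclass(frozen=True)
class IntronSegment:
    """One annotated intron with flanking exon context.

    ``exon1`` is the genomically left exon and ``exon2`` the right one
    regardless of strand; ``intron_index`` and the sequence fields follow the
    coding strand (for minus-strand genes the coding 5' exon is ``exon2``).
    """

    gene_id: str
    intron_index: int  # 1-based, 5'->3' on the coding strand
    chrom: str
    strand: str
    exon1_start: int
    exon1_end: int
    intron_start: int
    intron_end: int
    exon2_start: int
    exon2_end: int
    donor_dinucleotide: str
    acceptor_dinucleotide: str
    intron_seq_5prime: str  # first K intron nucleotides, coding strand
    exon_triplet: str  # last 3 nt of the 5' exon (positions -3..-1)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.exon1_end != self.intron_start or self.intron_end != self.exon2_start:
            raise ValueError(
                f"{self.gene_id}: exons must abut the intron "
                f"({self.exon1_end},{self.intron_start},{self.intron_end},{self.exon2_start})"
            )
        if self.intron_length < MIN_INTRON_LENGTH:
            raise ValueError(
                f"{self.gene_id}: intron length {self.intron_length} < {MIN_INTRON_LENGTH}"
            )

    @property
    def segment_id(self) -> str:
        return f"{self.gene_id}.i{self.intron_index}"

    @property
    def intron_length(self) -> int:
        return self.intron_end - self.intron_start

    @property
    def fourth_nucleotide(self) -> str:
        """Intron position +4 on the coding strand (faces U6 snRNA m6A)."""
        return self.intron_seq_5prime[3]

    # genomic position of the exon/intron boundary at the coding-strand 5'SS
    @property
    def donor_junction(self) -> int:
        return self.intron_start if self.strand == "+" else self.intron_end

    @property
    def acceptor_junction(self) -> int:
        return self.intron_end if self.strand == "+" else self.intron_start


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch [start, end) from a pyfaidx.Fasta or a plain dict of strings.

    Positions outside the chromosome are padded with N so that windows near
    contig edges stay fixed-width.
    """
    if isinstance(genome, (pyfaidx.Fasta, Mapping)):
        record = genome[chrom]
    else:
        raise TypeError(f"unsupported genome object: {type(genome)!r}")
    length = len(record)
    if start >= length and end > length:
        # fully out of bounds on the right
        return "N" * (end - start)
    lo, hi = max(start, 0), min(end, length)
    seq = record[lo:hi]
    if not isinstance(seq, str):  # pyfaidx returns a Sequence object
        seq = str(seq)
    return "N" * (lo - start) + seq.upper() + "N" * (end - hi)


def _chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])


def _transcript_gene_map(db: gffutils.FeatureDB) -> dict[str, str]:
    tx2gene: dict[str, str] = {}
    for ftype in ("mRNA", "transcript"):
        for feat in db.features_of_type(ftype):
            gene = feat.attributes.get("gene_id", feat.attributes.get("Parent", [feat.id]))
            tx2gene[feat.id] = gene[0]
    return tx2gene


def _exon_transcript_id(feat) -> str | None:
    for key in ("Parent", "transcript_id"):
        if key in feat.attributes:
            return feat.attributes[key][0]
    return None


def extract_intron_segments(
    annotation: str,
    genome,
    k: int = 6,
) -> list[IntronSegment]:
    """Build one segment per consecutive annotated exon pair.

    Parameters
    ----------
    annotation:
        Path to a GFF3 or GTF file (or annotation text) with exon features
        grouped by transcript.
    genome:
        pyfaidx.Fasta, or a mapping chrom -> sequence string.
    k:
        Number of 5'-terminal intron nucleotides to record (>= 6 so the
        fourth nucleotide and the +1..+6 logo window are covered).

    Transcripts with fewer than two exons yield no segments.  Segments with
    identical (chrom, strand, intron coordinates) arising from multiple
    transcripts are collapsed; the gene of the first transcript in sorted
    order wins.
    """
    if k < 6:
        raise ValueError("k must be >= 6")
    db = gffutils.create_db(
        annotation,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        from_string=not _looks_like_path(annotation),
    )
    tx2gene = _transcript_gene_map(db)

    exons_by_tx: dict[str, list] = {}
    for exon in db.features_of_type("exon"):
        tx = _exon_transcript_id(exon)
        if tx is None:
            logger.warning("exon without Parent/transcript_id skipped: %s", exon)
            continue
        exons_by_tx.setdefault(tx, []).append(exon)

    seen: dict[tuple, None] = {}
    raw: list[dict] = []
    for tx in sorted(exons_by_tx, key=lambda t: (tx2gene.get(t, t), t)):
        exons = sorted(exons_by_tx[tx], key=lambda e: e.start)
        gene_id = tx2gene.get(tx, tx)
        for e1, e2 in zip(exons, exons[1:]):
            # GFF 1-based inclusive -> 0-based half-open
            istart, iend = e1.end, e2.start - 1
            chrom, strand = e1.seqid, e1.strand
            chrom_len = _chrom_length(genome, chrom)
            if e1.start - 1 < 0 or e2.end > chrom_len:
                raise CoordinateError(
                    f"exon of {tx} outside chromosome {chrom} (length {chrom_len})"
                )
            if iend - istart < MIN_INTRON_LENGTH:
                logger.warning(
                    "%s: exon gap [%d,%d) shorter than %d nt skipped",
                    tx, istart, iend, MIN_INTRON_LENGTH,
                )
                continue
            key = (chrom, strand, istart, iend)
            if key in seen:
                continue
            seen[key] = None
            raw.append(
                dict(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exon1_start=e1.start - 1,
                    exon1_end=istart,
                    intron_start=istart,
                    intron_end=iend,
                    exon2_start=iend,
                    exon2_end=e2.end,
                )
            )

    # intron_index: 1-based along the coding strand within each gene
    by_gene: dict[str, list[dict]] = {}
    for rec in raw:
        by_gene.setdefault(rec["gene_id"], []).append(rec)
    segments: list[IntronSegment] = []
    for gene_id in sorted(by_gene):
        recs = by_gene[gene_id]
        minus = recs[0]["strand"] == "-"
        recs.sort(key=lambda r: r["intron_start"], reverse=minus)
        for idx, rec in enumerate(recs, start=1):
            segments.append(_finish_segment(rec, idx, genome, k))
    segments.sort(key=lambda s: (s.chrom, s.intron_start, s.intron_end, s.strand))
    return segments


def _finish_segment(rec: dict, index: int, genome, k: int) -> IntronSegment:
    chrom = rec["chrom"]
    istart, iend = rec["intron_start"], rec["intron_end"]
    if rec["strand"] == "+":
        donor = _fetch(genome, chrom, istart, istart + 2)
        acceptor = _fetch(genome, chrom, iend - 2, iend)
        intron5 = _fetch(genome, chrom, istart, istart + k)
        triplet = _fetch(genome, chrom, istart - 3, istart)
    else:
        donor = reverse_complement(_fetch(genome, chrom, iend - 2, iend))
        acceptor = reverse_complement(_fetch(genome, chrom, istart, istart + 2))
        intron5 = reverse_complement(_fetch(genome, chrom, iend - k, iend))
        triplet = reverse_complement(_fetch(genome, chrom, iend, iend + 3))
    return IntronSegment(
        gene_id=rec["gene_id"],
        intron_index=index,
        chrom=chrom,
        strand=rec["strand"],
        exon1_start=rec["exon1_start"],
        exon1_end=rec["exon1_end"],
        intron_start=istart,
        intron_end=iend,
        exon2_start=rec["exon2_start"],
        exon2_end=rec["exon2_end"],
        donor_dinucleotide=donor,
        acceptor_dinucleotide=acceptor,
        intron_seq_5prime=intron5,
        exon_triplet=triplet,
    )


def _looks_like_path(annotation: str) -> bool:
    return "\n" not in annotation and "\t" not in annotation


def segments_by_id(segments: Iterable[IntronSegment]) -> dict[str, IntronSegment]:
    return {s.segment_id: s for s in segments}
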