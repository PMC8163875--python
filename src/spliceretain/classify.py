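"""Junction-read classification and counting.

Every spliced-alignment read overlapping a segment is assigned exactly one of
five classes, defined in coding-strand orientation:

* ``CSR``  — canonical splicing read: an N-gap whose boundaries equal the
  annotated intron, with enough aligned nucleotides on both sides.
* ``EIJR`` — 5' exon–intron junction read: contiguous alignment (no gap at the
  5' splice site) across the donor junction.
* ``IEJR`` — intron–3' exon junction read: contiguous across the acceptor
  junction.
* ``A5R``  — alternative 5'SS read: an N-gap joined to the canonical acceptor
  from a non-canonical donor within the segment.
* ``A3R``  — alternative 3'SS read: the canonical donor joined to a
  non-canonical acceptor within the segment.
* ``NONE`` — anything else (reads fully inside the intron or fully exonic).

The classes feed cov(Total) = (EIJR + IEJR)/2 + A5R + A3R + CSR: a retained
transcript is seen at two junctions, so the exon–intron classes are averaged.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .metrics import total_coverage
from .segments import IntronSegment


class ReadClass(enum.Enum):
    EIJR = "eijr"
    IEJR = "iejr"
    CSR = "csr"
    A5R = "a5r"
    A3R = "a3r"
    NONE = "none"


COUNT_COLUMNS = ["eijr", "iejr", "csr", "a5r", "a3r"]

# CIGAR op codes: M=0, I=1, D=2, N=3, S=4, H=5, P=6, ==7, X=8
_REF_CONSUMING = {0, 2, 7, 8}
_GAP = 3


def _blocks_and_gaps(aln: pysam.AlignedSegment):
    """Reference-aligned blocks split only at N gaps (deletions stay merged).

    Returns ``(blocks, gaps)`` where blocks are [start, end) intervals and
    ``gaps[i]`` sits between ``blocks[i]`` and ``blocks[i+1]``.
    """
    if aln.cigartuples is None:
        raise ValueError(f"alignment {aln.query_name!r} has no CIGAR")
    blocks: list[list[int]] = []
    gaps: list[tuple[int, int]] = []
    pos = aln.reference_start
    block_start = pos
    open_block = False
    for op, length in aln.cigartuples:
        if op in _REF_CONSUMING:
            if not open_block:
                block_start = pos
                open_block = True
            pos += length
        elif op == _GAP:
            if open_block:
                blocks.append([block_start, pos])
                open_block = False
            gaps.append((pos, pos + length))
            pos += length
        # I/S/H/P consume no reference
    if open_block:
        blocks.append([block_start, pos])
    return [tuple(b) for b in blocks], gaps


def classify_alignment(
    aln: pysam.AlignedSegment,
    segment: IntronSegment,
    min_overhang: int = 8,
) -> ReadClass:
    """Assign one junction-read class to an alignment against one segment."""
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    if aln.is_unmapped or aln.reference_name != segment.chrom:
        return ReadClass.NONE
    blocks, gaps = _blocks_and_gaps(aln)
    if not blocks:
        return ReadClass.NONE
    o = min_overhang
    istart, iend = segment.intron_start, segment.intron_end

    def flanks_ok(i: int) -> bool:
        left = blocks[i][1] - blocks[i][0]
        right = blocks[i + 1][1] - blocks[i + 1][0]
        return left >= o and right >= o

    for i, (gs, ge) in enumerate(gaps):
        if (gs, ge) == (istart, iend) and flanks_ok(i):
            return ReadClass.CSR

    # alternative-site gaps: one boundary canonical, the other elsewhere but
    # still inside the segment (exon1 start .. exon2 end)
    lo, hi = segment.exon1_start, segment.exon2_end
    plus = segment.strand == "+"
    for i, (gs, ge) in enumerate(gaps):
        if not flanks_ok(i):
            continue
        if plus:
            alt_donor = ge == iend and gs != istart and lo < gs < iend
            alt_acceptor = gs == istart and ge != iend and istart < ge < hi
        else:
            alt_donor = gs == istart and ge != iend and istart < ge < hi
            alt_acceptor = ge == iend and gs != istart and lo < gs < iend
        if alt_donor:
            return ReadClass.A5R
        if alt_acceptor:
            return ReadClass.A3R

    dj, aj = segment.donor_junction, segment.acceptor_junction
    for bs, be in blocks:
        if bs <= dj - o and be >= dj + o:
            return ReadClass.EIJR
    for bs, be in blocks:
        if bs <= aj - o and be >= aj + o:
            return ReadClass.IEJR
    return ReadClass.NONE


@dataclass
class CountingParams:
    min_overhang: int = 8


def _open_alignments(alignments) -> Iterator[pysam.AlignedSegment]:
    if isinstance(alignments, (str, os.PathLike)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            yield from fh
    else:
        yield from alignments


def count_junctions(
    alignments,
    segments: Iterable[IntronSegment],
    sample_id: str,
    params: CountingParams | None = None,
) -> pd.DataFrame:
    """Count the five junction-read classes per segment for one sample.

    Parameters
    ----------
    alignments:
        Path to a SAM/BAM file, an open pysam.AlignmentFile, or any iterable
        of AlignedSegment.  Unmapped, secondary and supplementary records are
        skipped; each remaining alignment contributes at most 1 to each
        overlapping segment.
    segments:
        Segments from :func:`spliceretain.segments.extract_intron_segments`.
    sample_id:
        Label written into the ``sample_id`` column.

    Returns a table with one row per segment (zero counts when no read
    matched) including cov(Total).
    """
    params = params or CountingParams()
    segments = list(segments)
    trees: dict[str, IntervalTree] = {}
    for seg in segments:
        trees.setdefault(seg.chrom, IntervalTree()).addi(
            seg.exon1_start, seg.exon2_end, seg
        )
    counts: dict[str, dict[str, int]] = {
        seg.segment_id: dict.fromkeys(COUNT_COLUMNS, 0) for seg in segments
    }
    for aln in _open_alignments(alignments):
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
            continue
        tree = trees.get(aln.reference_name)
        if tree is None:
            continue
        for iv in tree.overlap(aln.reference_start, aln.reference_end):
            seg: IntronSegment = iv.data
            cls = classify_alignment(aln, seg, params.min_overhang)
            if cls is not ReadClass.NONE:
                counts[seg.segment_id][cls.value] += 1

    rows = []
    for seg in segments:
        c = counts[seg.segment_id]
        rows.append(
            {
                "segment_id": seg.segment_id,
                "gene_id": seg.gene_id,
                "intron_index": seg.intron_index,
                "chrom": seg.chrom,
                "strand": seg.strand,
                "intron_start": seg.intron_start,
                "intron_end": seg.intron_end,
                "sample_id": sample_id,
                **c,
                "total": total_coverage(**c),
            }
        )
    return pd.DataFrame(rows)
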