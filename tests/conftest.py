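import pysam
import pytest

from spliceretain.segments import IntronSegment

#: one reference for in-memory alignment construction
SAM_HEADER = pysam.AlignmentHeader.from_references(["chr1", "chr2"], [1000, 1000])


def make_alignment(pos: int, cigar: str, chrom: str = "chr1",
                   name: str = "r", flag: int = 0) -> pysam.AlignedSegment:
    aln = pysam.AlignedSegment(header=SAM_HEADER)
    aln.query_name = name
    aln.flag = flag
    aln.reference_name = chrom
    aln.reference_start = pos
    aln.mapping_quality = 60
    aln.cigarstring = cigar
    return aln


def make_segment(
    strand: str = "+",
    exon1=(0, 100),
    intron=(100, 200),
    exon2=(200, 300),
    gene_id: str = "g1",
    intron_index: int = 1,
    donor: str = "GT",
    acceptor: str = "AG",
    intron5: str = "GTAAGT",
    triplet: str = "AAG",
    chrom: str = "chr1",
) -> IntronSegment:
    return IntronSegment(
        gene_id=gene_id,
        intron_index=intron_index,
        chrom=chrom,
        strand=strand,
        exon1_start=exon1[0],
        exon1_end=exon1[1],
        intron_start=intron[0],
        intron_end=intron[1],
        exon2_start=exon2[0],
        exon2_end=exon2[1],
        donor_dinucleotide=donor,
        acceptor_dinucleotide=acceptor,
        intron_seq_5prime=intron5,
        exon_triplet=triplet,
    )


@pytest.fixture
def plus_segment() -> IntronSegment:
    return make_segment("+")


@pytest.fixture
def minus_segment() -> IntronSegment:
    return make_segment("-")
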