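"""Synthetic genome, annotation, retention model, counts and spliced reads.

The generator emulates the study design the pipeline targets: quadruplicate
poly(A)+ RNA-seq of a fission-yeast-like wild type (WT) and a knockout (KO)
lacking the U6 snRNA m6A modification.  Ground truth is parameterised per
intron:

* the fourth intron nucleotide (the base that pairs with the U6 m6A) drawn
  from a configurable composition — defaults follow the observed A/T/C/G
  split at +4 among eligible fission-yeast introns (~0.50/0.37/0.10/0.03);
* the 5' exon terminal triplet, with per-position probabilities giving an
  AAG (U5 loop-I consensus) fraction of roughly 11%;
* a baseline retention odds (log-normal) shared by both conditions;
* a knockout odds multiplier depending on the fourth nucleotide, applied
  only to non-AAG introns (default A4 x6, C4 x3, T4 x1, G4 x1.2, AAG x1) —
  the structure whereby m6A loss hurts A4/C4 introns unless a strong U5
  contact compensates.

Counts are the primary simulation level: per replicate the informative
fragment total is negative-binomial (Poisson when dispersion = 0), the
canonical-splice count binomial with probability 1 - r where the retention
fraction r = odds/(1+odds), and retained fragments split between the two
exon-intron junction classes.  A read-level emitter materialises any counts
table as a valid SAM file whose CIGARs realise the intended classes, for
end-to-end tests of the classifier.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import pysam

from .segments import reverse_complement

DEFAULT_FOURTH_NT_PROBS = {
    # observed +4 composition among eligible introns: 2539/1846/514/157 of 5056
    "A": 2539 / 5056,
    "T": 1846 / 5056,
    "C": 514 / 5056,
    "G": 157 / 5056,
}

DEFAULT_KNOCKOUT_EFFECTS = {"A4": 6.0, "C4": 3.0, "T4": 1.0, "G4": 1.2}


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic WT/KO design."""

    n_genes: int = 2000
    introns_per_gene: int = 1
    exon_length: int = 100
    intron_length: int = 60
    intergenic_length: int = 50
    minus_strand_fraction: float = 0.5
    gc_content: float = 0.36  # fission-yeast-like background
    fourth_nt_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FOURTH_NT_PROBS))
    donor_gc_fraction: float = 0.02  # GC- (vs GT-) donors
    # exon triplet: P(A at -3), P(A at -2), P(G at -1); 0.40*0.50*0.55 ~ 11% AAG
    triplet_pa3: float = 0.40
    triplet_pa2: float = 0.50
    triplet_pg1: float = 0.55
    baseline_log2_odds_mean: float = -5.5
    baseline_log2_odds_sd: float = 1.0
    knockout_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_KNOCKOUT_EFFECTS))
    aag_effect: float = 1.0  # KO multiplier for AAG introns (overrides class)
    expression_mean: float = 500.0
    expression_log2_sd: float = 0.0  # per-gene depth spread (0 = uniform)
    dispersion: float = 0.1  # NB overdispersion; 0 = Poisson
    n_replicates: int = 4
    alt5_rate: float = 0.0
    alt3_rate: float = 0.0
    eijr_fraction: float = 0.5
    chrom_name: str = "chr_sim"

    def __post_init__(self) -> None:
        if self.intron_length < 6:
            raise ConfigError("intron_length must be >= 6")
        if self.exon_length < 9:
            raise ConfigError("exon_length must be >= 9")
        if self.n_genes < 1 or self.introns_per_gene < 1:
            raise ConfigError("need at least one gene and one intron per gene")
        if self.n_replicates < 2:
            raise ConfigError("need >= 2 replicates per condition")
        probs = np.array([self.fourth_nt_probs.get(nt, 0.0) for nt in "ATCG"])
        if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise ConfigError("fourth_nt_probs must be a distribution over ATCG")


def null_config(config: SimulationConfig | None = None) -> SimulationConfig:
    """The same design with every knockout effect set to 1 (no retention
    change between conditions)."""
    config = config or SimulationConfig()
    return dataclasses.replace(
        config,
        knockout_effects={g: 1.0 for g in config.knockout_effects},
        aag_effect=1.0,
    )


@dataclass
class SyntheticReference:
    genome: dict[str, str]
    truth: pd.DataFrame
    gff3_text: str
    seed: int

    @property
    def fasta_text(self) -> str:
        out = []
        for name in sorted(self.genome):
            out.append(f">{name}")
            seq = self.genome[name]
            out.extend(seq[i:i + 70] for i in range(0, len(seq), 70))
        return "\n".join(out) + "\n"

    def write(self, directory) -> dict[str, str]:
        import os

        paths = {
            "fasta": os.path.join(directory, "genome.fa"),
            "gff3": os.path.join(directory, "annotation.gff3"),
            "truth": os.path.join(directory, "truth.tsv"),
        }
        with open(paths["fasta"], "w") as fh:
            fh.write(self.fasta_text)
        with open(paths["gff3"], "w") as fh:
            fh.write(self.gff3_text)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _sample_triplet(rng: np.random.Generator, cfg: SimulationConfig) -> str:
    p3 = "A" if rng.random() < cfg.triplet_pa3 else rng.choice(list("CGT"))
    p2 = "A" if rng.random() < cfg.triplet_pa2 else rng.choice(list("CGT"))
    p1 = "G" if rng.random() < cfg.triplet_pg1 else rng.choice(list("ACT"))
    return f"{p3}{p2}{p1}"


def _write_motif(genome: np.ndarray, start: int, seq: str) -> None:
    genome[start:start + len(seq)] = np.frombuffer(seq.encode(), dtype="S1")


def generate_reference(
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> SyntheticReference:
    """Deterministic toy genome + GFF3 annotation + per-intron ground truth.

    Every intron gets a GT (or, rarely, GC) donor and an AG acceptor on the
    coding strand; the fourth intron nucleotide and the 5' exon terminal
    triplet are drawn from the configured compositions and recorded exactly
    in the truth table.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    n_exons = cfg.introns_per_gene + 1
    gene_span = n_exons * cfg.exon_length + cfg.introns_per_gene * cfg.intron_length
    total_len = cfg.n_genes * (gene_span + cfg.intergenic_length) + cfg.intergenic_length

    gc = cfg.gc_content
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = rng.choice(bases, size=total_len, p=probs)

    nt_list = list("ATCG")
    nt_probs = np.array([cfg.fourth_nt_probs[nt] for nt in nt_list])

    truth_rows = []
    gff = ["##gff-version 3",
           f"##sequence-region {cfg.chrom_name} 1 {total_len}"]
    cursor = cfg.intergenic_length
    digits = max(4, len(str(cfg.n_genes)))
    for g in range(cfg.n_genes):
        gene_id = f"sg{g:0{digits}d}"
        strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
        gene_start = cursor
        exon_bounds = []
        pos = gene_start
        for _ in range(n_exons):
            exon_bounds.append((pos, pos + cfg.exon_length))
            pos += cfg.exon_length + cfg.intron_length
        gene_end = exon_bounds[-1][1]

        gff.append("\t".join([cfg.chrom_name, "spliceretain_sim", "gene",
                              str(gene_start + 1), str(gene_end), ".", strand, ".",
                              f"ID={gene_id};gene_id={gene_id}"]))
        tx_id = f"{gene_id}.1"
        gff.append("\t".join([cfg.chrom_name, "spliceretain_sim", "mRNA",
                              str(gene_start + 1), str(gene_end), ".", strand, ".",
                              f"ID={tx_id};Parent={gene_id};gene_id={gene_id}"]))
        for (es, ee) in exon_bounds:
            for ftype in ("exon", "CDS"):
                gff.append("\t".join([cfg.chrom_name, "spliceretain_sim", ftype,
                                      str(es + 1), str(ee), ".", strand,
                                      "0" if ftype == "CDS" else ".",
                                      f"Parent={tx_id};gene_id={gene_id}"]))

        expr = cfg.expression_mean * float(
            2.0 ** rng.normal(0.0, cfg.expression_log2_sd)) \
            if cfg.expression_log2_sd > 0 else cfg.expression_mean

        genomic_introns = []
        for j in range(cfg.introns_per_gene):
            istart = exon_bounds[j][1]
            iend = exon_bounds[j + 1][0]
            genomic_introns.append((istart, iend, exon_bounds[j][0],
                                    exon_bounds[j + 1][1]))
        coding_order = genomic_introns if strand == "+" else genomic_introns[::-1]
        for idx, (istart, iend, exl_start, exr_end) in enumerate(coding_order, 1):
            fourth = str(rng.choice(nt_list, p=nt_probs))
            donor = "GC" if rng.random() < cfg.donor_gc_fraction else "GT"
            triplet = _sample_triplet(rng, cfg)
            if strand == "+":
                _write_motif(genome, istart, donor)
                _write_motif(genome, istart + 3, fourth)
                _write_motif(genome, iend - 2, "AG")
                _write_motif(genome, istart - 3, triplet)
            else:
                _write_motif(genome, iend - 2, reverse_complement(donor))
                _write_motif(genome, iend - 4, reverse_complement(fourth))
                _write_motif(genome, istart, reverse_complement("AG"))
                _write_motif(genome, iend, reverse_complement(triplet))
            is_aag = triplet == "AAG"
            group = f"{fourth}4"
            effect = cfg.aag_effect if is_aag else cfg.knockout_effects.get(group, 1.0)
            baseline_odds = float(2.0 ** rng.normal(
                cfg.baseline_log2_odds_mean, cfg.baseline_log2_odds_sd))
            truth_rows.append({
                "gene_id": gene_id,
                "segment_id": f"{gene_id}.i{idx}",
                "chrom": cfg.chrom_name,
                "strand": strand,
                "exon_left_start": exl_start,
                "intron_start": istart,
                "intron_end": iend,
                "exon_right_end": exr_end,
                "donor": donor,
                "fourth_nt": fourth,
                "fourth_group": group,
                "exon_triplet": triplet,
                "is_aag": is_aag,
                "baseline_odds": baseline_odds,
                "ko_effect": effect,
                "expression_mean": expr,
                "dispersion": cfg.dispersion,
            })
        cursor = gene_end + cfg.intergenic_length

    genome_str = genome.tobytes().decode()
    return SyntheticReference(
        genome={cfg.chrom_name: genome_str},
        truth=pd.DataFrame(truth_rows),
        gff3_text="\n".join(gff) + "\n",
        seed=seed,
    )


def _draw_totals(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    return rng.negative_binomial(shape, shape / (shape + mean))


def simulate_junction_counts(
    truth: pd.DataFrame,
    config: SimulationConfig | None = None,
    seed: int = 0,
    conditions: tuple[str, str] = ("WT", "KO"),
) -> pd.DataFrame:
    """Per-intron, per-replicate junction-class counts for both conditions.

    Returns a long table with sample ids ``WT_1 .. KO_n``, the five class
    counts, cov(Total) and the generating retention fraction.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    wt_label, ko_label = conditions
    baseline = truth["baseline_odds"].to_numpy(float)
    effect = truth["ko_effect"].to_numpy(float)
    mean = truth["expression_mean"].to_numpy(float)
    n = len(truth)
    frames = []
    for cond in (wt_label, ko_label):
        odds = baseline * (effect if cond == ko_label else 1.0)
        r = odds / (1.0 + odds)
        for rep in range(1, cfg.n_replicates + 1):
            total = _draw_totals(rng, mean, cfg.dispersion)
            a5r = rng.binomial(total, cfg.alt5_rate) if cfg.alt5_rate > 0 \
                else np.zeros(n, dtype=int)
            remainder = total - a5r
            a3r = rng.binomial(remainder, cfg.alt3_rate) if cfg.alt3_rate > 0 \
                else np.zeros(n, dtype=int)
            remainder = remainder - a3r
            csr = rng.binomial(remainder, 1.0 - r)
            retained = remainder - csr
            eijr = rng.binomial(retained, cfg.eijr_fraction)
            iejr = retained - eijr
            frames.append(pd.DataFrame({
                "segment_id": truth["segment_id"].to_numpy(),
                "condition": cond,
                "replicate": rep,
                "sample_id": f"{cond}_{rep}",
                "eijr": eijr, "iejr": iejr, "csr": csr,
                "a5r": a5r, "a3r": a3r,
                "total": (eijr + iejr) / 2 + a5r + a3r + csr,
                "retention_fraction": r,
            }))
    return pd.concat(frames, ignore_index=True)


def sample_conditions(counts: pd.DataFrame) -> dict[str, str]:
    """sample_id -> condition map recovered from a simulated counts table."""
    return dict(
        counts[["sample_id", "condition"]].drop_duplicates().itertuples(index=False)
    )


def _contiguous_read(rng, j, istart, iend, exl, exr, rl, o):
    """Start position for a contiguous read crossing junction j with >= o nt
    on both sides but without a >= o overhang across the other junction."""
    ilen = iend - istart
    a_min, a_max = o, rl - o
    if j == istart:
        a_max = min(a_max, j - exl)              # stay inside the left exon
        a_min = max(a_min, rl - (ilen + o - 1))  # < o overhang past other junction
    else:  # j == iend
        a_max = min(a_max, ilen + o - 1, j - exl)  # < o overhang past other junction
        a_min = max(a_min, rl - (exr - j))       # stay inside the right exon
    if a_min > a_max:
        raise ConfigError("segment too short for read_length/min_overhang")
    a = int(rng.integers(a_min, a_max + 1))
    return j - a


def emit_reads(
    reference: SyntheticReference,
    counts: pd.DataFrame,
    path: str,
    read_length: int = 50,
    min_overhang: int = 8,
    alt_shift: int = 6,
    seed: int = 0,
) -> int:
    """Write a SAM file realising every counted read of a counts table.

    For each (segment, class) count one alignment per unit is emitted whose
    CIGAR produces exactly that class under the classifier: an N-gap over the
    intron for CSR, a contiguous match across the coding-strand 5'SS for
    EIJR (3'SS for IEJR), and N-gaps with one shifted boundary for A5R/A3R.
    Returns the number of records written.
    """
    cfg_rl, o = read_length, min_overhang
    if cfg_rl < 2 * o:
        raise ConfigError("read_length must be >= 2 * min_overhang")
    rng = np.random.default_rng(seed)
    truth = reference.truth.set_index("segment_id")
    chrom_names = sorted(reference.genome)
    header = pysam.AlignmentHeader.from_references(
        chrom_names, [len(reference.genome[c]) for c in chrom_names])

    n_written = 0
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for row in counts.itertuples(index=False):
            seg = truth.loc[row.segment_id]
            istart, iend = int(seg["intron_start"]), int(seg["intron_end"])
            exl, exr = int(seg["exon_left_start"]), int(seg["exon_right_end"])
            strand = seg["strand"]
            ilen = iend - istart
            if ilen <= alt_shift:
                raise ConfigError("intron too short for alt_shift")
            chrom = seg["chrom"]
            seq = reference.genome[chrom]
            donor_j = istart if strand == "+" else iend
            acceptor_j = iend if strand == "+" else istart
            sample = getattr(row, "sample_id", "sim")

            def emit(pos: int, cigar: str, cls: str, k: int) -> None:
                nonlocal n_written
                a = pysam.AlignedSegment(header=header)
                a.query_name = f"{row.segment_id}:{sample}:{cls}:{k}"
                a.flag = 0
                a.reference_name = chrom
                a.reference_start = pos
                a.mapping_quality = 255
                a.cigarstring = cigar
                read_seq = []
                p = pos
                for op, length in a.cigartuples:
                    if op in (0, 7, 8):
                        read_seq.append(seq[p:p + length])
                        p += length
                    elif op in (2, 3):
                        p += length
                a.query_sequence = "".join(read_seq)
                a.query_qualities = pysam.qualitystring_to_array("I" * len(a.query_sequence))
                out.write(a)
                n_written += 1

            for k in range(int(row.csr)):
                a_min = max(o, cfg_rl - (exr - iend))
                a_max = min(cfg_rl - o, istart - exl)
                if a_min > a_max:
                    raise ConfigError("exons too short for CSR reads")
                a_len = int(rng.integers(a_min, a_max + 1))
                emit(istart - a_len,
                     f"{a_len}M{ilen}N{cfg_rl - a_len}M", "csr", k)
            for k in range(int(row.eijr)):
                pos = _contiguous_read(rng, donor_j, istart, iend, exl, exr, cfg_rl, o)
                emit(pos, f"{cfg_rl}M", "eijr", k)
            for k in range(int(row.iejr)):
                pos = _contiguous_read(rng, acceptor_j, istart, iend, exl, exr, cfg_rl, o)
                emit(pos, f"{cfg_rl}M", "iejr", k)
            for k in range(int(row.a5r)):
                if strand == "+":
                    gs, ge = istart + alt_shift, iend
                else:
                    gs, ge = istart, iend - alt_shift
                left = int(rng.integers(o, cfg_rl - o + 1))
                emit(gs - left,
                     f"{left}M{ge - gs}N{cfg_rl - left}M", "a5r", k)
            for k in range(int(row.a3r)):
                if strand == "+":
                    gs, ge = istart, iend - alt_shift
                else:
                    gs, ge = istart + alt_shift, iend
                left = int(rng.integers(o, cfg_rl - o + 1))
                emit(gs - left,
                     f"{left}M{ge - gs}N{cfg_rl - left}M", "a3r", k)
    return n_written
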