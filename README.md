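# spliceretain

Quantification of intron retention from spliced RNA-seq alignments, built
around the junction-read bookkeeping used to study the splicing phenotype of
fission-yeast cells lacking the N6-methyladenosine (m6A) modification of U6
snRNA. The m6A in the U6 ACAGA box base-pairs with the fourth nucleotide of
the intron during 5' splice-site recognition, and U5 snRNA loop I reads the
last three nucleotides of the upstream exon; `spliceretain` provides the
statistics needed to see both signals in bulk RNA-seq: which introns are
retained more in a mutant, and which sequence features predict it.

It is a library for people analysing spliced alignments of a WT-vs-mutant
design (plus a thin `spliceretain` CLI for the file-level steps), and it
ships a synthetic-data generator that emulates the quadruplicate
WT/knockout study design so the entire pipeline is testable without any
sequencing data.

## Model

For each annotated intron (a *segment*: the intron plus its flanking exons),
reads are classified into five classes: 5' exon–intron junction reads
(EIJR), intron–3' exon junction reads (IEJR), canonical splicing reads
(CSR, an N-gap exactly matching the intron), and alternative 5'/3' splice
site reads (A5R/A3R). With cov(x) the read count of class x:

    cov(Total) = (cov(EIJR) + cov(IEJR)) / 2 + cov(A5R) + cov(A3R) + cov(CSR)

    IRS = log2( (cov(EIJR) + cov(IEJR) + 0.1) / (2 cov(CSR) + 0.1) )

    PCS = cov(CSR) / cov(Total)

IRS (Intron Retention Score) measures retention level; PCS (Proportion of
Canonical Splicing) the fraction of canonically spliced transcripts.
Retention differences between conditions are ranked per intron by a
two-sample Z-score over replicate IRS values,

    Z = (mu_KO − mu_WT) / sqrt(sigma_KO^2 / n_KO + sigma_WT^2 / n_WT)

restricted to GY-AG introns with cov(Total) > 10 in every replicate and
mean CSR > 10 in at least one condition. Introns are split by Z-score
quartiles; the high and low quartiles are compared at sequence level with
information-content logos, Jensen–Shannon difference logos, and exact
two-sided Fisher tests per splice-site position. Introns are further grouped
by their fourth nucleotide (A4/T4/C4/G4) and by the 5' exon terminal triplet
(AAG vs its degenerate classes BAG … BBH), and per-group ΔIRS
(mean IRS KO − mean IRS WT) distributions are compared by Wilcoxon rank-sum
tests. Finally, gene-level counts can be corrected for splicing,

    adjusted counts = raw counts × Π_k PCS_k

over the introns inside the gene's CDS, for downstream differential
expression.

## Worked example

`examples/04_group_effects.py` simulates a 1000-intron quadruplicate WT/KO
study in which knockout retention odds are multiplied by 6 for A4 introns,
3 for C4, 1.2 for G4 and 1 for T4 — except that AAG-triplet introns are
protected (×1) — then recovers that structure from the counts alone:

```
ΔIRS by fourth intron nucleotide:

       q1  median     q3  whisker_low  whisker_high      n
A4  0.280   2.294  2.855       -0.804         3.734  499.0
C4  1.252   1.636  2.072       -0.328         3.225  112.0
G4  0.059   0.341  0.737       -0.577         1.560   28.0
T4 -0.154   0.023  0.201       -0.684         0.732  361.0

AAG-A4 median ΔIRS:     +0.026  (n=49)
non-AAG-A4 median ΔIRS: +2.621  (n=450)
```

A4 introns show the largest retention increase, C4 intermediate, T4/G4
little; AAG-A4 introns are suppressed to near zero — the cooperative
U6-m6A / U5-loop-I signature. The other examples cover junction counting
from SAM (`01`), IRS/PCS/Z-scores (`02`), difference logos and the +4
Fisher enrichment (`03`), and splicing-adjusted counts (`05`); each prints
its numbers with a note on what they mean.

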