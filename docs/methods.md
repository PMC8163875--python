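# Methods

## Segments and coordinates

The unit of analysis is the *intron segment*: one annotated intron with its
two flanking exons, built from every consecutive exon pair of every
transcript. Internally all coordinates are 0-based half-open; GFF3/GTF
input (1-based inclusive) is converted on read, which makes junction
arithmetic unambiguous (the donor boundary of a plus-strand intron *is*
`exon1_end == intron_start`). Segments identical in (chromosome, strand,
intron coordinates) across transcripts are collapsed; the gene of the first
transcript in sorted order wins, so the output is deterministic. Intron
indices are 1-based along the coding strand, and all sequence fields
(donor/acceptor dinucleotides, the first K ≥ 6 intron nucleotides, the 5'
exon terminal triplet) are reported on the coding strand, i.e.
reverse-complemented for minus-strand genes. Introns shorter than 4 nt are
skipped with a warning; exons outside their chromosome raise a coordinate
error.

## Read classification

Classification is strand-aware and purely coordinate-based. An alignment's
CIGAR is reduced to reference blocks separated only by N gaps (deletions do
not break contiguity; insertions and clips are ignored). Against one
segment, precedence is CSR → A5R → A3R → EIJR → IEJR → NONE:

* **CSR** — an N-gap whose boundaries equal the annotated intron, with at
  least `min_overhang` aligned nucleotides in the blocks on both sides.
* **A5R / A3R** — an N-gap sharing exactly one boundary with the annotated
  intron, the other falling elsewhere inside the segment (exon1 start to
  exon2 end), again with sufficient flanks. Which of the two labels applies
  follows the coding strand: a gap joining an alternative *donor* to the
  canonical acceptor is A5R.
* **EIJR / IEJR** — a contiguous block spanning the coding-strand donor
  (resp. acceptor) junction with `min_overhang` on both sides.

The precedence makes classification exhaustive and mutually exclusive per
(alignment, segment) pair; a read contiguous across *both* junctions of a
very short intron is counted as EIJR. `min_overhang` defaults to 8 nt,
mirroring common aligner junction-overhang settings. Counting uses primary
alignments only (each mate of a pair counts independently); a read
overlapping several segments is evaluated independently against each, which
also handles multi-intron (two-N-gap) reads. Alternative splice sites are
*not* required to look GT/AG-like — the A5R/A3R classes are bookkeeping for
mis-splicing, not site discovery.

Strand-awareness of EIJR/IEJR and A5R/A3R is what makes the classifier
invariant under reverse-complementing the genome and flipping the
annotation (a property the test suite checks); defining the classes by
genomic left/right instead would swap labels for minus-strand genes.

## Scores

With the five class counts of one segment in one sample:

* `cov(Total) = (EIJR + IEJR)/2 + A5R + A3R + CSR` — the halving reflects
  that one retained transcript presents two exon–intron junctions.
* `IRS = log2((EIJR + IEJR + 0.1)/(2·CSR + 0.1))` — the 0.1 pseudocount is
  fixed, not configurable, so scores remain comparable between analyses;
  IRS is finite for all non-negative counts and strictly monotone
  (increasing in EIJR/IEJR, decreasing in CSR).
* `PCS = CSR / cov(Total)` ∈ [0, 1]; undefined at zero coverage and
  propagated as missing, never imputed as 0 or 1.
* The RT-qPCR-style IRS (`qpcr_irs`) is the plain log2 ratio of retained to
  spliced isoform abundance, without pseudocount; both abundances must be
  positive.

## Z-scores, eligibility and quartiles

Retention change per intron is scored by a two-sample Z on replicate IRS
values, `(mean_KO − mean_WT)/sqrt(s2_KO/n_KO + s2_WT/n_WT)` with *sample*
variances (ddof = 1) — the standard two-sample convention; with
quadruplicates this is exactly the σ²/4 form, and the implementation
generalises to any n ≥ 2 per condition. If both variances are zero the
score is 0 for equal means and signed infinity otherwise, so such introns
sort to the extremes rather than being dropped.

Eligibility requires a GY donor (G then pyrimidine) and AG acceptor,
cov(Total) strictly greater than 10 in *every* replicate of both
conditions, and mean CSR strictly greater than 10 in at least one
condition; a segment missing counts in any sample fails the depth filter.

The quartile split sorts Z descending: `high` is strictly above the upper
quartile boundary and `low` strictly below the lower one (inclusive/linear
quantiles); boundary ties fall into `mid`, and if all Z are equal both
extreme classes are empty. For n distinct values this yields ⌊n/4⌋ introns
per extreme class. Strict value comparison makes the split deterministic
without any tie-breaking randomness.

Per-intron IRS is reported per replicate; condition summaries are replicate
means (ΔIRS = mean KO − mean WT). Pooled-count IRS can be obtained by
summing counts before scoring, but replicate means are what the Z-score and
ΔIRS use.

## Sequence analysis

5'SS windows cover exon −3..−1 plus intron +1..+6 and 3'SS windows intron
−6..−1 plus exon +1..+3 by default (configurable); these widths cover every
position the retention analysis interprets — the +4 nucleotide facing the
U6 m6A and the −3..−1 triplet read by U5 loop I. Position frequency
matrices exclude ambiguous bases column-wise (per-column n). Logo letter
heights are `p · (2 − H)` bits with no small-sample correction and no
pseudocounts (zero-probability letters have zero height). Difference logos
use the column Jensen–Shannon divergence (base 2) as stack height, with
per-nucleotide contributions `(p_high − p_low)` rescaled so absolute
contributions sum to the divergence; the sign encodes
enrichment/depletion, swapping inputs flips all signs.

Positional enrichment (focal nucleotide vs all others, high-Z vs low-Z
sets) uses a two-sided Fisher exact test computed by exact big-integer
hypergeometric enumeration: the p-value is the sum of probabilities of all
margin-fixed tables whose probability does not exceed the observed one,
with comparisons on exact integers (no floating-point threshold slack);
empty margins give p = 1 by convention. Group ΔIRS comparisons use the
Wilcoxon rank-sum test: exact enumeration when both groups have ≤ 50
tie-free observations, otherwise the normal approximation with continuity
and tie correction. Box summaries report quartiles and 1.5×IQR whiskers.

## Expression adjustment

Gene counts are multiplied by the product of PCS values of the gene's
CDS-internal introns (UTR introns excluded; CDS membership is determined
from the union span of the gene's CDS features). Missing PCS values are
skipped — equivalent to PCS = 1 — and logged, rather than zeroing a gene on
a coverage gap; whether a depth-filtered intron's PCS should instead be
imputed is genuinely open, and skipping is the conservative choice (it
never shrinks a count based on absent evidence). Adjusted counts are left
as reals; rounding is the differential-expression tool's concern.

## Synthetic data

The generator's defaults are the study conditions the pipeline is validated
under, chosen once:

* 2000 single-intron genes on one chromosome (100 nt exons, 60 nt introns —
  fission-yeast-like sizes), ~50% minus-strand, GC 0.36;
* +4 composition A/T/C/G = 2539/1846/514/157 ÷ 5056 (the observed split
  among eligible fission-yeast introns); donors GT with 2% GC; acceptors AG;
* exon triplet per-position probabilities P(A at −3) = 0.40,
  P(A at −2) = 0.50, P(G at −1) = 0.55, giving ≈ 11% AAG — matching the
  AAG fraction among A4 introns (289/2539);
* baseline retention odds log-normal, log2 mean −5.5 ± 1 (WT IRS bulk
  around −5 to −6 at depth 500);
* knockout odds multipliers A4 ×6, C4 ×3, T4 ×1, G4 ×1.2 on non-AAG
  introns and ×1 on AAG introns;
* per-replicate fragment totals negative-binomial with mean 500 and
  dispersion 0.1 (Poisson when 0); CSR ~ Binomial(total, 1 − r) with
  r = odds/(1 + odds); retained fragments split Binomial(·, 0.5) between
  EIJR and IEJR (each retained fragment observes one junction, so the
  expected (EIJR+IEJR)/2 : CSR ratio is odds/2); A5R/A3R rates default to 0.

Counts are the primary simulation level — fast, and they exercise every
formula. The read emitter materialises a counts table as SAM (CIGARs
realising each class, placement uniform within the feasibility window,
overhangs ≥ `min_overhang`, sequences copied from the genome) and exists to
round-trip the classifier exactly. What the simulator does *not* emulate:
sequencing errors and quality variation, fragment-length and positional
coverage bias, multi-mapping, overlapping genes, transcription-level
condition effects beyond the PCS coupling, and intron-length or branch-point
diversity. Passing tests therefore demonstrate correctness of the
bookkeeping and statistics under a clean generative model, not robustness
to alignment artefacts in real libraries.

## Null calibration

With all effects at 1, mean ΔIRS is ~0, but the fraction of |Z| > 1.96 is
*not* the nominal 5%: with estimated variances at n = 4 the null statistic
is Welch-t distributed (df ≈ 3–6), whose expected exceedance is ≈ 0.10.
The calibration test therefore compares the pipeline's empirical exceedance
to a Monte-Carlo oracle of the same statistic on normal replicates (within
three combined binomial standard deviations) instead of to the
normal-theory constant. Quartile selection, not a Z p-value threshold, is
what the downstream analysis uses, so the small-n inflation does not affect
the group comparisons.

## Problem sizes

The test suite and acceptance script use 2000 introns at depth 500 with
4 + 4 replicates for the effect-recovery and null runs, and 200
mixed-strand segments for the read-level round trip; these sizes make every
group (including G4 at ~3%) large enough for stable medians while keeping a
full run in seconds.
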