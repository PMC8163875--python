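"""Splice-site sequence windows, frequency matrices, logos and enrichment.

Windows are extracted in coding-strand orientation around both splice sites:
the 5'SS window covers the last ``exon5`` exonic nucleotides (positions
-exon5..-1) plus the first ``intron5`` intron nucleotides (+1..+intron5);
the 3'SS window covers the last ``intron3`` intron nucleotides plus the first
``exon3`` nucleotides of the downstream exon.

Information-content logos use column height 2 - H (Shannon entropy, bits)
with letter height = probability x column height and no small-sample
correction.  Difference logos compare two position frequency matrices
column-wise by Jensen-Shannon divergence (base 2); per-nucleotide signed
contributions are the probability differences rescaled so their absolute sum
equals the column divergence — enriched letters plot above the axis,
depleted below.

Positional enrichment of one nucleotide between two intron sets is tested by
a two-sided Fisher exact test computed by exact big-integer hypergeometric
enumeration (the sum of all table probabilities not exceeding the observed
table's).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .segments import IntronSegment, _fetch, reverse_complement

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class WindowSpec:
    exon5: int = 3   # exonic positions upstream of the 5'SS
    intron5: int = 6  # intron positions downstream of the 5'SS
    intron3: int = 6  # intron positions upstream of the 3'SS
    exon3: int = 3   # exonic positions downstream of the 3'SS


def five_prime_positions(spec: WindowSpec) -> list[str]:
    return [f"-{i}" for i in range(spec.exon5, 0, -1)] + \
        [f"+{i}" for i in range(1, spec.intron5 + 1)]


def three_prime_positions(spec: WindowSpec) -> list[str]:
    return [f"-{i}" for i in range(spec.intron3, 0, -1)] + \
        [f"+{i}" for i in range(1, spec.exon3 + 1)]


def splice_site_windows(
    segments: Iterable[IntronSegment],
    genome,
    spec: WindowSpec | None = None,
) -> pd.DataFrame:
    """Fixed-width 5'SS and 3'SS sequences per segment, coding strand.

    Segments whose intron is too short for both windows are skipped with a
    warning.  Returns columns segment_id, five_prime, three_prime.
    """
    spec = spec or WindowSpec()
    rows = []
    for seg in segments:
        if seg.intron_length < max(spec.intron5, spec.intron3):
            logger.warning("segment %s too short for window, skipped", seg.segment_id)
            continue
        if seg.strand == "+":
            five = _fetch(genome, seg.chrom,
                          seg.intron_start - spec.exon5,
                          seg.intron_start + spec.intron5)
            three = _fetch(genome, seg.chrom,
                           seg.intron_end - spec.intron3,
                           seg.intron_end + spec.exon3)
        else:
            five = reverse_complement(
                _fetch(genome, seg.chrom,
                       seg.intron_end - spec.intron5,
                       seg.intron_end + spec.exon5))
            three = reverse_complement(
                _fetch(genome, seg.chrom,
                       seg.intron_start - spec.exon3,
                       seg.intron_start + spec.intron3))
        rows.append({"segment_id": seg.segment_id,
                     "five_prime": five, "three_prime": three})
    return pd.DataFrame(rows, columns=["segment_id", "five_prime", "three_prime"])


@dataclass
class PositionFrequencyMatrix:
    """Per-position nucleotide counts over aligned equal-length sequences.

    ``counts`` is positions x ACGT; ambiguous bases are excluded from their
    column, so ``n`` (valid sequences) is tracked per column.
    """

    counts: pd.DataFrame  # index = position labels, columns = ACGT
    n: pd.Series          # valid (non-ambiguous) sequences per column

    @classmethod
    def from_sequences(
        cls,
        sequences: Sequence[str],
        positions: Sequence[str] | None = None,
    ) -> "PositionFrequencyMatrix":
        sequences = [s.upper() for s in sequences]
        if not sequences:
            raise ValueError("no sequences")
        width = len(sequences[0])
        if any(len(s) != width for s in sequences):
            raise ValueError("sequences must have equal length")
        if positions is None:
            positions = [str(i + 1) for i in range(width)]
        elif len(positions) != width:
            raise ValueError("positions must match sequence width")
        counts = np.zeros((width, 4), dtype=int)
        lut = {nt: j for j, nt in enumerate(NUCLEOTIDES)}
        for seq in sequences:
            for i, base in enumerate(seq):
                j = lut.get(base)
                if j is not None:
                    counts[i, j] += 1
        frame = pd.DataFrame(counts, index=list(positions), columns=list(NUCLEOTIDES))
        return cls(counts=frame, n=frame.sum(axis=1))

    @property
    def positions(self) -> list[str]:
        return list(self.counts.index)

    def probabilities(self) -> pd.DataFrame:
        n = self.n.replace(0, np.nan)
        return self.counts.div(n, axis=0).fillna(0.0)


def information_logo(pfm: PositionFrequencyMatrix) -> pd.DataFrame:
    """Letter heights in bits: height = p * (2 - H(column))."""
    probs = pfm.probabilities().to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    entropy = -plogp.sum(axis=1)
    column_height = np.where(pfm.n.to_numpy() > 0, 2.0 - entropy, 0.0)
    heights = probs * column_height[:, None]
    return pd.DataFrame(heights, index=pfm.positions, columns=list(NUCLEOTIDES))


def _jensen_shannon(p: np.ndarray, q: np.ndarray) -> float:
    m = (p + q) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_p = np.where(p > 0, p * np.log2(p / m), 0.0).sum()
        kl_q = np.where(q > 0, q * np.log2(q / m), 0.0).sum()
    return float((kl_p + kl_q) / 2)


def difference_logo(
    pfm_high: PositionFrequencyMatrix,
    pfm_low: PositionFrequencyMatrix,
) -> pd.DataFrame:
    """Column-wise JSD difference logo (high minus low).

    Returns one row per position with per-nucleotide signed contributions
    (summing in absolute value to the column divergence) plus a
    ``divergence`` column in bits.  Identical inputs give all-zero rows;
    swapping the inputs flips every sign and keeps the divergence.
    """
    if pfm_high.positions != pfm_low.positions:
        raise ValueError("position sets differ between matrices")
    p_high = pfm_high.probabilities().to_numpy()
    p_low = pfm_low.probabilities().to_numpy()
    rows = []
    for i, pos in enumerate(pfm_high.positions):
        jsd = _jensen_shannon(p_high[i], p_low[i])
        diff = p_high[i] - p_low[i]
        denom = np.abs(diff).sum()
        contrib = diff * (jsd / denom) if denom > 0 else np.zeros(4)
        rows.append({"position": pos,
                     **dict(zip(NUCLEOTIDES, contrib)),
                     "divergence": jsd})
    return pd.DataFrame(rows).set_index("position")


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table, by exact enumeration.

    Sums hypergeometric probabilities of all tables (fixed margins) whose
    probability does not exceed the observed table's; comparisons are done on
    exact integers, the final p as a Fraction converted to float.  An empty
    margin returns p = 1 by convention.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    observed = comb(r1, a) * comb(r2, c1 - a)
    numerator = 0
    for k in range(kmin, kmax + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        if w <= observed:
            numerator += w
    return float(Fraction(numerator, comb(n, c1)))


def positional_fisher(
    high_counts: Mapping[str, int],
    low_counts: Mapping[str, int],
    focal_nt: str,
) -> float:
    """Two-sided Fisher p for focal-vs-other nucleotide at one position,
    comparing the high-Z and low-Z intron sets."""
    focal_nt = focal_nt.upper()
    if focal_nt not in NUCLEOTIDES:
        raise ValueError(f"focal_nt must be one of {NUCLEOTIDES}")
    hf = int(high_counts.get(focal_nt, 0))
    lf = int(low_counts.get(focal_nt, 0))
    ho = sum(int(high_counts.get(nt, 0)) for nt in NUCLEOTIDES) - hf
    lo = sum(int(low_counts.get(nt, 0)) for nt in NUCLEOTIDES) - lf
    return fisher_exact_two_sided([[hf, ho], [lf, lo]])


def render_logo(heights: pd.DataFrame, path: str, title: str | None = None) -> None:
    """Render a (difference) logo to SVG/PNG with matplotlib.

    Letters are drawn as scaled text paths stacked per column; negative
    heights (difference logos) stack below the axis.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    font = FontProperties(weight="bold", family="monospace")
    fig, ax = plt.subplots(figsize=(0.6 * len(heights) + 1, 2.5))
    nts = [nt for nt in NUCLEOTIDES if nt in heights.columns]
    for x, (_, row) in enumerate(heights[nts].iterrows()):
        for sign in (1, -1):
            base = 0.0
            items = sorted(
                ((nt, row[nt]) for nt in nts if sign * row[nt] > 0),
                key=lambda kv: abs(kv[1]),
            )
            for nt, h in items:
                tp = TextPath((0, 0), nt, size=1, prop=font)
                bbox = tp.get_extents()
                scale = Affine2D() \
                    .translate(-bbox.x0, -bbox.y0) \
                    .scale(0.9 / bbox.width, abs(h) / bbox.height) \
                    .translate(x + 0.05, base if sign > 0 else base - abs(h))
                ax.add_patch(PathPatch(tp.transformed(scale),
                                       color=colors[nt], lw=0))
                base += sign * abs(h)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xticks([x + 0.5 for x in range(len(heights))])
    ax.set_xticklabels(heights.index, fontsize=8)
    ax.set_xlim(0, len(heights))
    lo = min(heights[nts].where(heights[nts] < 0).sum(axis=1).min(), 0)
    hi = max(heights[nts].where(heights[nts] > 0).sum(axis=1).max(), 0.1)
    ax.set_ylim(lo * 1.1 - 0.02, hi * 1.1)
    ax.set_ylabel("bits")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
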