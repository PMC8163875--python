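"""Splicing metrics: coverage, IRS, PCS, replicate Z-scores and filters.

For one intron segment in one sample with junction-read class counts, the
informative coverage is

    cov(Total) = (EIJR + IEJR)/2 + A5R + A3R + CSR

the Intron Retention Score is

    IRS = log2( (EIJR + IEJR + 0.1) / (2*CSR + 0.1) )

and the Proportion of Canonical Splicing is

    PCS = CSR / cov(Total)            (undefined when cov(Total) = 0)

The 0.1 pseudocount keeps IRS finite for any non-negative counts and is fixed
(not configurable) so scores stay comparable across analyses.  Retention
differences between two conditions are ranked per intron by a two-sample
Z-score on replicate IRS values,

    Z = (mean_KO - mean_WT) / sqrt(var_KO/n_KO + var_WT/n_WT)

using sample variances (ddof=1); with quadruplicates on both sides this is
the sigma^2/4 form.  Introns are then split by Z-score quartiles into
high / mid / low retention-difference classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PSEUDOCOUNT = 0.1

QUARTILE_HIGH = "high"
QUARTILE_MID = "mid"
QUARTILE_LOW = "low"


def _check_counts(**counts: float) -> None:
    for name, value in counts.items():
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")


def total_coverage(eijr=0, iejr=0, csr=0, a5r=0, a3r=0, **_ignored) -> float:
    """cov(Total) = (EIJR+IEJR)/2 + A5R + A3R + CSR."""
    _check_counts(eijr=eijr, iejr=iejr, csr=csr, a5r=a5r, a3r=a3r)
    return (eijr + iejr) / 2 + a5r + a3r + csr


def intron_retention_score(eijr=0, iejr=0, csr=0, **_ignored) -> float:
    """IRS = log2((EIJR+IEJR+0.1) / (2*CSR+0.1)); finite for all counts."""
    _check_counts(eijr=eijr, iejr=iejr, csr=csr)
    return math.log2((eijr + iejr + PSEUDOCOUNT) / (2 * csr + PSEUDOCOUNT))


def proportion_canonical_splicing(eijr=0, iejr=0, csr=0, a5r=0, a3r=0, **_ignored) -> float:
    """PCS = CSR / cov(Total); NaN (missing, never 0) when cov(Total) = 0."""
    total = total_coverage(eijr, iejr, csr, a5r, a3r)
    if total == 0:
        return math.nan
    return csr / total


def qpcr_irs(retained_abundance: float, spliced_abundance: float) -> float:
    """IRS from isoform abundances: log2(retained / spliced).

    The RT-qPCR / minigene definition — no pseudocount, both abundances must
    be positive.
    """
    if retained_abundance <= 0 or spliced_abundance <= 0:
        raise ValueError("abundances must be > 0")
    return math.log2(retained_abundance / spliced_abundance)


def compute_metrics(counts: pd.DataFrame) -> pd.DataFrame:
    """Per (segment, sample) IRS / PCS / cov(Total) from a counts table."""
    eijr = counts["eijr"].to_numpy(float)
    iejr = counts["iejr"].to_numpy(float)
    csr = counts["csr"].to_numpy(float)
    a5r = counts["a5r"].to_numpy(float)
    a3r = counts["a3r"].to_numpy(float)
    if (eijr < 0).any() or (iejr < 0).any() or (csr < 0).any() \
            or (a5r < 0).any() or (a3r < 0).any():
        raise ValueError("negative counts")
    total = (eijr + iejr) / 2 + a5r + a3r + csr
    irs = np.log2((eijr + iejr + PSEUDOCOUNT) / (2 * csr + PSEUDOCOUNT))
    with np.errstate(invalid="ignore", divide="ignore"):
        pcs = np.where(total > 0, csr / np.where(total > 0, total, 1.0), np.nan)
    return pd.DataFrame(
        {
            "segment_id": counts["segment_id"].to_numpy(),
            "sample_id": counts["sample_id"].to_numpy(),
            "irs": irs,
            "pcs": pcs,
            "cov_total": total,
        }
    )


def zscore(irs_wt: Sequence[float], irs_ko: Sequence[float]) -> float:
    """Two-sample Z for the IRS difference (KO minus WT).

    Uses sample variances / n per condition; antisymmetric under swapping the
    conditions.  With both variances zero the score is 0 for equal means and
    +/-inf otherwise (sorts to the extreme end).
    """
    wt = np.asarray(irs_wt, float)
    ko = np.asarray(irs_ko, float)
    if wt.size < 2 or ko.size < 2:
        raise ValueError("need >= 2 replicates per condition")
    diff = ko.mean() - wt.mean()
    denom = math.sqrt(ko.var(ddof=1) / ko.size + wt.var(ddof=1) / wt.size)
    if denom == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return diff / denom


@dataclass
class FilterSpec:
    """Eligibility thresholds; both count filters are strict (>)."""

    min_total: float = 10.0
    min_mean_csr: float = 10.0
    donor_pattern: str = "GY"
    acceptor_pattern: str = "AG"

    def __post_init__(self) -> None:
        if self.min_total < 0 or self.min_mean_csr < 0:
            raise ValueError("thresholds must be >= 0")


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "Y": "CT", "R": "AG", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "N": "ACGT",
}


def _matches(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        s in _IUPAC.get(p, p) for s, p in zip(seq.upper(), pattern.upper())
    )


def filter_introns(
    counts: pd.DataFrame,
    conditions: Mapping[str, str],
    splice_dinucleotides: Mapping[str, tuple[str, str]],
    spec: FilterSpec | None = None,
) -> list[str]:
    """Eligible segments for the retention-difference analysis.

    A segment is retained iff its donor matches GY and acceptor AG, its
    cov(Total) exceeds ``min_total`` in *every* replicate of both conditions,
    and its mean CSR exceeds ``min_mean_csr`` in at least one condition
    ("either strain").  Segments missing counts in any sample fail the depth
    filter.

    Parameters
    ----------
    counts:
        Long counts table with segment_id, sample_id, csr, total columns.
    conditions:
        sample_id -> condition label (exactly two conditions).
    splice_dinucleotides:
        segment_id -> (donor, acceptor) on the coding strand; use
        :func:`splice_dinucleotides_from_segments` for IntronSegment input.
    """
    spec = spec or FilterSpec()
    cond_labels = sorted(set(conditions.values()))
    if len(cond_labels) != 2:
        raise ValueError(f"expected exactly two conditions, got {cond_labels}")
    samples = list(conditions)
    sub = counts[counts["sample_id"].isin(samples)]
    total = sub.pivot_table(index="segment_id", columns="sample_id",
                            values="total", aggfunc="first")
    csr = sub.pivot_table(index="segment_id", columns="sample_id",
                          values="csr", aggfunc="first")
    eligible = []
    for segment_id in total.index:
        pair = splice_dinucleotides.get(segment_id)
        if pair is None:
            continue
        donor, acceptor = pair
        if not (_matches(donor, spec.donor_pattern)
                and _matches(acceptor, spec.acceptor_pattern)):
            continue
        tot_row = total.loc[segment_id].reindex(samples)
        if tot_row.isna().any() or not (tot_row > spec.min_total).all():
            continue
        csr_row = csr.loc[segment_id].reindex(samples)
        means = [
            csr_row[[s for s in samples if conditions[s] == label]].mean()
            for label in cond_labels
        ]
        if any(m > spec.min_mean_csr for m in means):
            eligible.append(segment_id)
    return eligible


def splice_dinucleotides_from_segments(segments) -> dict[str, tuple[str, str]]:
    return {
        s.segment_id: (s.donor_dinucleotide, s.acceptor_dinucleotide)
        for s in segments
    }


def zscore_table(
    metrics: pd.DataFrame,
    conditions: Mapping[str, str],
    wt: str = "WT",
    ko: str = "KO",
    segment_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Replicate-aggregated IRS means/SDs and Z-score per segment."""
    wt_samples = [s for s, c in conditions.items() if c == wt]
    ko_samples = [s for s, c in conditions.items() if c == ko]
    if len(wt_samples) < 2 or len(ko_samples) < 2:
        raise ValueError("need >= 2 replicates per condition")
    irs = metrics.pivot_table(index="segment_id", columns="sample_id",
                              values="irs", aggfunc="first")
    if segment_ids is not None:
        irs = irs.reindex([s for s in segment_ids if s in irs.index])
    rows = []
    for segment_id, row in irs.iterrows():
        w = row[wt_samples].to_numpy(float)
        k = row[ko_samples].to_numpy(float)
        if np.isnan(w).any() or np.isnan(k).any():
            continue
        rows.append(
            {
                "segment_id": segment_id,
                "mu_wt": w.mean(),
                "mu_ko": k.mean(),
                "sigma_wt": w.std(ddof=1),
                "sigma_ko": k.std(ddof=1),
                "n_wt": w.size,
                "n_ko": k.size,
                "z": zscore(w, k),
            }
        )
    return pd.DataFrame(rows)


def quartile_partition(z_by_segment: Mapping[str, float] | pd.Series) -> pd.Series:
    """Split segments by Z-score quartiles into high / mid / low.

    ``high`` holds Z strictly above the first (descending) quartile boundary,
    ``low`` strictly below the third; everything else (including exact
    boundary ties) is ``mid``.  With all values equal, both extreme classes
    are empty.  Input order is made deterministic by sorting on segment id.
    """
    series = pd.Series(dict(z_by_segment), dtype=float).sort_index()
    if series.size < 4:
        raise ValueError("need >= 4 segments for a quartile split")
    q1 = float(np.quantile(series.to_numpy(), 0.75))  # first in descending order
    q3 = float(np.quantile(series.to_numpy(), 0.25))
    labels = np.full(series.size, QUARTILE_MID, dtype=object)
    labels[series.to_numpy() > q1] = QUARTILE_HIGH
    labels[series.to_numpy() < q3] = QUARTILE_LOW
    return pd.Series(labels, index=series.index, name="quartile_class")
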