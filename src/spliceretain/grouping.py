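"""Intron grouping and retention-difference comparisons.

Introns are grouped two ways:

* by the intron's fourth nucleotide (A4/T4/C4/G4) — the position that pairs
  with the U6 snRNA m6A during 5'SS recognition;
* by the 5' exon terminal triplet (positions -3..-1), the sequence read by
  U5 snRNA loop I, coded per position as A (adenosine) vs B (not A) at -3 and
  -2 and G vs H (not G) at -1, giving the eight classes AAG, BAG, ABG, AAH,
  BBG, BAH, ABH, BBH.

Per-intron retention change is ΔIRS = mean IRS(KO) - mean IRS(WT).  Groups
are compared by empirical cumulative curves, pairwise two-sided Wilcoxon
rank-sum tests and box-plot summaries (quartiles, 1.5x IQR whiskers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .segments import IntronSegment

logger = logging.getLogger(__name__)

FOURTH_NT_GROUPS = ("A4", "T4", "C4", "G4")
TRIPLET_GROUPS = ("AAG", "BAG", "ABG", "AAH", "BBG", "BAH", "ABH", "BBH")


def classify_fourth_nucleotide(segment: IntronSegment | str) -> str | None:
    """A4/T4/C4/G4 from intron position +4; None for ambiguous bases."""
    seq = segment if isinstance(segment, str) else segment.intron_seq_5prime
    if len(seq) < 4:
        raise ValueError("intron sequence shorter than 4 nt")
    nt = seq[3].upper()
    return f"{nt}4" if nt in "ATCG" else None


def classify_exon_triplet(segment: IntronSegment | str) -> str | None:
    """Triplet class of the 5' exon positions -3..-1; None on ambiguity."""
    triplet = (segment if isinstance(segment, str) else segment.exon_triplet).upper()
    if len(triplet) != 3:
        raise ValueError("exon triplet must be 3 nt")
    if any(nt not in "ACGT" for nt in triplet):
        return None
    code = ("A" if triplet[0] == "A" else "B") \
        + ("A" if triplet[1] == "A" else "B") \
        + ("G" if triplet[2] == "G" else "H")
    return code


def delta_irs(
    metrics: pd.DataFrame,
    conditions: Mapping[str, str],
    wt: str = "WT",
    ko: str = "KO",
) -> pd.DataFrame:
    """Per-segment ΔIRS = mean IRS over KO replicates - mean over WT.

    Segments missing either condition entirely are omitted.
    """
    wt_samples = [s for s, c in conditions.items() if c == wt]
    ko_samples = [s for s, c in conditions.items() if c == ko]
    irs = metrics.pivot_table(index="segment_id", columns="sample_id",
                              values="irs", aggfunc="first")
    rows = []
    for segment_id, row in irs.iterrows():
        w = row.reindex(wt_samples).dropna()
        k = row.reindex(ko_samples).dropna()
        if w.empty or k.empty:
            continue
        rows.append({"segment_id": segment_id, "delta": k.mean() - w.mean()})
    return pd.DataFrame(rows, columns=["segment_id", "delta"])


def rank_sum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both groups have <= 50 observations and the pooled
    sample is tie-free; otherwise the normal approximation with continuity
    and tie correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 50 and y.size <= 50 and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method, use_continuity=True).pvalue)


def _box_summary(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "q1": q1, "median": med, "q3": q3,
        "whisker_low": inside.min() if inside.size else q1,
        "whisker_high": inside.max() if inside.size else q3,
        "n": int(values.size),
    }


@dataclass
class GroupComparison:
    cdf: pd.DataFrame       # columns: group, value, cdf (shared grid)
    pvalues: pd.DataFrame   # symmetric pairwise rank-sum p matrix
    box: pd.DataFrame       # per-group quartiles / whiskers / n


def group_compare(deltas_by_group: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Compare ΔIRS distributions across intron groups.

    Empty groups are excluded with a warning.  The cumulative curves are
    empirical CDFs evaluated on the shared grid of all observed values.
    """
    groups = {}
    for name, values in deltas_by_group.items():
        arr = np.asarray(values, float)
        if arr.size == 0:
            logger.warning("group %s is empty, excluded", name)
            continue
        groups[name] = arr
    if not groups:
        raise ValueError("all groups empty")

    grid = np.unique(np.concatenate(list(groups.values())))
    cdf_rows = []
    for name, arr in groups.items():
        sorted_arr = np.sort(arr)
        cdf = np.searchsorted(sorted_arr, grid, side="right") / arr.size
        cdf_rows.append(pd.DataFrame({"group": name, "value": grid, "cdf": cdf}))

    names = list(groups)
    pmat = pd.DataFrame(np.ones((len(names), len(names))),
                        index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            p = rank_sum_p(groups[a], groups[b])
            pmat.loc[a, b] = pmat.loc[b, a] = p

    box = pd.DataFrame({name: _box_summary(arr) for name, arr in groups.items()}).T
    return GroupComparison(cdf=pd.concat(cdf_rows, ignore_index=True),
                           pvalues=pmat, box=box)
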