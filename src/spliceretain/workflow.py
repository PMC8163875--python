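"""Convenience driver chaining the per-stage functions.

Runs the standard retention-difference analysis on a long junction-count
table: per-sample IRS/PCS metrics, GY-AG + depth eligibility filtering,
replicate Z-scores, quartile classes and per-intron ΔIRS.  Each stage is a
plain library function; this wrapper only wires them together.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .grouping import delta_irs
from .metrics import (
    FilterSpec,
    compute_metrics,
    filter_introns,
    quartile_partition,
    zscore_table,
)


@dataclass
class RetentionAnalysis:
    metrics: pd.DataFrame       # segment x sample IRS / PCS / cov(Total)
    eligible: list[str]         # segment ids passing the GY-AG + depth filter
    zscores: pd.DataFrame       # per-eligible-segment Z table + quartile_class
    deltas: pd.DataFrame        # per-eligible-segment ΔIRS (KO - WT)


def run_retention_analysis(
    counts: pd.DataFrame,
    conditions: Mapping[str, str],
    splice_dinucleotides: Mapping[str, tuple[str, str]],
    spec: FilterSpec | None = None,
    wt: str = "WT",
    ko: str = "KO",
) -> RetentionAnalysis:
    metrics = compute_metrics(counts)
    eligible = filter_introns(counts, conditions, splice_dinucleotides, spec)
    ztab = zscore_table(metrics, conditions, wt=wt, ko=ko, segment_ids=eligible)
    quart = quartile_partition(dict(zip(ztab["segment_id"], ztab["z"])))
    ztab = ztab.copy()
    ztab["quartile_class"] = quart.reindex(ztab["segment_id"]).to_numpy()
    deltas = delta_irs(
        metrics[metrics["segment_id"].isin(eligible)], conditions, wt=wt, ko=ko
    )
    return RetentionAnalysis(
        metrics=metrics, eligible=eligible, zscores=ztab, deltas=deltas
    )
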