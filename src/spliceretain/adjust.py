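"""Splicing-adjusted gene-level expression counts.

A gene whose introns are poorly spliced accumulates unproductive pre-mRNA
reads; comparing raw counts between strains then confounds transcription
with splicing.  The correction multiplies each gene's raw count by the
product of the PCS values of its CDS-internal introns:

    adjusted = raw * prod_k PCS_k

so a gene with PCS = 1 everywhere (or no CDS introns) is unchanged and the
adjusted count never exceeds the raw count.  Missing PCS values (introns
with zero informative coverage in that sample) are skipped — treated as 1 —
and counted in a warning log.  Rounding is left to the downstream
differential-expression tool.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

from .segments import IntronSegment, _looks_like_path, _transcript_gene_map

logger = logging.getLogger(__name__)


def splicing_adjusted_counts(raw: float, pcs_list: Sequence[float]) -> float:
    """adjusted = raw x product of non-missing PCS values in [0, 1]."""
    if raw < 0:
        raise ValueError("raw count must be non-negative")
    product = 1.0
    skipped = 0
    for pcs in pcs_list:
        if pcs is None or (isinstance(pcs, float) and math.isnan(pcs)):
            skipped += 1
            continue
        if not 0.0 <= pcs <= 1.0:
            raise ValueError(f"PCS outside [0,1]: {pcs}")
        product *= pcs
    if skipped:
        logger.warning("skipped %d missing PCS values", skipped)
    return raw * product


def cds_intron_map(
    annotation: str,
    segments: Iterable[IntronSegment],
) -> dict[str, list[str]]:
    """Map gene -> ordered CDS-internal intron segment ids.

    An intron counts as CDS-internal when it lies within the CDS span
    (min CDS start .. max CDS end across the gene's transcripts); UTR
    introns are excluded.  Segment order follows intron_index.
    """
    db = gffutils.create_db(
        annotation, ":memory:", merge_strategy="create_unique",
        keep_order=True, from_string=not _looks_like_path(annotation),
    )
    tx2gene = _transcript_gene_map(db)
    spans: dict[str, list[int]] = {}
    for cds in db.features_of_type("CDS"):
        parent = cds.attributes.get("Parent", [None])[0]
        gene = cds.attributes.get("gene_id", [tx2gene.get(parent, parent)])[0]
        if gene is None:
            continue
        span = spans.setdefault(gene, [cds.start - 1, cds.end])
        span[0] = min(span[0], cds.start - 1)
        span[1] = max(span[1], cds.end)
    mapping: dict[str, list[str]] = {}
    for seg in sorted(segments, key=lambda s: (s.gene_id, s.intron_index)):
        span = spans.get(seg.gene_id)
        if span and span[0] <= seg.intron_start and seg.intron_end <= span[1]:
            mapping.setdefault(seg.gene_id, []).append(seg.segment_id)
    return mapping


def adjust_table(
    gene_counts: pd.DataFrame,
    metrics: pd.DataFrame,
    gene_introns: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Adjusted gene x sample count matrix.

    Parameters
    ----------
    gene_counts:
        Raw counts, genes as index and samples as columns.
    metrics:
        Long metrics table with segment_id, sample_id, pcs columns.
    gene_introns:
        gene -> CDS intron segment ids (see :func:`cds_intron_map`).  Genes
        absent from the map pass through unchanged.
    """
    pcs = metrics.pivot_table(index="segment_id", columns="sample_id",
                              values="pcs", aggfunc="first")
    adjusted = gene_counts.astype(float).copy()
    for gene in gene_counts.index:
        seg_ids = gene_introns.get(gene)
        if not seg_ids:
            continue
        for sample in gene_counts.columns:
            values = [
                pcs.at[seg, sample] if (seg in pcs.index and sample in pcs.columns)
                else math.nan
                for seg in seg_ids
            ]
            adjusted.at[gene, sample] = splicing_adjusted_counts(
                float(gene_counts.at[gene, sample]), values
            )
    return adjusted
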