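import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spliceretain.metrics import (
    FilterSpec,
    compute_metrics,
    filter_introns,
    intron_retention_score,
    proportion_canonical_splicing,
    qpcr_irs,
    quartile_partition,
    total_coverage,
    zscore,
    zscore_table,
)

counts_st = st.integers(min_value=0, max_value=500)


@pytest.mark.parametrize(
    "counts,expected",
    [
        (dict(eijr=10, iejr=14, a5r=2, a3r=3, csr=30), 47.0),
        (dict(), 0.0),
        (dict(eijr=1), 0.5),
    ],
)
def test_total_coverage_examples(counts, expected):
    assert total_coverage(**counts) == expected


@pytest.mark.parametrize(
    "counts,expected",
    [
        (dict(), 0.0),
        (dict(eijr=10, iejr=10, csr=10), 0.0),  # balance point
        (dict(eijr=20, iejr=20, csr=5), math.log2(40.1 / 10.1)),
    ],
)
def test_intron_retention_score_examples(counts, expected):
    assert intron_retention_score(**counts) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "counts,expected",
    [
        (dict(csr=30, eijr=10, iejr=14, a5r=2, a3r=3), 30 / 47),
        (dict(csr=10), 1.0),
        (dict(csr=0, eijr=2, iejr=2), 0.0),
    ],
)
def test_proportion_canonical_splicing_examples(counts, expected):
    assert proportion_canonical_splicing(**counts) == pytest.approx(expected)


def test_pcs_undefined_at_zero_coverage_is_missing_not_zero():
    assert math.isnan(proportion_canonical_splicing())


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        total_coverage(eijr=-1)
    with pytest.raises(ValueError):
        intron_retention_score(csr=-2)


@given(e=counts_st, i=counts_st, c=counts_st)
@settings(max_examples=200, deadline=None)
def test_irs_monotone_in_retention_and_splicing(e, i, c):
    base = intron_retention_score(eijr=e, iejr=i, csr=c)
    assert intron_retention_score(eijr=e + 1, iejr=i, csr=c) > base
    assert intron_retention_score(eijr=e, iejr=i, csr=c + 1) < base


@given(e=counts_st, i=counts_st, c=counts_st, a5=counts_st, a3=counts_st)
@settings(max_examples=200, deadline=None)
def test_pcs_complements_noncanonical_fraction(e, i, c, a5, a3):
    total = total_coverage(e, i, c, a5, a3)
    if total == 0:
        return
    pcs = proportion_canonical_splicing(e, i, c, a5, a3)
    noncanonical = ((e + i) / 2 + a5 + a3) / total
    assert 0.0 <= pcs <= 1.0
    assert pcs + noncanonical == pytest.approx(1.0, abs=1e-12)


def test_zscore_examples():
    assert zscore([1, 1, 1, 1], [1, 1, 1, 1]) == 0.0
    base = np.array([-1.5, -0.5, 0.5, 1.5]) / math.sqrt(5 / 3)  # sample SD 1
    assert zscore(base, base + 2) == pytest.approx(2 / math.sqrt(0.5), rel=1e-9)


def test_zscore_degenerate_variances():
    assert zscore([1, 1], [2, 2]) == math.inf
    assert zscore([2, 2], [1, 1]) == -math.inf


@given(
    wt=st.lists(st.floats(-10, 10), min_size=2, max_size=8),
    ko=st.lists(st.floats(-10, 10), min_size=2, max_size=8),
)
@settings(max_examples=300, deadline=None)
def test_zscore_antisymmetric_and_matches_oracle(wt, ko):
    z = zscore(wt, ko)
    assert zscore(ko, wt) == pytest.approx(-z, abs=1e-12) or (
        math.isinf(z) and zscore(ko, wt) == -z
    )
    # independent oracle from statistics module
    mw, mk = statistics.fmean(wt), statistics.fmean(ko)
    vw, vk = statistics.variance(wt), statistics.variance(ko)
    denom = math.sqrt(vk / len(ko) + vw / len(wt))
    if denom > 0:
        assert z == pytest.approx((mk - mw) / denom, abs=1e-12)


def test_quartile_partition_descending_quartiles():
    labels = quartile_partition({f"s{i}": float(i) for i in range(1, 9)})
    assert set(labels[labels == "high"].index) == {"s7", "s8"}
    assert set(labels[labels == "low"].index) == {"s1", "s2"}
    assert (labels[["s3", "s4", "s5", "s6"]] == "mid").all()


def test_quartile_partition_all_equal_degenerate():
    labels = quartile_partition({f"s{i}": 1.0 for i in range(10)})
    assert (labels == "mid").all()


def test_quartile_partition_matches_sorting_oracle():
    rng = np.random.default_rng(5)
    for n in (4, 17, 100, 5056, 10_000):
        z = dict(zip((f"s{i}" for i in range(n)), rng.normal(size=n)))
        labels = quartile_partition(z)
        # independent oracle: inclusive quartiles from the statistics module
        q1, _, q3 = statistics.quantiles(z.values(), n=4, method="inclusive")
        for seg, value in z.items():
            expected = "high" if value > q3 else "low" if value < q1 else "mid"
            assert labels[seg] == expected
        if n == 5056:
            assert (labels == "high").sum() == 1264


def make_counts(rows):
    return pd.DataFrame(rows, columns=["segment_id", "sample_id", "csr", "total"])


SAMPLES = {"WT_1": "WT", "WT_2": "WT", "KO_1": "KO", "KO_2": "KO"}


def counts_for(segment_id, totals, csrs):
    return [
        {"segment_id": segment_id, "sample_id": s, "csr": c, "total": t}
        for s, t, c in zip(SAMPLES, totals, csrs)
    ]


def test_filter_requires_strictly_more_than_min_total_everywhere():
    counts = make_counts(counts_for("a", [50, 10, 50, 50], [20, 20, 20, 20]))
    dinucs = {"a": ("GT", "AG")}
    assert filter_introns(counts, SAMPLES, dinucs) == []


def test_filter_mean_csr_in_either_condition_suffices():
    counts = make_counts(counts_for("a", [50, 50, 50, 50], [12, 12, 3, 3]))
    assert filter_introns(counts, SAMPLES, {"a": ("GT", "AG")}) == ["a"]


def test_filter_rejects_non_gy_ag_splice_sites():
    counts = make_counts(counts_for("a", [50, 50, 50, 50], [30, 30, 30, 30]))
    assert filter_introns(counts, SAMPLES, {"a": ("GA", "AG")}) == []
    assert filter_introns(counts, SAMPLES, {"a": ("GT", "AC")}) == []
    assert filter_introns(counts, SAMPLES, {"a": ("GC", "AG")}) == ["a"]


def test_filter_missing_sample_counts_fail_depth():
    rows = counts_for("a", [50, 50, 50, 50], [30, 30, 30, 30])[:3]
    assert filter_introns(make_counts(rows), SAMPLES, {"a": ("GT", "AG")}) == []


def test_filter_spec_validation():
    with pytest.raises(ValueError):
        FilterSpec(min_total=-1)


@pytest.mark.parametrize(
    "retained,spliced,expected",
    [(1, 1, 0.0), (8, 1, 3.0), (3, 7, math.log2(3 / 7))],
)
def test_qpcr_irs_examples(retained, spliced, expected):
    assert qpcr_irs(retained, spliced) == pytest.approx(expected, abs=1e-12)


def test_qpcr_irs_rejects_nonpositive_abundance():
    with pytest.raises(ValueError):
        qpcr_irs(0, 1)
    with pytest.raises(ValueError):
        qpcr_irs(1, -2)


def test_compute_metrics_and_zscore_table_roundtrip():
    rows = []
    for s in SAMPLES:
        shift = 30 if SAMPLES[s] == "KO" else 0
        rows.append({"segment_id": "a", "sample_id": s,
                     "eijr": 10 + shift, "iejr": 10 + shift, "csr": 100,
                     "a5r": 0, "a3r": 0})
        rows.append({"segment_id": "b", "sample_id": s,
                     "eijr": 0, "iejr": 0, "csr": 0, "a5r": 0, "a3r": 0})
    metrics = compute_metrics(pd.DataFrame(rows))
    by = metrics.set_index(["segment_id", "sample_id"])
    assert by.loc[("a", "WT_1"), "irs"] == pytest.approx(
        intron_retention_score(eijr=10, iejr=10, csr=100))
    assert math.isnan(by.loc[("b", "WT_1"), "pcs"])
    ztab = zscore_table(metrics, SAMPLES).set_index("segment_id")
    assert ztab.loc["a", "mu_ko"] > ztab.loc["a", "mu_wt"]
    assert ztab.loc["a", "z"] == zscore(
        metrics.query("segment_id == 'a' and sample_id.str.startswith('WT')")["irs"],
        metrics.query("segment_id == 'a' and sample_id.str.startswith('KO')")["irs"],
    )
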