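import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats

from spliceretain.logos import (
    PositionFrequencyMatrix,
    WindowSpec,
    difference_logo,
    fisher_exact_two_sided,
    five_prime_positions,
    information_logo,
    positional_fisher,
    splice_site_windows,
    three_prime_positions,
)
from spliceretain.segments import reverse_complement

from conftest import make_segment


@pytest.fixture(scope="module")
def toy_locus():
    exon1 = "AAAAAAACC"            # ends in ACC (positions -3..-1)
    intron = "GTAAGT" + "C" * 8 + "TTTTAG"  # 20 nt, GT..AG
    exon2 = "GGGCCCAAA"
    seq = exon1 + intron + exon2
    seg = make_segment(
        "+", exon1=(0, 9), intron=(9, 29), exon2=(29, 38),
        intron5=intron[:6], triplet="ACC",
    )
    return {"chr1": seq}, seg, exon1, intron, exon2


def test_five_prime_window_concatenates_exon_and_intron(toy_locus):
    genome, seg, exon1, intron, exon2 = toy_locus
    windows = splice_site_windows([seg], genome)
    assert windows.iloc[0].five_prime == "ACCGTAAGT"
    assert windows.iloc[0].three_prime == intron[-6:] + exon2[:3]
    assert five_prime_positions(WindowSpec()) == \
        ["-3", "-2", "-1", "+1", "+2", "+3", "+4", "+5", "+6"]
    assert three_prime_positions(WindowSpec()) == \
        ["-6", "-5", "-4", "-3", "-2", "-1", "+1", "+2", "+3"]


def test_minus_strand_window_mirrors_plus(toy_locus):
    genome, seg, *_ = toy_locus
    seq = genome["chr1"]
    mirrored = {"chr1": reverse_complement(seq)}
    length = len(seq)
    mseg = make_segment(
        "-",
        exon1=(length - 38, length - 29),
        intron=(length - 29, length - 9),
        exon2=(length - 9, length),
        intron5=seg.intron_seq_5prime, triplet=seg.exon_triplet,
    )
    fwd = splice_site_windows([seg], genome).iloc[0]
    rev = splice_site_windows([mseg], mirrored).iloc[0]
    assert rev.five_prime == fwd.five_prime
    assert rev.three_prime == fwd.three_prime


def test_window_skips_intron_shorter_than_window():
    seg = make_segment("+", exon1=(0, 100), intron=(100, 104), exon2=(104, 200),
                       intron5="GTAA", triplet="AAG")
    genome = {"chr1": "A" * 200}
    assert splice_site_windows([seg], genome).empty


def test_pfm_counts_and_ambiguity_handling():
    pfm = PositionFrequencyMatrix.from_sequences(["AC", "AG"])
    assert pfm.counts.loc["1", "A"] == 2
    assert pfm.counts.loc["2", "C"] == 1 and pfm.counts.loc["2", "G"] == 1
    assert (pfm.counts.sum(axis=1) == pfm.n).all()

    with_n = PositionFrequencyMatrix.from_sequences(["AC", "NG"])
    assert with_n.n.tolist() == [1, 2]
    assert with_n.probabilities().loc["1", "A"] == 1.0


def test_pfm_rejects_bad_input():
    with pytest.raises(ValueError):
        PositionFrequencyMatrix.from_sequences([])
    with pytest.raises(ValueError):
        PositionFrequencyMatrix.from_sequences(["AC", "ACG"])


def test_uniform_sequence_set_gives_full_height():
    pfm = PositionFrequencyMatrix.from_sequences(["GTAAGT"] * 100)
    heights = information_logo(pfm)
    assert heights.loc["1", "G"] == pytest.approx(2.0)
    assert heights.to_numpy().sum(axis=1) == pytest.approx(2.0)


def test_information_logo_entropy_arithmetic():
    pfm = PositionFrequencyMatrix.from_sequences(["A", "C", "G", "T"])
    assert information_logo(pfm).to_numpy().sum() == pytest.approx(0.0)
    half = PositionFrequencyMatrix.from_sequences(["A", "A", "C", "C"])
    heights = information_logo(half)
    assert heights.loc["1", "A"] == pytest.approx(0.5)
    assert heights.loc["1", "C"] == pytest.approx(0.5)


def test_difference_logo_identical_inputs_zero():
    pfm = PositionFrequencyMatrix.from_sequences(["GTAAGT", "GTATGT"])
    diff = difference_logo(pfm, pfm)
    assert np.allclose(diff.to_numpy(), 0.0)


def test_difference_logo_disjoint_point_masses():
    high = PositionFrequencyMatrix.from_sequences(["A"] * 5)
    low = PositionFrequencyMatrix.from_sequences(["T"] * 7)
    diff = difference_logo(high, low)
    assert diff.loc["1", "divergence"] == pytest.approx(1.0)  # JSD of A vs T
    assert diff.loc["1", "A"] > 0 > diff.loc["1", "T"]
    assert abs(diff.loc["1", list("ACGT")]).sum() == pytest.approx(1.0)


def test_difference_logo_antisymmetric_under_swap():
    rng = np.random.default_rng(0)
    seqs_a = ["".join(rng.choice(list("ACGT"), 4)) for _ in range(30)]
    seqs_b = ["".join(rng.choice(list("ACGT"), 4)) for _ in range(20)]
    a = PositionFrequencyMatrix.from_sequences(seqs_a)
    b = PositionFrequencyMatrix.from_sequences(seqs_b)
    ab, ba = difference_logo(a, b), difference_logo(b, a)
    assert np.allclose(ab["divergence"], ba["divergence"])
    assert np.allclose(ab[list("ACGT")].to_numpy(), -ba[list("ACGT")].to_numpy())
    # stack heights sum to the column divergence
    assert np.allclose(ab[list("ACGT")].abs().sum(axis=1), ab["divergence"])


def test_difference_logo_position_mismatch_rejected():
    a = PositionFrequencyMatrix.from_sequences(["AC"], positions=["-1", "+1"])
    b = PositionFrequencyMatrix.from_sequences(["AC"], positions=["+1", "+2"])
    with pytest.raises(ValueError):
        difference_logo(a, b)


def test_fisher_worked_examples_exact():
    assert fisher_exact_two_sided([[8, 2], [2, 8]]) == float(Fraction(4252, 184756))
    assert fisher_exact_two_sided([[5, 5], [5, 5]]) == 1.0
    assert fisher_exact_two_sided([[10, 0], [0, 10]]) == \
        pytest.approx(2 / comb(20, 10), rel=1e-15)
    assert fisher_exact_two_sided([[0, 0], [5, 5]]) == 1.0  # empty margin
    with pytest.raises(ValueError):
        fisher_exact_two_sided([[1, -1], [0, 2]])


def test_fisher_agrees_with_scipy_small_sweep():
    for r1 in range(9):
        for r2 in range(9):
            for a in range(r1 + 1):
                for c in range(r2 + 1):
                    table = [[a, r1 - a], [c, r2 - c]]
                    ours = fisher_exact_two_sided(table)
                    ref = stats.fisher_exact(table, alternative="two-sided")[1]
                    assert math.isclose(ours, ref, abs_tol=1e-12), table


def test_positional_fisher_counts_interface():
    p = positional_fisher({"A": 8, "C": 1, "G": 1}, {"A": 2, "T": 8}, "A")
    assert p == fisher_exact_two_sided([[8, 2], [2, 8]])
    with pytest.raises(ValueError):
        positional_fisher({"A": 1}, {"C": 1}, "N")


def test_render_logo_writes_figure(tmp_path):
    pfm = PositionFrequencyMatrix.from_sequences(["GTAAGT", "GTATGT", "GTAAGT"])
    out = tmp_path / "logo.svg"
    from spliceretain.logos import render_logo

    render_logo(information_logo(pfm), str(out))
    assert out.exists() and out.stat().st_size > 0
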