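"""Splice-site logos, difference logos and positional enrichment.

Compares the 5'SS sequences of the high-Z and low-Z intron quartiles from a
synthetic knockout study: builds position frequency matrices, a difference
logo (Jensen-Shannon stack heights), and a Fisher exact test for adenosine
enrichment at intron position +4.
"""

from spliceretain import (
    PositionFrequencyMatrix,
    SimulationConfig,
    WindowSpec,
    difference_logo,
    extract_intron_segments,
    generate_reference,
    positional_fisher,
    run_retention_analysis,
    sample_conditions,
    simulate_junction_counts,
    splice_site_windows,
)
from spliceretain.logos import five_prime_positions

cfg = SimulationConfig(n_genes=600)
ref = generate_reference(cfg, seed=20)
counts = simulate_junction_counts(ref.truth, cfg, seed=21)
dinucs = {r.segment_id: (r.donor, "AG") for r in ref.truth.itertuples()}
analysis = run_retention_analysis(counts, sample_conditions(counts), dinucs)

segments = {s.segment_id: s for s in
            extract_intron_segments(ref.gff3_text, ref.genome)}
z = analysis.zscores.set_index("segment_id")
windows = splice_site_windows(segments.values(), ref.genome)
windows = windows.set_index("segment_id")["five_prime"]
positions = five_prime_positions(WindowSpec())

high = windows.loc[z[z.quartile_class == "high"].index]
low = windows.loc[z[z.quartile_class == "low"].index]
pfm_high = PositionFrequencyMatrix.from_sequences(high.tolist(), positions)
pfm_low = PositionFrequencyMatrix.from_sequences(low.tolist(), positions)

diff = difference_logo(pfm_high, pfm_low)
print("difference logo (high-Z minus low-Z), bits per letter:\n")
print(diff.round(3).to_string())

p = positional_fisher(pfm_high.counts.loc["+4"].to_dict(),
                      pfm_low.counts.loc["+4"].to_dict(), "A")
print(f"\ntwo-sided Fisher p for A-vs-other at +4: {p:.3e}")
print("positive A at +4 above the axis means adenosine is enriched among the"
      "\nintrons most sensitive to loss of the U6 snRNA m6A.")
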