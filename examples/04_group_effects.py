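"""Fourth-nucleotide and exon-triplet group comparison of ΔIRS.

Runs the full synthetic study, groups introns by the intron's fourth
nucleotide and by the 5' exon terminal triplet, and compares the per-group
retention change (ΔIRS = mean IRS KO - mean IRS WT) with rank-sum tests.
"""

from spliceretain import (
    SimulationConfig,
    generate_reference,
    group_compare,
    run_retention_analysis,
    sample_conditions,
    simulate_junction_counts,
)

cfg = SimulationConfig(n_genes=1000)
ref = generate_reference(cfg, seed=30)
counts = simulate_junction_counts(ref.truth, cfg, seed=31)
dinucs = {r.segment_id: (r.donor, "AG") for r in ref.truth.itertuples()}
analysis = run_retention_analysis(counts, sample_conditions(counts), dinucs)

truth = ref.truth.set_index("segment_id")
deltas = analysis.deltas.set_index("segment_id").join(
    truth[["fourth_group", "is_aag"]])

by_group = {g: sub["delta"].to_numpy()
            for g, sub in deltas.groupby("fourth_group")}
result = group_compare(by_group)
print("ΔIRS by fourth intron nucleotide:\n")
print(result.box.round(3).to_string())
print("\npairwise two-sided Wilcoxon rank-sum p-values:\n")
print(result.pvalues.map("{:.2e}".format).to_string())

a4 = deltas[deltas.fourth_group == "A4"]
print("\nAAG-A4 median ΔIRS:     "
      f"{a4[a4.is_aag]['delta'].median():+.3f}  (n={int(a4.is_aag.sum())})")
print("non-AAG-A4 median ΔIRS: "
      f"{a4[~a4.is_aag]['delta'].median():+.3f}  (n={int((~a4.is_aag).sum())})")
print(
    "\nA4 introns (pairing the U6 m6A) lose the most splicing efficiency in"
    "\nthe knockout, except when a consensus AAG exon triplet lets U5 snRNA"
    "\ncompensate."
)
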