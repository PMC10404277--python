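"""Translation-efficiency analysis on a simulated polysome-profiling design.

Simulates a 2-genotype x 3-fraction (total / monosome / polysome) x
2-replicate count matrix with ERCC-like spike-ins and two genes carrying
planted TE log2 fold-changes, then runs the full stack: spike-in size
factors -> normalization -> per-gene TE -> TE-change classification.
"""

from polyte import (
    SimulationDesign,
    compute_size_factors,
    generate_fraction_counts,
    make_spikein_reference,
    normalize_counts,
    te_table,
)

genes = [f"gene{i:03d}" for i in range(1, 41)]
design = SimulationDesign(
    mean_depth=500.0,
    dispersion=0.05,
    te_effects={"gene003": 2.0, "gene007": -2.0},  # planted TE log2FC
    seed=11,
)
ref = make_spikein_reference()
counts, libraries = generate_fraction_counts(genes, design, ref)

factors = compute_size_factors(counts, ref)
normalized = normalize_counts(counts, factors)
table = te_table(normalized.genes, libraries)

called = table[table.te_class != "unchanged"]
print(called.round(3).to_string(index=False))
print(
    f"\n{len(called)} of {len(table)} genes called TE-changed; "
    "te_log2fc near +2/-2 with rna_log2fc near 0 means ribosome loading "
    "changed while transcript abundance did not - the planted truth for "
    "gene003/gene007. With only 2 replicates at NB dispersion 0.05 an "
    "occasional null gene drifts past the |log2FC|>1 threshold."
)
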