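# Demonstration run: synthetic data at a reduced gene count.
# Omitted synthetic parameters (shapes, scales, zero inflation, copula)
# fall back to the package defaults, which encode the qualitative
# cross-taxa and cross-level ordering structure.

mode = "synthetic"
seed = 1
granularity = "pooled"
tail_fraction = 0.025
baseline_reps = 101

[synthetic]
genes_per_taxon = 400
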