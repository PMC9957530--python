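"""Simulate a two-group RNA-seq count matrix with planted structure.

Builds a 300-gene dataset for 8 fertile (FH) and 7 subfertile (SFH)
heifer samples with 8 planted differentially expressed genes and one
20-gene co-expression module active only in the subfertile group, then
prints what was planted. The ground truth is what the downstream examples
try to recover.
"""

from pcitnet import ModuleSpec, SimConfig, simulate_counts

config = SimConfig(
    n_genes=300,
    n_samples_per_group=(8, 7),
    n_deg=8,
    lfc_magnitude=2.0,
    nb_dispersion=0.05,
    modules=(ModuleSpec(tuple(range(20)), ("SFH",), 0.95),),
    seed=1,
)
counts, truth = simulate_counts(config)

print(f"counts: {counts.n_genes} genes x {counts.n_samples} samples")
print(f"mean count: {counts.counts.to_numpy().mean():.0f}")
print(f"planted DEGs: {len(truth.deg_genes)} "
      f"(|log2FC| = {config.lfc_magnitude})")
print(f"rewired genes (SFH-only module): {len(truth.rewired_genes)}")
print(f"expected SFH co-expression edges: {len(truth.expected_edges('SFH'))}")
# Counts are negative-binomial with dispersion 0.05; the module genes share
# a latent factor only in SFH samples, so their pairwise correlation is
# high there and at background level in FH.
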