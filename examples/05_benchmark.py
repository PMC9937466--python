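"""Miniature enrichment benchmark: how well does the competitive P-value
ranking recover the simulated truth?

Runs a reduced version of the simulation study (full scale lives in
scripts/acceptance.py) and prints Kendall's tau per repetition.
"""

import numpy as np

from pathprs.simulate import benchmark_enrichment

table = benchmark_enrichment(
    h2_list=(0.1, 0.5), n_base=3000, n_target=1500, n_snps=1500,
    n_genes=300, n_sets=80, genes_per_set=10, k_causal=15,
    n_perm=300, reps=3, seed=42,
)
print(table[["h2", "rep", "tau"]].to_string(index=False))
print(f"\nmedian tau: {np.median(table['tau']):.3f}")
print(
    "tau compares the -log10 competitive P ranking of 80 pathways with "
    "the true causal-enrichment ranking; higher h2 and larger samples "
    "push it up. The full-scale run reports it over 5,000 SNPs, 300 "
    "pathways and 12 seeded configurations."
)
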