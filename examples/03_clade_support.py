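"""Bremer decay and bootstrap support for the clades of a parsimony tree.

The Bremer value of a clade is how many extra steps the best tree
*without* that clade needs — the cost of breaking it.  Bootstrap support
is how often the clade survives character resampling.  High values on
both scales mark robust clades.
"""

from morphpars import (
    BootstrapConfig,
    SearchConfig,
    SimulationConfig,
    bootstrap_supports,
    branch_and_bound,
    bremer_supports,
    simulate_matrix,
)
from morphpars.support import merge_support_tables

matrix, _ = simulate_matrix(
    SimulationConfig(n_taxa=8, n_chars=60, change_prob=0.08, seed=7)
)
result = branch_and_bound(matrix, SearchConfig())
print(f"best length {result.length}, {result.mpt_count} MPT(s)")

bremer = bremer_supports(matrix, result)
boot = bootstrap_supports(matrix, BootstrapConfig(replicates=200, seed=7))
table = merge_support_tables(bremer, boot)
print("\nper-clade support (Bremer = extra steps to break the clade;")
print("bootstrap = % of 200 character-resampling replicates retaining it):")
print(table.to_dataframe().to_string(index=False))

print("\nbootstrap majority-rule tree (frequencies as node labels):")
freq = {r.split: round(r.bootstrap_pct) for r in boot.rows if r.bootstrap_pct > 50}
print(boot.majority_tree.to_newick(support=freq))
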