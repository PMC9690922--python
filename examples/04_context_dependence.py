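"""Detecting context-dependent mutation at the third codon position.

If mutation is an independent single-site event, third-base frequencies in
the eight 4-fold degenerate families cannot depend on the first/second
codon bases.  This script generates one genome-scale codon pool under the
null and one with an injected context effect, builds the six family-by-base
contingency tables, and runs chi-square tests with BH correction.
"""

import numpy as np

from chlorocodon import SyntheticSpec, bh_correct, build_context_tables, generate_counts
from chlorocodon.mutation_selection import test_independence

for label, delta in (("independent third base (null)", 0.0), ("context-dependent", 0.8)):
    spec = SyntheticSpec(n_genes=1, codons_per_gene=20_000, gc3_target=0.26,
                         context_delta=delta, seed=5)
    vec = generate_counts(spec)[0]
    results = bh_correct(
        [test_independence(t, "pearson_chi2") for t in build_context_tables(vec)],
        fdr=0.05,
    )
    print(f"\n{label}:")
    for r in results:
        mark = " *" if r.p_bh_significant else ""
        print(f"  {r.name:<38s} chi2 = {r.statistic:8.2f}  p = {r.p:.3f}{mark}")

print("\n'*' = significant after Benjamini-Hochberg correction at FDR 0.05.")
print("Under the null nothing should be starred; with the injected context")
print("effect the tests reject, as they do for real chloroplast genome pools.")
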