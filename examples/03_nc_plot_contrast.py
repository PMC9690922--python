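"""The estimated-vs-expected Nc contrast: composition-driven genes track the
expected curve, selection-biased genes fall below it.

Generates genes along a GC3s gradient twice — once with codon choice driven
purely by third-base composition, once with an extra within-family
preference — and prints how far each set sits from the expected-Nc curve.
"""

import numpy as np

from chlorocodon import SyntheticSpec, expected_nc, generate_counts, positional_gc, sun_nc


def deviations(bias_strength):
    out = []
    for i, gc3 in enumerate(np.linspace(0.15, 0.6, 10)):
        spec = SyntheticSpec(
            n_genes=1, codons_per_gene=5000, gc3_target=float(gc3),
            bias_strength=bias_strength, seed=100 + i,
        )
        vec = generate_counts(spec)[0]
        s = positional_gc(vec).gc3s / 100
        out.append(expected_nc(s) - sun_nc(vec))
    return np.array(out)


neutral = deviations(0.0)
selected = deviations(2.0)

print("deviation from the expected-Nc curve (expected - estimated, in codons):")
print(f"  composition-only genes: mean |dev| = {np.abs(neutral).mean():.2f}")
print(f"  selection-biased genes: mean dev   = {selected.mean():.2f} (all positive: {(selected > 0).all()})")
print("\nA positive deviation means the gene uses fewer codons than its GC3s")
print("predicts — the signature a highly translated gene like psbA shows.")
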