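"""Codon-usage basics on a single gene: RSCU, bias classes, and the three
effective-number-of-codons values.

Builds a small codon count vector by hand, then prints the statistics a
practitioner would report for one coding sequence.
"""

from chlorocodon import CodonCountVector, expected_nc, positional_gc, rscu, sun_nc, wright_nc

# A toy gene: Phe strongly biased toward TTC, Lys balanced, Ala uniform,
# Ile present, Leu (6-fold) favouring TTA as chloroplast genes do.
vector = CodonCountVector.from_dict(
    {
        "TTC": 20, "TTT": 6,                      # Phe, 2-fold, biased
        "AAA": 10, "AAG": 10,                     # Lys, 2-fold, balanced
        "GCA": 5, "GCC": 5, "GCG": 5, "GCT": 5,   # Ala, 4-fold, uniform
        "ATT": 9, "ATA": 6, "ATC": 3,             # Ile, 3-fold
        "TTA": 12, "TTG": 6, "CTT": 4, "CTA": 2,  # Leu, 6-fold, T/A-ending
        "ATG": 8,                                 # Met (single codon)
    },
    label="toy",
)

profile = rscu(vector)
print("RSCU values and bias classes:")
for codon in ("TTC", "TTT", "AAA", "GCA"):
    print(f"  {codon}: RSCU = {profile.rscu[codon]:.3f}  ({profile.bias_class[codon]})")

gc = positional_gc(vector)
print(f"\nGC of synonymous codons: GC1s={gc.gc1s:.2f}%  GC2s={gc.gc2s:.2f}%  GC3s={gc.gc3s:.2f}%")

print(f"\nWright's Nc: {wright_nc(vector):.3f}   (20 = extreme bias, 61 = none)")
print(f"Sun's Nc:    {sun_nc(vector):.3f}   (bounded by observed families and sense codons)")
print(f"Expected Nc at this GC3s: {expected_nc(gc.gc3s / 100):.3f}")
print("\nAn estimated Nc far below the expected value flags selection on codon choice")
print("beyond what third-position composition alone explains.")
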