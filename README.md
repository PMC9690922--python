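# chlorocodon

Codon-usage analysis of chloroplast genomes, built around the comparative
study design used for *Quercus* (oak) plastomes: extract and curate the
protein-coding genes of a set of annotated genomes, quantify how biased and
how similar their codon usage is, and ask whether mutation (including
context-dependent mutation at the third codon position) or translational
selection drives that usage.

It is a library first — every stage is an importable function operating on
plain containers (codon count vectors, RSCU profiles, pandas DataFrames) —
with a thin `chlorocodon` command-line wrapper and an `examples/` directory
of narrative scripts.

## What it computes

**Curation** (`cds_io`): GenBank parsing, CDS splicing (joins, minus
strands, trans-spliced genes), declarative curation overrides (rename /
replace coordinates / drop), removal of ambiguous codons, of genes without
a proper stop codon, with internal stops, or shorter than 100 codons,
deduplication of inverted-repeat gene copies, and the shared gene set
across genomes.

**Bias statistics** (`usage_stats`), for a gene with codon counts
$n_c$:

- GC1s/GC2s/GC3s — G+C percentage at each codon position over synonymous
  codons (Met, Trp and stops excluded).
- RSCU — for codon $c$ of an amino acid with total count $n_{aa}$ and
  degeneracy $k$: $\mathrm{RSCU}_c = n_c / (n_{aa}/k)$, classed as
  over-represented (> 1.6), positively biased, unbiased, negatively biased,
  under-represented (< 0.6) or unused, plus the ending-base × bias-class
  percentage summary.
- Wright's effective number of codons
  $N_c = 2 + 9/\bar F_2 + 1/F_3 + 5/\bar F_4 + 3/\bar F_6$, with
  per-family homozygosity $\hat F = (n\sum \hat p_i^2 - 1)/(n-1)$.
- Sun's improved $N_c$ — six-fold families split into two-fold + four-fold
  subfamilies, pseudocount homozygosity
  $F = \sum \left(\frac{n_i+1}{n+k}\right)^2$, $N_c = \sum_{\text{families}} 1/F$.
- The expected $N_c$ under pure composition,
  $N_c^{\exp} = 2 + s + 29/(s^2 + (1-s)^2)$ with $s$ = GC3s.

**Comparison** (`comparative`): cosine similarity of RSCU profiles over the
59 degenerate sense codons, cumulate similarity with percentile scores,
one-way repeated-measures ANOVA (genes vs genomes, either orientation),
and average-linkage/Euclidean clustering exported as Newick.

**Mutation vs selection** (`mutation_selection`): estimated-vs-expected
$N_c$ deviations; the neutrality plot (OLS of $P_{12}$ on $P_3$, the GC of
codon positions 1+2 vs 3 with ATG/TGG/ATA/stops excluded); and the six
family × third-base contingency datasets (Leu4/Pro/Arg4, Val/Ala/Gly, the
pooled combination, Leu4/Val, Arg4/Gly, Ser4/Pro/Thr/Ala) tested for
independence by Pearson chi-square or Fisher's exact test (full
enumeration with a seeded Monte-Carlo fallback), with Benjamini–Hochberg
correction at FDR 0.05.

**Synthetic data** (`synthetic_data`): seeded generation of codon count
vectors, genes and GenBank fixtures with controllable GC3s, within-family
bias strength and third-base context dependence, so every stage is
testable without downloads.

## Worked example

`python examples/01_codon_bias_basics.py` builds a toy gene (Phe biased
20:6 toward TTC, Lys balanced, Ala uniform, a T/A-leaning Leu family) and
prints:

```
RSCU values and bias classes:
  TTC: RSCU = 1.538  (positive)
  TTT: RSCU = 0.462  (under)
  AAA: RSCU = 1.000  (unbiased)
  GCA: RSCU = 1.000  (unbiased)

GC of synonymous codons: GC1s=24.07%  GC2s=18.52%  GC3s=45.37%

Wright's Nc: 54.290   (20 = extreme bias, 61 = none)
Sun's Nc:    15.885   (bounded by observed families and sense codons)
Expected Nc at this GC3s: 59.961
```

TTC is used 1.538 times more than equal use of the Phe codons would
predict; the gene's Sun $N_c$ of 15.9 against 18 usable sense codons says
usage is mildly concentrated, and the gap to the expected $N_c$ is what
the selection analyses work from.  The other examples run the full
synthetic pipeline (`02`), the estimated-vs-expected $N_c$ contrast
(`03`), and the context-dependence tests (`04`).

## Running on real genomes

Drop the 26 oak chloroplast RefSeq GenBank flat files (accessions
NC_020152.1, NC_026790.1, NC_026907.1, NC_026913.1, NC_029490.1,
NC_031356.1, NC_031357.1, NC_036370.1, NC_036930.1, NC_036936.1,
NC_036941.1, NC_039428.1, NC_039429.1, NC_039725.1, NC_039972.1,
NC_043857.1, NC_043858.1, NC_046388.1, NC_046583.1, NC_047481.1,
NC_048488.1, NC_049876.1, NC_050963.1, NC_050972.1, NC_054352.1,
NC_057248.1; ~4 MB total, e.g. via NCBI efetch with `rettype=gbwithparts`)
into `data/genomes/` and run

```bash
chlorocodon run-all --genbank data/genomes \
    --overrides data/overrides_quercus.txt --out results/quercus
```

`data/overrides_quercus.txt` carries the two annotation fixes these
genomes need (the *psi*→*psbB* rename in NC_020152.1 and the corrected
*ndhJ* coordinates in NC_047481.1).  The genome-scale tests in
`tests/test_acceptance.py` then verify the 50-gene shared set and the
per-gene statistics against their published values; no download client is
included — fetching the accessions is the user's responsibility.

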