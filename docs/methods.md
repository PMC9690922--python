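# Methods

This note records what the package computes, the conventions it fixes
where the literature leaves room, and what the synthetic-data generator
does and does not emulate.

## Gene extraction and curation

Genomes are read from GenBank flat files; every CDS feature carrying a
`/gene` qualifier is kept, including both inverted-repeat (IR) copies,
with its join structure and per-segment strand.  Coordinates are GenBank
convention (1-based, inclusive) throughout, including in the overrides
config and any exported interval files.  Extraction concatenates segments
in the order the location parser yields them, reverse-complementing
minus-strand segments; this reproduces Biopython's `location.extract`
exactly (asserted against it in the tests) and covers trans-spliced genes
whose segments sit on opposite strands.

Curation is declarative only: overrides can rename a gene, replace (or
supply) its coordinates, or drop it.  No alignment or annotation transfer
is performed; the shipped `data/overrides_quercus.txt` encodes the two
fixes the oak reference genomes need.

Filtering, in order: codons containing a non-ACGT base are deleted
codon-wise (the gene is kept); genes whose spliced sequence does not end
in TAA/TAG/TGA, or whose length is not divisible by three, are dropped;
genes with internal stop codons are dropped; genes shorter than 100 codons
after ambiguity removal are dropped; for duplicated genes (the IR set
ndhB, rpl2, rps12, rps7, ycf2, and any other duplicated name) only the
copy occurring first in genome coordinate order is kept.  Because IR
copies are sequence-identical, the choice of copy should not affect any
statistic; the filter is deterministic about it anyway.  The whole filter
is idempotent.

## Bias statistics

*Positional GC.*  GC1s/GC2s/GC3s are computed over one consistent codon
set: all synonymous codons, i.e. excluding ATG, TGG and stops at all three
positions.  The neutrality statistics P1/P2/P3 use a different exclusion
set — ATG, TGG, ATA and the stops — because the third position of those
six codons is not free to vary synonymously in the two-/four-fold sense
that analysis assumes.  The two codon sets are deliberately not unified.

*RSCU.*  RSCU of codon c is its count divided by the equal-use
expectation; the family mean is 1 by construction (tested to 1e-9).
Single-codon amino acids carry RSCU 1 when present.  Bias classes follow
the 0.6/1.6 thresholds with strict inequalities for "under"/"over", so a
codon at exactly 1.6 is "positive" and one at exactly 0.6 is "negative";
equality with 1 is tested within 1e-9.  Amino acids with zero count are
"absent" and excluded from ending-base denominators; ATG and TGG are
excluded from the ending-base summary entirely (they carry no synonymous
choice).  Computed subtotals of the ending-base table are reported as
computed, never copied from elsewhere.

*Wright's Nc.*  Per family with total usage n >= 2, homozygosity is
estimated as F = (n * sum(p^2) - 1)/(n - 1); Nc = 2 + 9/F2 + 1/F3 + 5/F4
+ 3/F6 with each class mean taken over its observed families and six-fold
families intact.  If Ile (the only three-fold family) is unobserved, F3
falls back to the mean of F2 and F4.  If a degeneracy class has no
computable family, or a class mean is zero, the gene's Wright Nc is
reported as missing (NaN) rather than guessed — for filter-passing genes
(>= 100 codons) this does not occur in practice.  The estimator is exactly
20 for a gene using one codon per amino acid and overshoots 61 on small
unbiased samples, its known pathology; doubling counts moves it
monotonically toward 61 (tested).

*Sun's Nc.*  The six-fold amino acids are split into their two-fold
(TTA/TTG, AGT/AGC, AGA/AGG) and four-fold subfamilies, giving 23 families.
Per observed family, homozygosity uses pseudocount proportions
p_i = (n_i + 1)/(n + k), F = sum(p_i^2), and Nc is the sum of 1/F over
observed families, bounded by [number of observed families, number of
sense codons in those families] (asserted).  The pseudocount convention is
isolated in one helper so it can be swapped if a reference implementation
with a different convention must be matched; absolute values of this
estimator are convention-sensitive, rank orderings much less so.

*Expected Nc.*  Nc_exp(s) = 2 + s + 29/(s^2 + (1 - s)^2), s = GC3s as a
fraction in [0, 1] (out-of-range input is an error).  A gene whose usage
is driven by third-position composition alone lands near this curve; a
gene under translational selection falls below it.  The deviation is
reported both as a difference and as a fraction of the expected value.

## Comparisons

Cosine similarity of two RSCU profiles is taken over the 59 degenerate
sense codons, with absent amino acids contributing zeros; it is
scale-invariant and lies in [0, 1] for non-negative profiles.  A gene's
cumulate similarity is its row sum minus the diagonal; percentile scores
are 100 * (count of values <= the gene's value)/n.  Published percentiles
for these genomes do not pin down the exact formula, so percentiles are
treated as coarse ranks, not reproduction targets.

Repeated-measures ANOVA is the standard one-way within-subjects
decomposition: F = MS_conditions / MS_(conditions x subjects), df = (k-1)
and (k-1)(n-1), no sphericity correction (matching how such comparisons
are usually reported in this literature).  Both orientations — genomes as
conditions with genes as subjects, and vice versa — are supported, since
the genes x genomes table is complete by construction.

Clustering for heat-map style outputs is average linkage on Euclidean
distances via scipy; rows are pre-sorted by label so tied merges resolve
deterministically, and trees are exported as Newick with branch lengths
derived from merge heights (non-decreasing by the monotonicity of average
linkage).

## Context-dependence tests

Within the eight four-fold families the third base is a synonymous,
putatively neutral site; if mutation is a single-site process its
distribution cannot depend on the first/second codon bases.  Six
family-group x third-base tables are built (composite rows pool their
families cell-wise) and tested for independence.  Large pooled counts use
Pearson chi-square without continuity correction; single-gene counts use
Fisher's exact test, defined for r x c as the total probability (under
fixed margins) of tables no more probable than the observed one.  Full
enumeration is used when it fits a configurable work bound (500k tables
by default); beyond that a seeded Monte-Carlo estimate with 1e5 samples
takes over, using the add-one estimator (hits+1)/(B+1).  Zero rows and
columns are dropped before testing so degrees of freedom reflect observed
categories; a table left with fewer than two rows or columns is an error.
BH correction is applied per six-test family at FDR 0.05.

## Synthetic data

The generator emulates the statistical structure the analyses consume,
not genome anatomy: amino-acid usage follows a fixed chloroplast-like
composition frozen in the source (membrane-protein-rich, hence abundant
Leu/Ile/Phe); a single exponential third-base tilt, solved numerically,
makes the expected aggregate GC3s equal `gc3_target` exactly;
`bias_strength` concentrates probability on one codon inside each
third-base group (moving mass only within a group, so GC3s is preserved
while homozygosity rises — a clean selection signature); `context_delta`
tilts third-base probabilities inside four-fold families toward the
family's first-position base and away from its second-position base, so
all six test datasets carry signal when it is positive and the
independence null holds exactly at zero.  All randomness flows through
one seeded generator; identical spec + seed gives identical output, and
fixture GenBank files (with at least one minus-strand gene and one
two-segment join) round-trip exactly through extraction.

Defaults mirror the study system: 50 genes, lengths 100-600 codons, GC3s
0.26, no selection or context signal unless requested.  What the
generator does not emulate: inverted repeats and duplicated genes,
intergenic structure, among-site rate variation within genes, and
phylogenetic correlation between genomes (synthetic genomes are
independent draws, whereas real congeneric plastomes are nearly
identical).  Passing simulation tests therefore demonstrate the
statistics' calibration and power under the generative model, not the
biological conclusions for any real genome set.

## Problem sizes and numerical choices

The simulation checks use 500 replicates of a 20,000-codon genome-scale
pool for the context-test calibration (nominal 5% level, observed
rejection required in [0.03, 0.07]) and power (strong dependence,
`context_delta` = 1, required >= 95% rejection), and ten 5,000-codon genes
along a GC3s gradient for the expected-Nc curve contrast; these sizes give
stable Monte-Carlo estimates while keeping the default suite fast.
Probabilities and homozygosities are computed in double precision;
log-gamma arithmetic is used for table probabilities to avoid overflow;
comparisons against thresholds use 1e-9 guards rather than rounded
equality.  Degenerate inputs (empty vectors, zero-variance regressors,
all-zero similarity vectors, degenerate tables) raise `ValueError` with
the offending label rather than returning silent defaults.

## Known limitations

- Wright's Nc is reported as missing for vectors lacking an entire
  degeneracy class; no extrapolation is attempted.
- Sun's-estimator absolute values depend on the pseudocount convention;
  cross-implementation comparisons should rely on rank order unless the
  convention is known to match.
- Fisher's Monte-Carlo p-values are estimates with standard error around
  sqrt(p(1-p)/1e5); borderline calls near a significance threshold should
  be re-run with a larger sample budget.
- The percentile-score formula is one of several plausible conventions.
- The pipeline assumes one GenBank record per file and standard-code
  translation (true of land-plant plastomes).
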