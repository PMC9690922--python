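"""Synthetic codon-usage data with controllable statistical structure.

Every pipeline stage can be exercised without downloading genomes: this
module generates per-gene codon count vectors from a small set of knobs,
expands them into well-formed genes, and writes standards-conformant
GenBank fixtures that the extraction stage recovers exactly.

Generative model
----------------
Amino-acid usage follows a fixed chloroplast-like composition (frozen in
:data:`AA_COMPOSITION`).  Within each synonymous family the third-base
distribution is set so that G/C-ending codons carry a total probability of
``gc3_target`` and A/T-ending codons the complement (split equally inside
each group), which makes the realized GC3s match the target in expectation
for every family.  Two optional distortions are layered on top:

* ``bias_strength`` concentrates probability on one preferred codon inside
  each third-base group of a family (weight ``exp(bias_strength)`` versus 1).
  Because mass moves only *within* a third-base group, GC3s is unchanged
  while within-family homozygosity rises — the signature of translational
  selection, pushing the gene below the expected-Nc curve.
* ``context_delta`` tilts third-base probabilities inside the four-fold
  families by ``exp(context_delta)`` toward the family's first-position base
  and away from its second-position base, creating exactly the kind of
  context-dependent mutation signal the independence tests are designed to
  detect.  At 0 the null of single-site mutation holds by construction.

Defaults mirror the study system: 50 genes per genome, gene lengths between
100 and 600 codons, GC3s around 0.26 (chloroplast coding sequences are
strongly AT-biased at the third position), and no selection or context
signal unless asked for.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .cds_io import GeneCDS
from .codon_core import (
    CODON_INDEX,
    CODONS,
    GENETIC_CODE,
    WRIGHT_PARTITION,
    CodonCountVector,
)

__all__ = [
    "AA_COMPOSITION",
    "SyntheticSpec",
    "SyntheticGenome",
    "codon_probabilities",
    "generate_counts",
    "counts_to_gene",
    "generate_genomes",
    "write_fixture_genbank",
]

#: Frozen chloroplast-like amino-acid composition (fractions; sum to 1).
#: Hydrophobic residues (Leu, Ile, Phe) are abundant in the membrane-rich
#: photosynthetic proteome; Cys and His are rare.
AA_COMPOSITION: dict[str, float] = {
    "A": 0.058, "C": 0.011, "D": 0.041, "E": 0.052, "F": 0.066,
    "G": 0.068, "H": 0.024, "I": 0.086, "K": 0.051, "L": 0.100,
    "M": 0.024, "N": 0.045, "P": 0.044, "Q": 0.035, "R": 0.054,
    "S": 0.075, "T": 0.056, "V": 0.060, "W": 0.017, "Y": 0.033,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generator; identical spec + seed gives identical data."""

    n_genes: int = 50
    codons_per_gene: int | tuple[int, int] = (100, 600)
    gc3_target: float = 0.26
    bias_strength: float = 0.0
    context_delta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.bias_strength < 0 or self.context_delta < 0:
            raise ValueError("bias_strength and context_delta must be >= 0")

    def gene_length(self, rng: np.random.Generator) -> int:
        if isinstance(self.codons_per_gene, int):
            return self.codons_per_gene
        lo, hi = self.codons_per_gene
        return int(rng.integers(lo, hi + 1))


@dataclass
class SyntheticGenome:
    label: str
    genes: list[GeneCDS]
    truth: SyntheticSpec


def _family_group_masses(fam, tilt: float) -> tuple[list, list, float, float]:
    """Split a family's codons into G/C-ending and A/T-ending groups and
    return the groups with their probability masses under an exponential
    third-base tilt ``exp(tilt)`` per G/C-ending codon."""
    gc_group = [c for c in fam.codons if c[2] in "GC"]
    at_group = [c for c in fam.codons if c[2] in "AT"]
    w_gc = len(gc_group) * math.exp(tilt)
    w_at = len(at_group) * 1.0
    total = w_gc + w_at
    return gc_group, at_group, w_gc / total, w_at / total


def _aggregate_gc3(tilt: float) -> float:
    """Expected GC3s over synonymous codons at a given third-base tilt."""
    num = 0.0
    den = 0.0
    for fam in WRIGHT_PARTITION:
        if fam.amino_acid in ("M", "W"):
            continue
        mass = AA_COMPOSITION[fam.amino_acid]
        _, _, m_gc, _ = _family_group_masses(fam, tilt)
        num += mass * m_gc
        den += mass
    return num / den


def _solve_tilt(gc3_target: float) -> float:
    """Third-base tilt whose expected aggregate GC3s equals the target."""
    from scipy.optimize import brentq

    if gc3_target == 0.0:
        return -math.inf
    if gc3_target == 1.0:
        return math.inf
    return float(brentq(lambda t: _aggregate_gc3(t) - gc3_target, -60.0, 60.0))


def codon_probabilities(spec: SyntheticSpec) -> np.ndarray:
    """Per-codon sampling probabilities over the 64 codons (stops are 0).

    A single exponential third-base tilt, shared by all families, is solved
    numerically so that the expected GC3s over synonymous codons equals
    ``gc3_target`` exactly; within each third-base group usage is uniform
    unless ``bias_strength``/``context_delta`` distort it (those distortions
    move mass within a group, or within a four-fold family, and leave the
    aggregate target essentially unchanged).
    """
    s = spec.gc3_target
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"gc3_target {s} unreachable; feasible range is [0, 1]")
    tilt = _solve_tilt(s)
    p = np.zeros(64)
    for fam in WRIGHT_PARTITION:
        aa_mass = AA_COMPOSITION[fam.amino_acid]
        if math.isinf(tilt):
            gc_group = [c for c in fam.codons if c[2] in "GC"]
            at_group = [c for c in fam.codons if c[2] in "AT"]
            m_gc, m_at = (1.0, 0.0) if tilt > 0 else (0.0, 1.0)
        else:
            gc_group, at_group, m_gc, m_at = _family_group_masses(fam, tilt)
        for group, mass in ((gc_group, m_gc), (at_group, m_at)):
            if not group:
                continue
            if not gc_group or not at_group:  # Met, Trp: single third-base group
                mass = 1.0
            elif mass == 0.0:
                continue
            # within-group weights: a preferred codon (alphabetically first)
            # gets exp(bias_strength); four-fold families additionally carry
            # the context tilt toward the first-position base and away from
            # the second-position base
            w = np.ones(len(group))
            w[0] = np.exp(spec.bias_strength)
            if fam.degeneracy == 4 and spec.context_delta > 0:
                for i, codon in enumerate(group):
                    if codon[2] == codon[0]:
                        w[i] *= np.exp(spec.context_delta)
                    if codon[2] == codon[1]:
                        w[i] *= np.exp(-spec.context_delta)
            w = w / w.sum() * mass
            for codon, wi in zip(group, w):
                p[CODON_INDEX[codon]] = aa_mass * wi
    return p / p.sum()


def generate_counts(spec: SyntheticSpec) -> list[CodonCountVector]:
    """Multinomial per-gene codon counts under the generative model."""
    rng = np.random.default_rng(spec.seed)
    p = codon_probabilities(spec)
    out = []
    for i in range(spec.n_genes):
        length = spec.gene_length(rng)
        counts = rng.multinomial(length, p)
        out.append(CodonCountVector(counts, f"synth{i + 1:03d}"))
    return out


def counts_to_gene(counts: CodonCountVector, seed: int, accession: str = "SYN") -> GeneCDS:
    """Expand a count vector into a shuffled in-frame gene that passes all
    curation filters (starts with ATG, ends with a stop, no ambiguity)."""
    if counts.total() < 100:
        raise ValueError("need at least 100 codons to build a filter-passing gene")
    rng = np.random.default_rng(seed)
    codons = [c for c in CODONS for _ in range(counts[c])]
    rng.shuffle(codons)
    if "ATG" in codons:
        codons.remove("ATG")
    codons.insert(0, "ATG")
    return GeneCDS(counts.label, accession, codons, stop_codon="TAA")


def generate_genomes(spec: SyntheticSpec, n_genomes: int = 2) -> list[SyntheticGenome]:
    """A set of genomes sharing gene names, each gene independently sampled
    from the spec (seeds derived from ``spec.seed``)."""
    genomes = []
    for g in range(n_genomes):
        label = f"SYN_{g + 1:06d}"
        gene_spec = SyntheticSpec(
            n_genes=spec.n_genes,
            codons_per_gene=spec.codons_per_gene,
            gc3_target=spec.gc3_target,
            bias_strength=spec.bias_strength,
            context_delta=spec.context_delta,
            seed=spec.seed + 1000 * g,
        )
        vectors = generate_counts(gene_spec)
        genes = [
            counts_to_gene(v, seed=gene_spec.seed + i + 1, accession=label)
            for i, v in enumerate(vectors)
        ]
        genomes.append(SyntheticGenome(label, genes, gene_spec))
    return genomes


def _spacer(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def write_fixture_genbank(genomes: Sequence[SyntheticGenome], out_dir) -> list[Path]:
    """Write one GenBank flat file per genome.

    The second gene of each genome is placed on the minus strand and the
    third is split into a two-segment ``join(...)``, so fixtures exercise
    reverse-complementation and join handling.  Extraction recovers every
    codon list exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for genome in genomes:
        rng = np.random.default_rng(zlib.crc32(genome.label.encode()) % (2**31))
        parts: list[str] = [_spacer(rng, 100)]
        features: list[SeqFeature] = []
        pos = 100
        for i, gene in enumerate(genome.genes):
            cds = gene.sequence()
            if i == 1:  # minus strand
                insert = str(Seq(cds).reverse_complement())
                loc = SimpleLocation(pos, pos + len(cds), strand=-1)
            elif i == 2 and len(cds) >= 6:  # two-segment join with a 50 bp gap
                cut = (len(cds) // 6) * 3
                gap = _spacer(rng, 50)
                insert = cds[:cut] + gap + cds[cut:]
                loc = CompoundLocation(
                    [
                        SimpleLocation(pos, pos + cut, strand=1),
                        SimpleLocation(pos + cut + 50, pos + len(cds) + 50, strand=1),
                    ]
                )
            else:
                insert = cds
                loc = SimpleLocation(pos, pos + len(cds), strand=1)
            parts.append(insert)
            feat = SeqFeature(loc, type="CDS", qualifiers={"gene": [gene.gene_name]})
            features.append(feat)
            spacer = _spacer(rng, 80)
            parts.append(spacer)
            pos += len(insert) + 80
        seq = "".join(parts)
        record = SeqRecord(
            Seq(seq),
            id=genome.label,
            name=genome.label.replace(".", "_")[:16],
            description="synthetic chloroplast-like fixture",
            features=features,
            annotations={"molecule_type": "DNA", "organism": "synthetic construct"},
        )
        path = out_dir / f"{genome.label}.gb"
        SeqIO.write(record, str(path), "genbank")
        paths.append(path)
    return paths
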