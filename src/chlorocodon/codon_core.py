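"""Standard genetic code, degeneracy partitions, and codon counting.

Everything downstream (RSCU, effective number of codons, neutrality
statistics, context-dependence tables) is computed from
:class:`CodonCountVector` objects produced here.  Codons are indexed in a
single fixed order (plain alphabetical, A < C < G < T) so that every exported
table is byte-stable.

Two partitions of the 61 sense codons into synonymous families are provided:

* ``wright`` — one family per amino acid (six-fold families intact), the
  partition behind Wright's effective number of codons;
* ``sun`` — the six-fold amino acids Leu, Ser and Arg split into their
  two-fold (TTA/TTG, AGT/AGC, AGA/AGG) and four-fold (CTN, TCN, CGN)
  subfamilies, the partition behind Sun's improved estimator and behind the
  third-position context-dependence tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "BASES",
    "CODONS",
    "CODON_INDEX",
    "STOP_CODONS",
    "SENSE_CODONS",
    "SINGLE_CODON_AA",
    "GENETIC_CODE",
    "AMINO_ACIDS",
    "Family",
    "FamilyPartition",
    "WRIGHT_PARTITION",
    "SUN_PARTITION",
    "FOURFOLD_FAMILIES",
    "CodonCountVector",
    "count_codons",
    "pool_counts",
    "family_counts",
    "write_count_table",
]

BASES = ("A", "C", "G", "T")

#: All 64 codons in alphabetical order (A < C < G < T); the canonical index.
CODONS: tuple[str, ...] = tuple("".join(p) for p in product(BASES, repeat=3))
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_std = _BioCodonTable.unambiguous_dna_by_id[1]
#: Sense codon -> one-letter amino acid, standard nuclear/plastid code.
GENETIC_CODE: dict[str, str] = {c: _std.forward_table[c] for c in CODONS if c not in STOP_CODONS}

SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(GENETIC_CODE.values())))
SINGLE_CODON_AA = {"M": "ATG", "W": "TGG"}


@dataclass(frozen=True)
class Family:
    """A synonymous-codon family: the codons read as one amino acid (or, for
    split six-fold amino acids, one of its two-fold/four-fold subsets)."""

    name: str
    amino_acid: str
    codons: tuple[str, ...]

    @property
    def degeneracy(self) -> int:
        return len(self.codons)


def _aa3(aa1: str) -> str:
    from Bio.SeqUtils import seq3

    return seq3(aa1)


def _families_by_aa() -> dict[str, tuple[str, ...]]:
    fams: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        fams.setdefault(GENETIC_CODE[codon], []).append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in fams.items()}


def _build_wright() -> tuple[Family, ...]:
    return tuple(
        Family(_aa3(aa), aa, codons) for aa, codons in sorted(_families_by_aa().items())
    )


def _build_sun() -> tuple[Family, ...]:
    out: list[Family] = []
    split = {
        "L": ("Leu2", ("TTA", "TTG")),
        "S": ("Ser2", ("AGC", "AGT")),
        "R": ("Arg2", ("AGA", "AGG")),
    }
    for aa, codons in sorted(_families_by_aa().items()):
        if aa in split:
            two_name, two = split[aa]
            four = tuple(c for c in codons if c not in two)
            out.append(Family(two_name, aa, two))
            out.append(Family(_aa3(aa)[:3] + "4", aa, four))
        else:
            out.append(Family(_aa3(aa), aa, codons))
    return tuple(out)


@dataclass(frozen=True)
class FamilyPartition:
    """A named partition of the 61 sense codons into synonymous families."""

    mode: str
    families: tuple[Family, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for fam in self.families:
            if seen & set(fam.codons):
                raise ValueError(f"partition {self.mode!r}: overlapping families")
            seen.update(fam.codons)
        if seen != set(SENSE_CODONS):
            raise ValueError(f"partition {self.mode!r} does not cover the 61 sense codons")

    def by_degeneracy(self, k: int) -> tuple[Family, ...]:
        return tuple(f for f in self.families if f.degeneracy == k)

    def __iter__(self):
        return iter(self.families)

    def __len__(self) -> int:
        return len(self.families)


WRIGHT_PARTITION = FamilyPartition("wright", _build_wright())
SUN_PARTITION = FamilyPartition("sun", _build_sun())

#: The eight four-fold degenerate families (Ala, Gly, Pro, Thr, Val and the
#: four-fold subsets of Leu, Ser, Arg), keyed by family name.  These are the
#: rows of the context-dependence contingency tables.
FOURFOLD_FAMILIES: dict[str, Family] = {
    f.name: f for f in SUN_PARTITION.by_degeneracy(4)
}


@dataclass
class CodonCountVector:
    """Counts over the 64 codons for one gene or a pooled set.

    Stop-codon slots are carried as structural zeros for per-gene vectors
    (the terminal stop is stripped during CDS extraction), which keeps the
    exclusion logic of positional statistics explicit.
    """

    counts: np.ndarray
    label: str = "pooled"

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.shape != (64,):
            raise ValueError("counts must have shape (64,)")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = arr

    @classmethod
    def from_dict(cls, counts: Mapping[str, int], label: str = "pooled") -> "CodonCountVector":
        arr = np.zeros(64, dtype=np.int64)
        for codon, n in counts.items():
            arr[CODON_INDEX[codon.upper()]] = n
        return cls(arr, label)

    def __getitem__(self, codon: str) -> int:
        return int(self.counts[CODON_INDEX[codon]])

    def total(self) -> int:
        return int(self.counts.sum())

    def sense_total(self) -> int:
        return self.total() - sum(self[s] for s in STOP_CODONS)

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CODONS), name=self.label)

    def __add__(self, other: "CodonCountVector") -> "CodonCountVector":
        return CodonCountVector(self.counts + other.counts, "pooled")


def count_codons(gene) -> CodonCountVector:
    """Tally the codons of a :class:`~chlorocodon.cds_io.GeneCDS` (or of any
    object with ``codons`` and a label-able identity) into a count vector."""
    arr = np.zeros(64, dtype=np.int64)
    for codon in gene.codons:
        arr[CODON_INDEX[codon]] += 1
    label = f"{gene.gene_name}|{gene.accession}" if hasattr(gene, "gene_name") else "gene"
    return CodonCountVector(arr, label)


def pool_counts(vectors: Sequence[CodonCountVector]) -> CodonCountVector:
    """Element-wise sum of count vectors (e.g. the 50 genes of one genome)."""
    if not vectors:
        raise ValueError("pool_counts requires a non-empty list")
    total = np.zeros(64, dtype=np.int64)
    for v in vectors:
        total += v.counts
    return CodonCountVector(total, "pooled")


def family_counts(
    vector: CodonCountVector, partition: FamilyPartition
) -> dict[str, tuple[dict[str, int], int]]:
    """Per-family codon counts and totals under the given partition."""
    out: dict[str, tuple[dict[str, int], int]] = {}
    for fam in partition:
        per = {c: vector[c] for c in fam.codons}
        out[fam.name] = (per, sum(per.values()))
    return out


def write_count_table(vectors: Iterable[CodonCountVector], path) -> pd.DataFrame:
    """Write a codon x sample TSV (rows = 64 codons, columns = labels)."""
    df = pd.DataFrame({v.label: v.as_series() for v in vectors})
    df.index.name = "codon"
    df.to_csv(path, sep="\t")
    return df
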