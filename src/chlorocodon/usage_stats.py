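"""Per-gene codon-usage statistics.

* positional GC of synonymous codons (GC1s/GC2s/GC3s),
* relative synonymous codon usage (RSCU) with bias classes,
* Wright's effective number of codons (Nc),
* Sun's improved Nc (six-fold families split, pseudocount homozygosity),
* the expected Nc under pure composition (a function of GC3s alone),
* the ending-base x bias-class summary over a set of RSCU profiles.

Conventions
-----------
GC1s/GC2s/GC3s are computed over *synonymous* codons: ATG (Met), TGG (Trp)
and stop codons are excluded at all three positions, so the three numbers
describe one consistent codon set.

RSCU for codon ``c`` of an amino acid with total count ``n_aa`` and
degeneracy ``k`` is ``count_c / (n_aa / k)``; the mean over a family is 1 by
construction.  Codons are classed as over-represented (RSCU > 1.6),
positively biased (1 < RSCU <= 1.6), unbiased (RSCU = 1), negatively biased
(0.6 <= RSCU < 1), under-represented (0 < RSCU < 0.6) or unused (RSCU = 0);
equality is tested within 1e-9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_core import (
    AMINO_ACIDS,
    CODONS,
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    SUN_PARTITION,
    WRIGHT_PARTITION,
    CodonCountVector,
    FamilyPartition,
)

__all__ = [
    "PositionalGC",
    "RSCUProfile",
    "NcResult",
    "EndingBaseSummary",
    "BIAS_CLASSES",
    "positional_gc",
    "rscu",
    "classify_rscu",
    "wright_nc",
    "sun_nc",
    "nc_result",
    "expected_nc",
    "ending_base_summary",
]

_EPS = 1e-9

#: Codons informative about synonymous choice: the 59 sense codons of
#: degenerate amino acids (ATG and TGG excluded).
DEGENERATE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if c not in ("ATG", "TGG")
)

_SYN_EXCLUDED = STOP_CODONS | {"ATG", "TGG"}

BIAS_CLASSES = ("over", "positive", "unbiased", "negative", "under", "unused")


@dataclass(frozen=True)
class PositionalGC:
    gc1s: float
    gc2s: float
    gc3s: float
    n_codons_used: int


def positional_gc(vector: CodonCountVector) -> PositionalGC:
    """GC percentage at each codon position over synonymous codons only."""
    used = 0
    gc = [0, 0, 0]
    for codon in CODONS:
        if codon in _SYN_EXCLUDED:
            continue
        n = vector[codon]
        if n == 0:
            continue
        used += n
        for k in range(3):
            if codon[k] in "GC":
                gc[k] += n
    if used == 0:
        raise ValueError(f"{vector.label}: no synonymous codons to compute GC from")
    return PositionalGC(*(100.0 * g / used for g in gc), n_codons_used=used)


def classify_rscu(value: float, count: int) -> str:
    if count == 0:
        return "unused"
    if abs(value - 1.0) <= _EPS:
        return "unbiased"
    if value > 1.6 + _EPS:
        return "over"
    if value > 1.0:
        return "positive"
    if value >= 0.6 - _EPS:
        return "negative"
    return "under"


@dataclass
class RSCUProfile:
    """Per-codon RSCU values plus bias class for one gene (or pooled set)."""

    rscu: dict  # codon -> float, only for codons of present amino acids
    bias_class: dict  # codon -> class name, 'absent' for absent amino acids
    absent_aa: frozenset
    label: str = ""

    def vector(self, support: Sequence[str] = DEGENERATE_CODONS) -> np.ndarray:
        """RSCU as a dense vector over ``support``; absent amino acids are 0."""
        return np.array([self.rscu.get(c, 0.0) for c in support])


def rscu(vector: CodonCountVector) -> RSCUProfile:
    if vector.sense_total() == 0:
        raise ValueError(f"{vector.label}: empty count vector")
    values: dict[str, float] = {}
    classes: dict[str, str] = {}
    absent: set[str] = set()
    for fam in WRIGHT_PARTITION:
        n_aa = sum(vector[c] for c in fam.codons)
        if n_aa == 0:
            absent.add(fam.amino_acid)
            for c in fam.codons:
                classes[c] = "absent"
            continue
        expected = n_aa / fam.degeneracy
        for c in fam.codons:
            val = vector[c] / expected
            values[c] = val
            classes[c] = classify_rscu(val, vector[c])
    return RSCUProfile(values, classes, frozenset(absent), vector.label)


# ---------------------------------------------------------------------------
# effective number of codons


def _wright_family_F(counts: Sequence[int]) -> float | None:
    """Wright's homozygosity estimator F-hat = (n * sum(p^2) - 1)/(n - 1).

    Returns None for families with fewer than 2 codons observed in total
    (the estimator is undefined there).
    """
    n = sum(counts)
    if n < 2:
        return None
    sum_p2 = sum((c / n) ** 2 for c in counts)
    return (n * sum_p2 - 1.0) / (n - 1.0)


def wright_nc(vector: CodonCountVector) -> float:
    """Wright's effective number of codons (six-fold families intact).

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, each mean homozygosity averaged over
    the observed families of that degeneracy.  If the single three-fold
    family (Ile) is unobserved, F3 falls back to the mean of F2 and F4; if a
    degeneracy class has no computable family, or a mean homozygosity is 0,
    the gene's Nc is reported as NaN (missing) rather than guessed.
    """
    means: dict[int, float] = {}
    for k in (2, 3, 4, 6):
        fs = [
            f
            for fam in WRIGHT_PARTITION.by_degeneracy(k)
            if (f := _wright_family_F([vector[c] for c in fam.codons])) is not None
        ]
        if fs:
            means[k] = float(np.mean(fs))
    if 3 not in means and 2 in means and 4 in means:
        means[3] = (means[2] + means[4]) / 2.0
    weights = {2: 9.0, 3: 1.0, 4: 5.0, 6: 3.0}
    if any(k not in means or means[k] <= 0 for k in weights):
        return float("nan")
    return 2.0 + sum(w / means[k] for k, w in weights.items())


def _sun_family_F(counts: Sequence[int]) -> float:
    """Pseudocount homozygosity: F = sum(((n_i + 1)/(n + k))^2)."""
    n = sum(counts)
    k = len(counts)
    return sum(((c + 1) / (n + k)) ** 2 for c in counts)


def sun_nc(vector: CodonCountVector) -> float:
    """Sun's improved Nc: six-fold families split into two-fold + four-fold
    subfamilies; Nc = sum over observed families of 1/F with pseudocount
    homozygosity.  Bounded by [number of observed families, number of sense
    codons in observed families]."""
    nc = 0.0
    n_fam = 0
    n_codon = 0
    for fam in SUN_PARTITION:
        counts = [vector[c] for c in fam.codons]
        if sum(counts) == 0:
            continue
        nc += 1.0 / _sun_family_F(counts)
        n_fam += 1
        n_codon += fam.degeneracy
    if n_fam == 0:
        raise ValueError(f"{vector.label}: no observed codon family")
    assert n_fam - _EPS <= nc <= n_codon + _EPS, "Sun Nc outside theoretical bounds"
    return nc


def expected_nc(gc3s_fraction: float) -> float:
    """Expected Nc under pure compositional (GC3s-driven) codon usage:
    Nc = 2 + s + 29 / (s^2 + (1 - s)^2) with s = GC3s as a fraction."""
    s = float(gc3s_fraction)
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"GC3s fraction must be in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


@dataclass(frozen=True)
class NcResult:
    wright_nc: float
    sun_nc: float
    expected_nc: float
    s: float  # GC3s as a fraction


def nc_result(vector: CodonCountVector) -> NcResult:
    """Wright's, Sun's, and expected Nc for one count vector."""
    s = positional_gc(vector).gc3s / 100.0
    return NcResult(wright_nc(vector), sun_nc(vector), expected_nc(s), s)


# ---------------------------------------------------------------------------
# ending-base summary (Table-2 style)


@dataclass
class EndingBaseSummary:
    """Percentage of (profile, codon) cells in each bias class, grouped by
    the codon's third base.  Cells of absent amino acids are excluded from
    the denominators; ATG and TGG are excluded (no synonymous choice)."""

    percentages: pd.DataFrame  # rows = bias classes, columns = A/C/G/T
    denominators: dict

    def subtotal(self, classes: Sequence[str]) -> pd.Series:
        """Computed subtotal over a group of classes (e.g. positive bias =
        'over' + 'positive')."""
        return self.percentages.loc[list(classes)].sum()


def ending_base_summary(profiles: Iterable[RSCUProfile]) -> EndingBaseSummary:
    counts = {b: {cls: 0 for cls in BIAS_CLASSES} for b in "ACGT"}
    denom = {b: 0 for b in "ACGT"}
    n_profiles = 0
    for prof in profiles:
        n_profiles += 1
        for codon in DEGENERATE_CODONS:
            cls = prof.bias_class.get(codon, "absent")
            if cls == "absent":
                continue
            base = codon[2]
            counts[base][cls] += 1
            denom[base] += 1
    if n_profiles == 0:
        raise ValueError("ending_base_summary needs at least one profile")
    table = pd.DataFrame(
        {
            b: [100.0 * counts[b][cls] / denom[b] if denom[b] else math.nan for cls in BIAS_CLASSES]
            for b in "ACGT"
        },
        index=list(BIAS_CLASSES),
    )
    return EndingBaseSummary(table, denom)


# ---------------------------------------------------------------------------
# per-gene summary table


def gene_stats_table(vectors: Sequence[CodonCountVector]) -> pd.DataFrame:
    """One row per count vector: n_codons, GC1s/GC2s/GC3s, Wright/Sun/expected Nc."""
    rows = []
    for v in vectors:
        pg = positional_gc(v)
        nc = nc_result(v)
        rows.append(
            {
                "label": v.label,
                "n_codons": v.sense_total(),
                "gc1s": pg.gc1s,
                "gc2s": pg.gc2s,
                "gc3s": pg.gc3s,
                "wright_nc": nc.wright_nc,
                "sun_nc": nc.sun_nc,
                "expected_nc": nc.expected_nc,
            }
        )
    return pd.DataFrame(rows)
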