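"""Mutation-versus-selection analyses.

Three complementary views of what drives codon usage:

* the gap between a gene's estimated Nc and the Nc expected from its GC3s
  alone (a gene under translational selection sits well below the expected
  curve);
* the neutrality plot, regressing mean GC at codon positions 1+2 (P12) on
  GC at position 3 (P3) — the slope acts as a mutation-selection
  equilibrium coefficient;
* context-dependence tests: if mutation at the third position is an
  independent single-site event, third-base frequencies within the eight
  four-fold degenerate families cannot depend on the first/second codon
  bases.  Six family x third-base contingency tables are tested for
  independence (Pearson chi-square for large pooled counts, Fisher's exact
  test for single-gene counts) with Benjamini-Hochberg correction across
  the six tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .codon_core import FOURFOLD_FAMILIES, CodonCountVector

__all__ = [
    "NeutralityPoint",
    "RegressionFit",
    "ContingencyTable",
    "IndependenceTestResult",
    "CONTEXT_DATASETS",
    "nc_deviation",
    "neutrality_point",
    "neutrality_regression",
    "build_context_tables",
    "test_independence",
    "bh_correct",
]

#: Codons excluded from the neutrality (P12-P3) statistics: the
#: single-codon amino acids, Ile's ATA, and the stops.
NEUTRALITY_EXCLUDED = frozenset({"ATG", "TGG", "ATA", "TAA", "TAG", "TGA"})

#: The six third-position context datasets: each row of a table is one
#: four-fold family or a pooled group of families.
CONTEXT_DATASETS: dict[str, tuple[tuple[str, tuple[str, ...]], ...]] = {
    "Leu4/Pro/Arg4": (("Leu4", ("Leu4",)), ("Pro", ("Pro",)), ("Arg4", ("Arg4",))),
    "Val/Ala/Gly": (("Val", ("Val",)), ("Ala", ("Ala",)), ("Gly", ("Gly",))),
    "Leu4+Val/Ser4+Pro+Thr+Ala/Arg4+Gly": (
        ("Leu4+Val", ("Leu4", "Val")),
        ("Ser4+Pro+Thr+Ala", ("Ser4", "Pro", "Thr", "Ala")),
        ("Arg4+Gly", ("Arg4", "Gly")),
    ),
    "Leu4/Val": (("Leu4", ("Leu4",)), ("Val", ("Val",))),
    "Arg4/Gly": (("Arg4", ("Arg4",)), ("Gly", ("Gly",))),
    "Ser4/Pro/Thr/Ala": (
        ("Ser4", ("Ser4",)),
        ("Pro", ("Pro",)),
        ("Thr", ("Thr",)),
        ("Ala", ("Ala",)),
    ),
}


def nc_deviation(estimated: float, expected: float) -> tuple[float, float]:
    """Absolute and relative shortfall of the estimated Nc below the
    expected (composition-only) Nc."""
    if expected <= 0:
        raise ValueError("expected Nc must be positive")
    diff = expected - estimated
    return diff, diff / expected


@dataclass(frozen=True)
class NeutralityPoint:
    gene: str
    P1: float
    P2: float
    P3: float

    @property
    def P12(self) -> float:
        return (self.P1 + self.P2) / 2.0


def neutrality_point(vector: CodonCountVector) -> NeutralityPoint:
    """GC percentage at each codon position with ATG, TGG, ATA and the stop
    codons excluded."""
    used = 0
    gc = [0, 0, 0]
    for codon in vector.as_series().index:
        if codon in NEUTRALITY_EXCLUDED:
            continue
        n = vector[codon]
        if n == 0:
            continue
        used += n
        for k in range(3):
            if codon[k] in "GC":
                gc[k] += n
    if used == 0:
        raise ValueError(f"{vector.label}: no codons left for the neutrality statistics")
    p1, p2, p3 = (100.0 * g / used for g in gc)
    return NeutralityPoint(vector.label, p1, p2, p3)


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int


def neutrality_regression(points: Sequence[NeutralityPoint]) -> RegressionFit:
    """Ordinary least squares of P12 on P3 with a two-sided slope t-test."""
    if len(points) < 3:
        raise ValueError("neutrality regression needs at least 3 points")
    x = np.array([pt.P3 for pt in points])
    y = np.array([pt.P12 for pt in points])
    if np.ptp(x) == 0:
        raise ValueError("P3 has zero variance; regression undefined")
    fit = stats.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n=len(points),
    )


@dataclass
class ContingencyTable:
    """Family-group x third-base counts for one context dataset."""

    name: str
    counts: pd.DataFrame  # rows = family groups, columns = A/C/G/T

    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def build_context_tables(vector: CodonCountVector) -> list[ContingencyTable]:
    """The six context-dependence contingency tables for one count vector.

    Rows are four-fold families (or cell-wise pooled groups of families);
    columns are the counts of third-position A/C/G/T within those families.
    """
    per_family = {}
    for name, fam in FOURFOLD_FAMILIES.items():
        row = {b: 0 for b in "ACGT"}
        for codon in fam.codons:
            row[codon[2]] += vector[codon]
        per_family[name] = row
    tables = []
    for ds_name, rows in CONTEXT_DATASETS.items():
        data = {
            label: {b: sum(per_family[f][b] for f in fams) for b in "ACGT"}
            for label, fams in rows
        }
        df = pd.DataFrame.from_dict(data, orient="index", columns=list("ACGT"))
        tables.append(ContingencyTable(ds_name, df))
    return tables


@dataclass(frozen=True)
class IndependenceTestResult:
    name: str
    method: str
    statistic: float | None
    p: float
    p_bh_significant: bool = False


def _log_table_prob(table: np.ndarray, logfact_margins: float, log_n_fact: float) -> float:
    """log P(table | margins) under the multivariate hypergeometric null."""
    return logfact_margins - log_n_fact - gammaln(table + 1.0).sum()


def _enumerate_fisher(observed: np.ndarray, max_tables: int) -> float | None:
    """Two-sided Fisher p by full enumeration of all tables with the observed
    margins: sum of probabilities of tables no more probable than the
    observed one.  Returns None if the enumeration exceeds ``max_tables``."""
    row_sums = observed.sum(axis=1)
    col_sums = observed.sum(axis=0)
    n = observed.sum()
    logfact_margins = gammaln(row_sums + 1.0).sum() + gammaln(col_sums + 1.0).sum()
    log_n_fact = gammaln(n + 1.0)
    log_p_obs = _log_table_prob(observed, logfact_margins, log_n_fact)
    r, c = observed.shape
    tol = 1e-7

    total_p = 0.0
    count = 0

    def recurse(row: int, remaining_cols: np.ndarray, log_acc: float):
        nonlocal total_p, count
        if count > max_tables:
            raise _EnumerationBudgetExceeded
        if row == r - 1:
            # last row forced by remaining column sums
            count += 1
            log_p = log_acc - gammaln(remaining_cols + 1.0).sum()
            if log_p <= log_p_obs + tol:
                total_p += math.exp(log_p)
            return
        target = row_sums[row]

        def fill(col: int, left: int, cols: np.ndarray, log_row: float):
            nonlocal count
            if col == c - 1:
                if left > cols[col]:
                    return
                cols2 = cols.copy()
                cols2[col] -= left
                recurse(row + 1, cols2, log_row - gammaln(left + 1.0))
                return
            lo = max(0, left - int(cols[col + 1 :].sum()))
            hi = min(left, int(cols[col]))
            for v in range(lo, hi + 1):
                cols2 = cols.copy()
                cols2[col] -= v
                fill(col + 1, left - v, cols2, log_row - gammaln(v + 1.0))

        fill(0, int(target), remaining_cols, log_acc)

    base = logfact_margins - log_n_fact
    try:
        recurse(0, col_sums.astype(np.int64), base)
    except _EnumerationBudgetExceeded:
        return None
    return min(total_p, 1.0)


class _EnumerationBudgetExceeded(Exception):
    pass


def _monte_carlo_fisher(observed: np.ndarray, n_samples: int, seed: int) -> float:
    """Seeded Monte-Carlo Fisher p: sample tables with the observed margins
    by permuting column labels, compare table probabilities."""
    rng = np.random.default_rng(seed)
    row_sums = observed.sum(axis=1)
    col_sums = observed.sum(axis=0)
    n = int(observed.sum())
    logfact_margins = gammaln(row_sums + 1.0).sum() + gammaln(col_sums + 1.0).sum()
    log_n_fact = gammaln(n + 1.0)
    log_p_obs = _log_table_prob(observed, logfact_margins, log_n_fact)
    r, c = observed.shape
    labels = np.repeat(np.arange(c), col_sums)
    row_edges = np.concatenate([[0], np.cumsum(row_sums)]).astype(int)
    hits = 0
    tol = 1e-7
    done = 0
    chunk = max(1, min(4096, n_samples))
    while done < n_samples:
        b = min(chunk, n_samples - done)
        # b independent permutations of the column labels at once
        order = np.argsort(rng.random((b, n)), axis=1)
        perm = labels[order]
        # per-sample log P(table): tables never materialized row by row
        log_p = np.full(b, logfact_margins - log_n_fact)
        for i in range(r):
            seg = perm[:, row_edges[i] : row_edges[i + 1]]
            for j in range(c):
                cell = (seg == j).sum(axis=1)
                log_p -= gammaln(cell + 1.0)
        hits += int((log_p <= log_p_obs + tol).sum())
        done += b
    return (hits + 1.0) / (n_samples + 1.0)


def test_independence(
    table: ContingencyTable,
    method: str = "pearson_chi2",
    max_enumeration: int = 500_000,
    mc_samples: int = 100_000,
    seed: int = 0,
) -> IndependenceTestResult:
    """Test whether third-base frequencies depend on the family (row).

    Zero rows/columns are dropped before testing so that the degrees of
    freedom reflect observed categories; a table with fewer than two
    non-zero rows or columns is degenerate and raises.  ``pearson_chi2`` is
    the asymptotic test (no continuity correction); ``fisher_exact`` uses
    full enumeration of tables with fixed margins when the enumeration fits
    in ``max_enumeration`` tables, else a seeded Monte-Carlo estimate with
    ``mc_samples`` draws.
    """
    df = table.counts
    df = df.loc[(df.sum(axis=1) > 0), (df.sum(axis=0) > 0)]
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError(f"{table.name}: degenerate table after dropping zero rows/columns")
    arr = df.to_numpy(dtype=np.int64)
    if method == "pearson_chi2":
        chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
        return IndependenceTestResult(table.name, method, float(chi2), float(p))
    if method == "fisher_exact":
        p = _enumerate_fisher(arr, max_enumeration)
        if p is None:
            p = _monte_carlo_fisher(arr, mc_samples, seed)
        return IndependenceTestResult(table.name, method, None, float(p))
    raise ValueError(f"unknown method {method!r}")


def bh_correct(
    results: Sequence[IndependenceTestResult], fdr: float = 0.05
) -> list[IndependenceTestResult]:
    """Benjamini-Hochberg step-up over one family of tests (e.g. the six
    context datasets of one genome or gene); sets the significance flags."""
    if not results:
        raise ValueError("bh_correct needs at least one result")
    if not (0.0 < fdr < 1.0):
        raise ValueError("fdr must be in (0, 1)")
    reject, _, _, _ = multipletests([r.p for r in results], alpha=fdr, method="fdr_bh")
    return [replace(r, p_bh_significant=bool(flag)) for r, flag in zip(results, reject)]
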