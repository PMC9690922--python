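"""Comparisons of codon usage across genes and genomes.

Cosine similarity of RSCU profiles measures how alike two coding sequences
use synonymous codons, independent of gene length; summing a gene's
similarities against all other genes gives a cumulate similarity index whose
percentile ranks the gene within the genome.  One-way repeated-measures
ANOVA tests whether a statistic (GC content, Nc, ...) differs between
conditions when the same set of subjects (genes, or genomes) is measured
under each condition.  Average-linkage (UPGMA) agglomeration on Euclidean
distances orders rows/columns for heat-map style outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .usage_stats import DEGENERATE_CODONS, RSCUProfile

__all__ = [
    "AnovaResult",
    "LinkageTree",
    "cosine_similarity",
    "similarity_analysis",
    "percentile_scores",
    "repeated_measures_anova",
    "average_linkage",
]


def cosine_similarity(a: RSCUProfile, b: RSCUProfile) -> float:
    """Cosine of the angle between two RSCU vectors over the 59 degenerate
    sense codons (Met and Trp carry no usage information and are excluded;
    codons of absent amino acids contribute 0)."""
    va = a.vector(DEGENERATE_CODONS)
    vb = b.vector(DEGENERATE_CODONS)
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for an all-zero RSCU vector")
    return float(np.dot(va, vb) / (na * nb))


def percentile_scores(values: pd.Series) -> pd.Series:
    """Percentile score of each value within the set: 100 * (count of values
    <= the value) / n."""
    n = len(values)
    ranks = values.rank(method="max")  # count of values <= value
    return 100.0 * ranks / n


def similarity_analysis(
    profiles: Mapping[str, RSCUProfile]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs cosine similarity matrix plus the cumulate-similarity table.

    Returns ``(matrix, cumulate)`` where ``matrix`` is a symmetric DataFrame
    with unit diagonal and ``cumulate`` has columns ``cumulate`` (row sum
    minus the diagonal) and ``percentile``.
    """
    names = sorted(profiles)
    if len(names) < 2:
        raise ValueError("similarity_analysis needs at least two profiles")
    vecs = np.array([profiles[n].vector(DEGENERATE_CODONS) for n in names])
    norms = np.linalg.norm(vecs, axis=1)
    if (norms == 0).any():
        raise ValueError("all-zero RSCU vector in similarity_analysis")
    mat = (vecs @ vecs.T) / np.outer(norms, norms)
    np.fill_diagonal(mat, 1.0)
    matrix = pd.DataFrame(mat, index=names, columns=names)
    cumulate = matrix.sum(axis=1) - 1.0
    table = pd.DataFrame(
        {"cumulate": cumulate, "percentile": percentile_scores(cumulate)}
    )
    return matrix, table


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_error: int
    p: float
    design: str


def repeated_measures_anova(matrix: pd.DataFrame, repeated_over: str = "columns") -> AnovaResult:
    """One-way repeated-measures ANOVA on a complete subjects x conditions table.

    ``repeated_over='columns'`` treats columns as the repeated conditions and
    rows as subjects (transpose semantics for ``'rows'``).  F is the
    between-condition mean square over the subject-by-condition residual mean
    square, with df = (k - 1) and (k - 1)(n - 1); no sphericity correction is
    applied.
    """
    if repeated_over not in ("columns", "rows"):
        raise ValueError("repeated_over must be 'columns' or 'rows'")
    data = matrix.to_numpy(dtype=float)
    if repeated_over == "rows":
        data = data.T
    if np.isnan(data).any():
        raise ValueError("repeated-measures ANOVA requires a complete matrix")
    n, k = data.shape  # subjects x conditions
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_error = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_error = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_error = ss_error / df_error
    if ms_error <= 0:
        f = 0.0 if ms_cond == 0 else float("inf")
    else:
        f = ms_cond / ms_error
    p = float(stats.f.sf(f, df_cond, df_error)) if np.isfinite(f) else 0.0
    return AnovaResult(float(f), df_cond, df_error, p, design=f"repeated over {repeated_over}")


@dataclass
class LinkageTree:
    """Average-linkage merge history over a set of labelled items."""

    labels: list
    linkage: np.ndarray  # scipy linkage matrix (n-1, 4)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def recurse(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = recurse(node.left, node.dist)
            right = recurse(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return recurse(tree, tree.dist) + ";"


def average_linkage(matrix: pd.DataFrame, axis: str = "rows") -> LinkageTree:
    """UPGMA-style agglomeration of rows (or columns) on Euclidean distances.

    Input rows are sorted by label before clustering so that tied merge
    decisions resolve deterministically.
    """
    if axis == "columns":
        matrix = matrix.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    matrix = matrix.sort_index()
    if len(matrix) < 2:
        raise ValueError("average_linkage needs at least two items")
    z = hierarchy.linkage(matrix.to_numpy(dtype=float), method="average", metric="euclidean")
    return LinkageTree(list(matrix.index), z)
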