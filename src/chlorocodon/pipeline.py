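"""End-to-end orchestration: extract -> stats -> compare -> neutrality -> context.

:func:`run_all` drives the full analysis over a directory of GenBank
genomes and writes every stage's TSV output plus a plain-text summary.
Outputs are byte-stable for a fixed configuration and input set: floats are
written with fixed precision and all orderings are sorted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cds_io, codon_core, comparative, mutation_selection, usage_stats
from .cds_io import GeneCDS
from .codon_core import CodonCountVector
from .usage_stats import RSCUProfile

__all__ = ["RunConfig", "run_all", "mean_rscu_profile"]

log = logging.getLogger("chlorocodon")

_FLOAT_FMT = "%.6f"


@dataclass
class RunConfig:
    input_dir: Path
    out_dir: Path
    overrides_path: Path | None = None
    min_aa: int = 100
    rscu_under: float = 0.6
    rscu_over: float = 1.6
    fdr: float = 0.05
    seed: int = 0
    focal_gene: str = "psbA"

    def __post_init__(self) -> None:
        if not (0 < self.rscu_under < 1 < self.rscu_over):
            raise ValueError("rscu thresholds must satisfy 0 < under < 1 < over")
        self.input_dir = Path(self.input_dir)
        self.out_dir = Path(self.out_dir)


def mean_rscu_profile(profiles: Sequence[RSCUProfile], label: str) -> RSCUProfile:
    """Average RSCU across homologous genes (one per genome).

    Per codon, values are averaged over the profiles whose amino acid is
    present; an amino acid absent from every profile stays absent.
    """
    values: dict[str, float] = {}
    classes: dict[str, str] = {}
    absent: set[str] = set()
    for fam in codon_core.WRIGHT_PARTITION:
        present = [p for p in profiles if fam.amino_acid not in p.absent_aa]
        if not present:
            absent.add(fam.amino_acid)
            for c in fam.codons:
                classes[c] = "absent"
            continue
        for c in fam.codons:
            val = float(np.mean([p.rscu[c] for p in present]))
            values[c] = val
            classes[c] = usage_stats.classify_rscu(val, count=1 if val > 0 else 0)
    return RSCUProfile(values, classes, frozenset(absent), label)


def _extract_all(config: RunConfig) -> dict[str, list[GeneCDS]]:
    paths = sorted(config.input_dir.glob("*.gb")) + sorted(config.input_dir.glob("*.gbk"))
    if not paths:
        raise FileNotFoundError(f"no GenBank files (*.gb, *.gbk) in {config.input_dir}")
    overrides = (
        cds_io.read_overrides(config.overrides_path) if config.overrides_path else []
    )
    per_genome: dict[str, list[GeneCDS]] = {}
    for path in paths:
        record = cds_io.parse_genbank(path)
        genes = cds_io.extract_cds(record, overrides=overrides)
        kept = cds_io.filter_genes(genes, min_aa=config.min_aa)
        log.info("%s: %d CDS extracted, %d retained", record.accession, len(genes), len(kept))
        per_genome[record.accession] = kept
    return per_genome


def run_all(config: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns a dict of the in-memory stage results (DataFrames and fits).
    """
    out = config.out_dir
    (out / "cds").mkdir(parents=True, exist_ok=True)

    # --- extraction ---------------------------------------------------
    per_genome = _extract_all(config)
    for acc, genes in sorted(per_genome.items()):
        cds_io.write_cds_fasta(sorted(genes, key=lambda g: g.gene_name), out / "cds" / f"{acc}.fasta")
    shared = cds_io.shared_gene_set(per_genome)
    (out / "shared_genes.txt").write_text("\n".join(shared) + "\n")

    accessions = sorted(per_genome)
    vectors: dict[tuple[str, str], CodonCountVector] = {}
    for acc in accessions:
        by_name = {g.gene_name: g for g in per_genome[acc]}
        for gene in shared:
            vectors[(gene, acc)] = codon_core.count_codons(by_name[gene])

    # --- per-gene statistics ------------------------------------------
    rows = []
    profiles: dict[tuple[str, str], RSCUProfile] = {}
    for gene in shared:
        for acc in accessions:
            v = vectors[(gene, acc)]
            pg = usage_stats.positional_gc(v)
            nc = usage_stats.nc_result(v)
            rows.append(
                {
                    "gene": gene,
                    "accession": acc,
                    "n_codons": v.sense_total(),
                    "gc1s": pg.gc1s,
                    "gc2s": pg.gc2s,
                    "gc3s": pg.gc3s,
                    "wright_nc": nc.wright_nc,
                    "sun_nc": nc.sun_nc,
                    "expected_nc": nc.expected_nc,
                }
            )
            profiles[(gene, acc)] = usage_stats.rscu(v)
    stats_df = pd.DataFrame(rows)
    stats_df.to_csv(out / "gene_stats.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    # RSCU long table
    rscu_rows = []
    for (gene, acc), prof in sorted(profiles.items()):
        for codon in usage_stats.DEGENERATE_CODONS:
            cls = prof.bias_class.get(codon, "absent")
            rscu_rows.append(
                {
                    "gene": gene,
                    "accession": acc,
                    "codon": codon,
                    "amino_acid": codon_core.GENETIC_CODE[codon],
                    "count": vectors[(gene, acc)][codon],
                    "rscu": prof.rscu.get(codon, float("nan")),
                    "class": cls,
                }
            )
    pd.DataFrame(rscu_rows).to_csv(out / "rscu_long.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    # ending-base summary over all gene x genome profiles
    ebs = usage_stats.ending_base_summary(list(profiles.values()))
    ebs.percentages.rename_axis("bias_class").to_csv(
        out / "ending_base_summary.tsv", sep="\t", float_format=_FLOAT_FMT
    )

    # --- comparative ---------------------------------------------------
    mean_profiles = {
        gene: mean_rscu_profile([profiles[(gene, acc)] for acc in accessions], gene)
        for gene in shared
    }
    sim_matrix, cumulate = comparative.similarity_analysis(mean_profiles)
    sim_matrix.rename_axis("gene").to_csv(out / "similarity_matrix.tsv", sep="\t", float_format=_FLOAT_FMT)
    cumulate.rename_axis("gene").to_csv(out / "cumulate_similarity.tsv", sep="\t", float_format=_FLOAT_FMT)

    anova_rows = []
    for stat in ("gc1s", "gc2s", "gc3s", "sun_nc"):
        wide = stats_df.pivot(index="gene", columns="accession", values=stat)
        between_genomes = comparative.repeated_measures_anova(wide, repeated_over="columns")
        between_genes = comparative.repeated_measures_anova(wide, repeated_over="rows")
        anova_rows.append({"statistic": stat, "comparison": "between_genomes",
                           "F": between_genomes.F, "df_between": between_genomes.df_between,
                           "df_error": between_genomes.df_error, "p": between_genomes.p})
        anova_rows.append({"statistic": stat, "comparison": "between_genes",
                           "F": between_genes.F, "df_between": between_genes.df_between,
                           "df_error": between_genes.df_error, "p": between_genes.p})
    anova_df = pd.DataFrame(anova_rows)
    anova_df.to_csv(out / "anova.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    gc_wide = stats_df.pivot(index="gene", columns="accession", values=["gc1s", "gc2s", "gc3s"])
    gc_wide.columns = [f"{acc}_{stat}" for stat, acc in gc_wide.columns]
    gene_tree = comparative.average_linkage(gc_wide, axis="rows")
    col_tree = comparative.average_linkage(gc_wide, axis="columns")
    (out / "linkage_genes.nwk").write_text(gene_tree.to_newick() + "\n")
    (out / "linkage_columns.nwk").write_text(col_tree.to_newick() + "\n")

    # --- neutrality and Nc deviations ---------------------------------
    points = []
    for gene in shared:
        pooled = codon_core.pool_counts([vectors[(gene, acc)] for acc in accessions])
        per_genome_pts = [
            mutation_selection.neutrality_point(vectors[(gene, acc)]) for acc in accessions
        ]
        points.append(
            mutation_selection.NeutralityPoint(
                gene,
                float(np.mean([p.P1 for p in per_genome_pts])),
                float(np.mean([p.P2 for p in per_genome_pts])),
                float(np.mean([p.P3 for p in per_genome_pts])),
            )
        )
    fit = mutation_selection.neutrality_regression(points)
    neut_df = pd.DataFrame(
        [{"gene": p.gene, "P1": p.P1, "P2": p.P2, "P3": p.P3, "P12": p.P12} for p in points]
    )
    neut_df.to_csv(out / "neutrality_points.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    (out / "neutrality_fit.txt").write_text(
        f"slope\t{fit.slope:.6f}\nintercept\t{fit.intercept:.6f}\n"
        f"r_squared\t{fit.r_squared:.6f}\np\t{fit.p:.6f}\nn\t{fit.n}\n"
    )

    mean_stats = stats_df.groupby("gene")[["gc3s", "sun_nc", "expected_nc"]].mean()
    dev_rows = []
    for gene, row in mean_stats.iterrows():
        diff, ratio = mutation_selection.nc_deviation(row["sun_nc"], row["expected_nc"])
        dev_rows.append({"gene": gene, "sun_nc": row["sun_nc"], "expected_nc": row["expected_nc"],
                         "difference": diff, "ratio": ratio})
    pd.DataFrame(dev_rows).to_csv(out / "nc_deviation.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    # --- context-dependence tests --------------------------------------
    genome_pool = codon_core.pool_counts(list(vectors.values()))
    genome_tables = mutation_selection.build_context_tables(genome_pool)
    genome_tests = mutation_selection.bh_correct(
        [mutation_selection.test_independence(t, "pearson_chi2") for t in genome_tables],
        fdr=config.fdr,
    )
    context_rows = [
        {"unit": "genome", "dataset": r.name, "method": r.method,
         "statistic": float("nan") if r.statistic is None else r.statistic,
         "p": r.p, "bh_significant": r.p_bh_significant}
        for r in genome_tests
    ]
    focal_tests = []
    if config.focal_gene in shared:
        focal_pool = codon_core.pool_counts(
            [vectors[(config.focal_gene, acc)] for acc in accessions]
        )
        focal_tables = mutation_selection.build_context_tables(focal_pool)
        focal_tests = mutation_selection.bh_correct(
            [
                mutation_selection.test_independence(t, "fisher_exact", seed=config.seed)
                for t in focal_tables
            ],
            fdr=config.fdr,
        )
        context_rows += [
            {"unit": config.focal_gene, "dataset": r.name, "method": r.method,
             "statistic": float("nan") if r.statistic is None else r.statistic,
             "p": r.p, "bh_significant": r.p_bh_significant}
            for r in focal_tests
        ]
    context_df = pd.DataFrame(context_rows)
    context_df.to_csv(out / "context_tests.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    # --- summary report -------------------------------------------------
    _write_summary(out / "summary.txt", stats_df, cumulate, fit, anova_df, context_df)

    return {
        "per_genome": per_genome,
        "shared": shared,
        "stats": stats_df,
        "profiles": profiles,
        "mean_profiles": mean_profiles,
        "similarity": sim_matrix,
        "cumulate": cumulate,
        "anova": anova_df,
        "neutrality_points": points,
        "neutrality_fit": fit,
        "context": context_df,
        "ending_base": ebs,
    }


def _write_summary(path, stats_df, cumulate, fit, anova_df, context_df) -> None:
    by_gene = stats_df.groupby("gene").agg(
        gc1s_mean=("gc1s", "mean"), gc1s_sd=("gc1s", "std"),
        gc2s_mean=("gc2s", "mean"), gc2s_sd=("gc2s", "std"),
        gc3s_mean=("gc3s", "mean"), gc3s_sd=("gc3s", "std"),
        nc_mean=("sun_nc", "mean"), nc_sd=("sun_nc", "std"),
    )
    lines = ["# chlorocodon summary", ""]
    lines.append(f"genomes: {stats_df['accession'].nunique()}  shared genes: {stats_df['gene'].nunique()}")
    for col, dp in (("gc1s_mean", 2), ("gc2s_mean", 2), ("gc3s_mean", 2), ("nc_mean", 3)):
        lo, hi = by_gene[col].idxmin(), by_gene[col].idxmax()
        lines.append(
            f"{col[:-5]}: min {by_gene.loc[lo, col]:.{dp}f} ({lo}), "
            f"max {by_gene.loc[hi, col]:.{dp}f} ({hi})"
        )
    lines.append(f"cumulate similarity: min {cumulate['cumulate'].idxmin()}, max {cumulate['cumulate'].idxmax()}")
    lines.append(
        f"neutrality fit: slope {fit.slope:.4f}, intercept {fit.intercept:.2f}, "
        f"R^2 {fit.r_squared:.4f}, p {fit.p:.3f}, n {fit.n}"
    )
    lines.append("")
    lines.append("per-gene mean +/- SD across genomes:")
    for gene, row in by_gene.iterrows():
        lines.append(
            f"  {gene}\tGC1s {row['gc1s_mean']:.2f}+/-{row['gc1s_sd']:.2f}"
            f"\tGC2s {row['gc2s_mean']:.2f}+/-{row['gc2s_sd']:.2f}"
            f"\tGC3s {row['gc3s_mean']:.2f}+/-{row['gc3s_sd']:.2f}"
            f"\tNc {row['nc_mean']:.3f}+/-{row['nc_sd']:.3f}"
        )
    lines.append("")
    lines.append("ANOVA:")
    for _, r in anova_df.iterrows():
        lines.append(
            f"  {r['statistic']} {r['comparison']}: F({r['df_between']:.0f},{r['df_error']:.0f})"
            f" = {r['F']:.3f}, p = {r['p']:.3f}"
        )
    lines.append("")
    lines.append("context-dependence tests (BH-corrected):")
    for _, r in context_df.iterrows():
        star = "*" if r["bh_significant"] else ""
        lines.append(f"  [{r['unit']}] {r['dataset']}: p = {r['p']:.3f}{star} ({r['method']})")
    Path(path).write_text("\n".join(lines) + "\n")
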