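"""GenBank parsing, CDS extraction, curation, and gene-set filtering.

Chloroplast genome records from RefSeq carry annotated CDS features, often
with multi-exon ``join(...)`` locations, minus-strand genes, and duplicated
genes inside the inverted repeat (IR).  This module turns such records into
clean in-frame codon lists:

1. :func:`parse_genbank` reads a flat file and collects every CDS feature
   (both IR copies, join structure and strand preserved);
2. :func:`extract_cds` applies declarative curation overrides (rename a
   misannotated gene, replace coordinates, drop a gene) and splices each CDS
   out of the genome sequence;
3. :func:`filter_genes` removes ambiguous codons codon-wise, drops genes
   without a proper stop codon or with internal stops, drops genes shorter
   than a minimum length, and keeps only the first IR copy of duplicated
   genes;
4. :func:`shared_gene_set` intersects gene names across genomes.

Coordinates are GenBank convention throughout: 1-based, inclusive.  Segments
of a CDS are stored in extraction order (the order in which Biopython's
location parser yields them), each tagged with its own strand; extraction
concatenates segments after reverse-complementing minus-strand ones.  This
also covers trans-spliced genes such as *rps12* whose segments sit on
opposite strands.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .codon_core import STOP_CODONS

__all__ = [
    "Segment",
    "CDSFeature",
    "GenomeRecord",
    "GeneCDS",
    "CurationOverride",
    "parse_genbank",
    "extract_cds",
    "filter_genes",
    "shared_gene_set",
    "read_overrides",
    "write_cds_fasta",
    "read_cds_fasta",
    "IR_DUPLICATED_GENES",
]

#: Genes carried twice by the chloroplast inverted repeat; only the first
#: annotated copy is retained by :func:`filter_genes`.
IR_DUPLICATED_GENES = frozenset({"ndhB", "rpl2", "rps12", "rps7", "ycf2"})

_CODON_RE = re.compile(r"^[ACGT]{3}$")


@dataclass(frozen=True)
class Segment:
    """One interval of a CDS, 1-based inclusive, with its own strand."""

    start: int
    end: int
    strand: int  # +1 or -1

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad segment {self.start}..{self.end}")
        if self.strand not in (1, -1):
            raise ValueError("strand must be +1 or -1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CDSFeature:
    """An annotated protein-coding feature (possibly one of two IR copies)."""

    gene_name: str
    segments: tuple[Segment, ...]
    copy_index: int = 1

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"CDS feature {self.gene_name!r} has no segments")


@dataclass
class GenomeRecord:
    accession: str
    species: str
    length_bp: int
    features: list[CDSFeature]
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")


@dataclass
class GeneCDS:
    """One gene's in-frame codon list (terminal stop removed)."""

    gene_name: str
    accession: str
    codons: list[str]
    stop_codon: str | None = None
    copy_index: int = 1
    had_ambiguous_removed: bool = False
    malformed: bool = False  # extracted length not divisible by 3

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    def sequence(self) -> str:
        return "".join(self.codons) + (self.stop_codon or "")


@dataclass(frozen=True)
class CurationOverride:
    """A declarative annotation fix applied before extraction.

    actions:
      * ``rename_gene``          payload = {"old": str, "new": str}
      * ``replace_coordinates``  payload = {"gene": str, "segments": [Segment, ...]}
        (upserts: replaces the gene's location, or adds the feature if the
        record lacks it — used e.g. to supply a missing IR copy)
      * ``drop_gene``            payload = {"gene": str}
    """

    accession: str
    action: str
    payload: tuple  # frozen as sorted (key, value) pairs

    @classmethod
    def make(cls, accession: str, action: str, **payload) -> "CurationOverride":
        required = {
            "rename_gene": {"old", "new"},
            "replace_coordinates": {"gene", "segments"},
            "drop_gene": {"gene"},
        }
        if action not in required:
            raise ValueError(f"unknown override action {action!r}")
        if set(payload) != required[action]:
            raise ValueError(f"{action} needs payload keys {sorted(required[action])}")
        items = tuple(sorted((k, tuple(v) if isinstance(v, list) else v) for k, v in payload.items()))
        return cls(accession, action, items)

    def get(self, key: str):
        return dict(self.payload)[key]


def parse_genbank(path) -> GenomeRecord:
    """Read one GenBank flat file into a :class:`GenomeRecord`.

    All CDS features carrying a ``/gene`` qualifier are collected, including
    second IR copies; ``copy_index`` counts occurrences of each gene name in
    annotation order.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # unreadable / not genbank
        raise ValueError(f"cannot read GenBank file {path}: {exc}") from exc

    features: list[CDSFeature] = []
    seen: dict[str, int] = {}
    for feat in record.features:
        if feat.type != "CDS":
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag") or [None])[0]
        if name is None:
            continue
        segments = tuple(
            Segment(int(part.start) + 1, int(part.end), int(part.strand or 1))
            for part in feat.location.parts
        )
        seen[name] = seen.get(name, 0) + 1
        features.append(CDSFeature(name, segments, copy_index=seen[name]))

    if not features:
        raise ValueError(f"no CDS features with gene qualifiers in {path}")

    accession = record.id or record.name
    species = record.annotations.get("organism", "")
    return GenomeRecord(
        accession=accession,
        species=species,
        length_bp=len(record.seq),
        features=features,
        sequence=str(record.seq).upper(),
    )


def _apply_overrides(
    record: GenomeRecord, overrides: Sequence[CurationOverride]
) -> list[CDSFeature]:
    features = [CDSFeature(f.gene_name, f.segments, f.copy_index) for f in record.features]
    for ov in overrides:
        if ov.accession != record.accession:
            continue
        if ov.action == "rename_gene":
            for f in features:
                if f.gene_name == ov.get("old"):
                    f.gene_name = ov.get("new")
        elif ov.action == "drop_gene":
            features = [f for f in features if f.gene_name != ov.get("gene")]
        elif ov.action == "replace_coordinates":
            gene = ov.get("gene")
            segs = tuple(ov.get("segments"))
            hits = [f for f in features if f.gene_name == gene]
            if hits:
                hits[0].segments = segs
            else:
                features.append(CDSFeature(gene, segs, copy_index=1))
    # re-number copies after renames/drops/additions
    seen: dict[str, int] = {}
    ordered = sorted(
        features, key=lambda f: (min(s.start for s in f.segments), f.gene_name)
    )
    for f in ordered:
        seen[f.gene_name] = seen.get(f.gene_name, 0) + 1
        f.copy_index = seen[f.gene_name]
    return ordered


def _extract_sequence(segments: Sequence[Segment], genome_seq: str) -> str:
    pieces = []
    for seg in segments:
        if seg.end > len(genome_seq):
            raise ValueError(f"segment {seg.start}..{seg.end} out of range")
        piece = genome_seq[seg.start - 1 : seg.end]
        if seg.strand == -1:
            piece = str(Seq(piece).reverse_complement())
        pieces.append(piece)
    return "".join(pieces).upper()


def extract_cds(
    record: GenomeRecord,
    genome_seq: str | None = None,
    overrides: Sequence[CurationOverride] = (),
) -> list[GeneCDS]:
    """Splice every CDS out of the genome, after applying curation overrides.

    The trailing codon is split off as ``stop_codon`` metadata when it is a
    stop; a CDS whose extracted length is not divisible by 3 is flagged
    ``malformed`` (and later removed by :func:`filter_genes`) rather than
    raising, since a single bad annotation should not abort a genome.
    """
    seq = (genome_seq if genome_seq is not None else record.sequence).upper()
    if not seq:
        raise ValueError(f"no genome sequence available for {record.accession}")

    out: list[GeneCDS] = []
    for feat in _apply_overrides(record, overrides):
        raw = _extract_sequence(feat.segments, seq)
        if len(raw) % 3 != 0:
            out.append(
                GeneCDS(feat.gene_name, record.accession, [], None, feat.copy_index, malformed=True)
            )
            continue
        codons = [raw[i : i + 3] for i in range(0, len(raw), 3)]
        stop = codons.pop() if codons and codons[-1] in STOP_CODONS else None
        out.append(GeneCDS(feat.gene_name, record.accession, codons, stop, feat.copy_index))
    return out


def filter_genes(
    genes: Iterable[GeneCDS],
    min_aa: int = 100,
    dedup: frozenset[str] | None = None,
) -> list[GeneCDS]:
    """Apply the curation filters to one genome's extracted genes.

    In order: ambiguous codons (any non-ACGT base) removed codon-wise;
    malformed genes and genes lacking a terminal TAA/TAG/TGA dropped; genes
    with internal stop codons dropped; genes shorter than ``min_aa`` codons
    (after ambiguity removal) dropped; for duplicated genes only the first
    copy kept.  Idempotent.
    """
    dedup = IR_DUPLICATED_GENES if dedup is None else dedup
    kept: list[GeneCDS] = []
    for gene in genes:
        if gene.malformed or gene.stop_codon not in STOP_CODONS:
            continue
        clean = [c for c in gene.codons if _CODON_RE.match(c)]
        removed = len(clean) < len(gene.codons)
        if any(c in STOP_CODONS for c in clean):
            continue
        if len(clean) < min_aa:
            continue
        kept.append(
            GeneCDS(
                gene.gene_name,
                gene.accession,
                clean,
                gene.stop_codon,
                gene.copy_index,
                had_ambiguous_removed=removed or gene.had_ambiguous_removed,
            )
        )
    # keep only the first copy of duplicated genes (IR copies in particular)
    first: dict[str, GeneCDS] = {}
    out = []
    for g in kept:
        if g.gene_name in dedup or sum(k.gene_name == g.gene_name for k in kept) > 1:
            if g.gene_name in first:
                continue
            first[g.gene_name] = g
        out.append(g)
    return out


def shared_gene_set(per_genome: Mapping[str, Sequence[GeneCDS]]) -> list[str]:
    """Sorted intersection of gene names present in every genome."""
    if len(per_genome) < 2:
        raise ValueError("shared_gene_set needs at least two genomes")
    sets = [set(g.gene_name for g in genes) for genes in per_genome.values()]
    shared = set.intersection(*sets)
    if not shared:
        raise ValueError("no gene is shared by all genomes")
    return sorted(shared)


# ---------------------------------------------------------------------------
# overrides file and FASTA intermediate

def read_overrides(path) -> list[CurationOverride]:
    """Parse the plain-text overrides config.

    One override per line, tab- or whitespace-separated::

        NC_020152.1  rename_gene          psi psbB
        NC_047481.1  replace_coordinates  ndhJ 54531..55007:-1
        NC_000000.1  drop_gene            xyz

    ``replace_coordinates`` takes comma-separated ``start..end[:strand]``
    segments (1-based inclusive; strand defaults to +1).  Lines starting with
    ``#`` are comments.
    """
    out: list[CurationOverride] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        acc, action = parts[0], parts[1]
        if action == "rename_gene":
            out.append(CurationOverride.make(acc, "rename_gene", old=parts[2], new=parts[3]))
        elif action == "drop_gene":
            out.append(CurationOverride.make(acc, "drop_gene", gene=parts[2]))
        elif action == "replace_coordinates":
            segs = []
            for token in parts[3].split(","):
                rng, _, strand = token.partition(":")
                start, end = rng.split("..")
                segs.append(Segment(int(start), int(end), int(strand) if strand else 1))
            out.append(
                CurationOverride.make(acc, "replace_coordinates", gene=parts[2], segments=segs)
            )
        else:
            raise ValueError(f"unknown override action {action!r} in {path}")
    return out


def write_cds_fasta(genes: Sequence[GeneCDS], path) -> None:
    """Write in-frame CDS to FASTA with ``gene|accession`` headers."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_name}|{g.accession}\n")
            seq = g.sequence()
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_cds_fasta(path) -> list[GeneCDS]:
    """Re-read the FASTA intermediate written by :func:`write_cds_fasta`."""
    out: list[GeneCDS] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_name, _, accession = rec.id.partition("|")
        seq = str(rec.seq).upper()
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        stop = codons.pop() if codons and codons[-1] in STOP_CODONS else None
        out.append(GeneCDS(gene_name, accession, codons, stop))
    return out
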