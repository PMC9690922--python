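import numpy as np
import pytest
from Bio import SeqIO
from Bio.Seq import Seq

from chlorocodon.cds_io import (
    CDSFeature,
    CurationOverride,
    GeneCDS,
    GenomeRecord,
    Segment,
    extract_cds,
    filter_genes,
    parse_genbank,
    read_cds_fasta,
    read_overrides,
    shared_gene_set,
    write_cds_fasta,
)


def _record(seq, features, accession="TEST.1"):
    return GenomeRecord(accession, "toy", len(seq), features, seq)


class TestParseAndExtract:
    def test_parse_fixture_finds_all_cds(self, fixture_genomes):
        genomes, paths, _ = fixture_genomes
        rec = parse_genbank(paths[0])
        assert rec.accession == genomes[0].label
        assert len(rec.features) == len(genomes[0].genes)

    def test_round_trip_through_fixture_writer(self, fixture_genomes):
        genomes, paths, _ = fixture_genomes
        for genome, path in zip(genomes, paths):
            extracted = {g.gene_name: g for g in extract_cds(parse_genbank(path))}
            for gene in genome.genes:
                got = extracted[gene.gene_name]
                assert got.codons == gene.codons
                assert got.stop_codon == gene.stop_codon

    def test_extraction_matches_biopython_oracle(self, fixture_genomes):
        """Our segment-wise extraction must equal Biopython's location.extract,
        including the minus-strand and two-segment-join features."""
        _, paths, _ = fixture_genomes
        bio = SeqIO.read(str(paths[0]), "genbank")
        ours = {g.gene_name: g.sequence() for g in extract_cds(parse_genbank(paths[0]))}
        for feat in bio.features:
            if feat.type != "CDS":
                continue
            name = feat.qualifiers["gene"][0]
            assert ours[name] == str(feat.location.extract(bio.seq))

    def test_minimal_plus_strand_cds(self):
        rec = _record("ATGAAATAA", [CDSFeature("toy", (Segment(1, 9, 1),))])
        (gene,) = extract_cds(rec)
        assert gene.codons == ["ATG", "AAA"] and gene.stop_codon == "TAA"

    def test_minus_strand_reverse_complement_involution(self):
        cds = "ATGGCCTAA"
        genome = "GG" + str(Seq(cds).reverse_complement()) + "CC"
        rec = _record(genome, [CDSFeature("rev", (Segment(3, 11, -1),))])
        (gene,) = extract_cds(rec)
        assert gene.sequence() == cds

    def test_length_not_divisible_by_three_flags_malformed(self):
        rec = _record("ATGAAAT", [CDSFeature("bad", (Segment(1, 7, 1),))])
        (gene,) = extract_cds(rec)
        assert gene.malformed and filter_genes([gene]) == []

    def test_segment_out_of_range_raises(self):
        rec = _record("ATGAAATAA", [CDSFeature("toy", (Segment(1, 99, 1),))])
        with pytest.raises(ValueError, match="out of range"):
            extract_cds(rec)

    def test_no_cds_features_is_hard_error(self, tmp_path):
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        path = tmp_path / "empty.gb"
        SeqIO.write(
            SeqRecord(Seq("ACGT" * 30), id="EMPTY.1", name="EMPTY",
                      annotations={"molecule_type": "DNA"}),
            str(path), "genbank",
        )
        with pytest.raises(ValueError, match="no CDS features"):
            parse_genbank(path)


class TestOverrides:
    def test_rename_gene(self):
        rec = _record("ATGAAATAA", [CDSFeature("psi", (Segment(1, 9, 1),))])
        ov = CurationOverride.make("TEST.1", "rename_gene", old="psi", new="psbB")
        names = [g.gene_name for g in extract_cds(rec, overrides=[ov])]
        assert names == ["psbB"]

    def test_replace_coordinates(self):
        # annotated interval is wrong (out of frame); override points at the real CDS
        genome = "CCC" + "ATGGGGTAA" + "CC"
        rec = _record(genome, [CDSFeature("ndhJ", (Segment(1, 5, 1),))])
        ov = CurationOverride.make(
            "TEST.1", "replace_coordinates", gene="ndhJ", segments=[Segment(4, 12, 1)]
        )
        (gene,) = extract_cds(rec, overrides=[ov])
        assert gene.codons == ["ATG", "GGG"] and gene.stop_codon == "TAA"

    def test_replace_coordinates_upserts_missing_gene(self):
        genome = "ATGAAATAA" + "ATGCCCTAA"
        rec = _record(genome, [CDSFeature("a", (Segment(1, 9, 1),))])
        ov = CurationOverride.make(
            "TEST.1", "replace_coordinates", gene="rps12", segments=[Segment(10, 18, 1)]
        )
        names = {g.gene_name for g in extract_cds(rec, overrides=[ov])}
        assert names == {"a", "rps12"}

    def test_drop_gene_and_accession_scoping(self):
        rec = _record("ATGAAATAA", [CDSFeature("x", (Segment(1, 9, 1),))])
        drop_other = CurationOverride.make("OTHER.1", "drop_gene", gene="x")
        assert len(extract_cds(rec, overrides=[drop_other])) == 1
        drop_here = CurationOverride.make("TEST.1", "drop_gene", gene="x")
        assert extract_cds(rec, overrides=[drop_here]) == []

    def test_overrides_file_round_trip(self, tmp_path):
        path = tmp_path / "overrides.txt"
        path.write_text(
            "# curation\n"
            "NC_020152.1\trename_gene\tpsi\tpsbB\n"
            "NC_047481.1\treplace_coordinates\tndhJ\t54531..55007:-1\n"
        )
        ovs = read_overrides(path)
        assert ovs[0].action == "rename_gene" and ovs[0].get("new") == "psbB"
        seg = ovs[1].get("segments")[0]
        assert (seg.start, seg.end, seg.strand) == (54531, 55007, -1)


def _gene(name, codons, stop="TAA", copy_index=1, acc="A"):
    return GeneCDS(name, acc, list(codons), stop, copy_index)


class TestFilterGenes:
    def test_short_gene_dropped_at_boundary(self):
        ok = _gene("long", ["ATG"] + ["AAA"] * 99)   # 100 codons
        short = _gene("short", ["ATG"] + ["AAA"] * 98)  # 99 codons
        kept = filter_genes([ok, short])
        assert [g.gene_name for g in kept] == ["long"]

    def test_ambiguous_codon_removed_codon_wise(self):
        codons = ["ATN"] + ["GAA"] * 119
        (kept,) = filter_genes([_gene("amb", codons)])
        assert kept.n_codons == 119 and kept.had_ambiguous_removed

    def test_missing_or_improper_stop_dropped(self):
        assert filter_genes([_gene("nostop", ["AAA"] * 120, stop=None)]) == []

    def test_internal_stop_dropped(self):
        codons = ["AAA"] * 60 + ["TGA"] + ["AAA"] * 60
        assert filter_genes([_gene("internal", codons)]) == []

    def test_ir_duplicate_keeps_first_copy(self):
        copy1 = _gene("ndhB", ["AAA"] * 120, copy_index=1)
        copy2 = _gene("ndhB", ["CCC"] * 120, copy_index=2)
        kept = filter_genes([copy1, copy2])
        assert len(kept) == 1 and kept[0].codons[0] == "AAA"

    def test_idempotent(self):
        genes = [
            _gene("a", ["ATG"] + ["AAA"] * 120),
            _gene("b", ["ATN"] + ["GGG"] * 150),
            _gene("short", ["AAA"] * 50),
        ]
        once = filter_genes(genes)
        twice = filter_genes(once)
        assert [(g.gene_name, g.codons) for g in once] == [
            (g.gene_name, g.codons) for g in twice
        ]

    def test_retained_genes_have_no_internal_stop_after_translation(self, fixture_genomes):
        from Bio.Seq import Seq

        _, paths, _ = fixture_genomes
        for path in paths:
            for gene in filter_genes(extract_cds(parse_genbank(path))):
                protein = str(Seq("".join(gene.codons)).translate())
                assert "*" not in protein


class TestSharedGeneSet:
    def test_identity(self):
        genes = [_gene("a", ["AAA"] * 120), _gene("b", ["CCC"] * 120)]
        assert shared_gene_set({"A": genes, "B": genes}) == ["a", "b"]

    def test_intersection(self):
        ga = [_gene(n, ["AAA"] * 120) for n in "abc"]
        gb = [_gene(n, ["AAA"] * 120) for n in "bcd"]
        assert shared_gene_set({"A": ga, "B": gb}) == ["b", "c"]

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError, match="no gene"):
            shared_gene_set({"A": [_gene("a", ["AAA"] * 120)], "B": [_gene("b", ["AAA"] * 120)]})


class TestFastaIntermediate:
    def test_round_trip(self, tmp_path, fixture_genomes):
        genomes, _, _ = fixture_genomes
        path = tmp_path / "cds.fasta"
        write_cds_fasta(genomes[0].genes, path)
        back = {g.gene_name: g for g in read_cds_fasta(path)}
        for gene in genomes[0].genes:
            assert back[gene.gene_name].codons == gene.codons
            assert back[gene.gene_name].stop_codon == gene.stop_codon
            assert back[gene.gene_name].accession == gene.accession
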