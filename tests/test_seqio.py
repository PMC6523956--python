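"""Genome model and format round-trips: GFF3 ranks, FASTA, CDS/protein
consistency and primer validation."""

import pytest

from soxkit import seqio
from soxkit.seqio import (
    CdsRecord,
    Gff3ParseError,
    PrimerRecord,
    ProteinRecord,
    read_cds_fasta,
    read_gff3,
    read_primer_table,
    read_protein_fasta,
    translate_cds,
    validate_cds_protein,
    write_cds_fasta,
    write_gff3,
    write_protein_fasta,
)

GFF = """##gff-version 3
chr1\tsrc\tgene\t100\t200\t.\t+\t.\tID=gA
chr1\tsrc\tgene\t500\t600\t.\t-\t.\tID=gB
chr1\tsrc\tgene\t300\t400\t.\t+\t.\tID=gC
chr1\tsrc\tmRNA\t100\t200\t.\t+\t.\tID=tA;Parent=gA
"""


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestGff3:
    def test_ranks_follow_start_order(self, tmp_path):
        genes = read_gff3(_write(tmp_path, "a.gff3", GFF))
        ranks = {g.gene_id: g.rank for g in genes}
        assert ranks == {"gA": 0, "gB": 2, "gC": 1}

    def test_non_gene_features_ignored(self, tmp_path):
        genes = read_gff3(_write(tmp_path, "a.gff3", GFF))
        assert len(genes) == 3

    def test_empty_file_gives_empty_list(self, tmp_path):
        assert read_gff3(_write(tmp_path, "e.gff3", "")) == []

    def test_malformed_line_reports_line_number(self, tmp_path):
        bad = "chr1\tsrc\tgene\t100\n"
        with pytest.raises(Gff3ParseError, match="line 1"):
            read_gff3(_write(tmp_path, "b.gff3", bad))

    def test_duplicate_gene_id_rejected(self, tmp_path):
        dup = (
            "chr1\ts\tgene\t1\t10\t.\t+\t.\tID=g1\n"
            "chr1\ts\tgene\t20\t30\t.\t+\t.\tID=g1\n"
        )
        with pytest.raises(Gff3ParseError, match="duplicate"):
            read_gff3(_write(tmp_path, "d.gff3", dup))

    def test_round_trip_identical(self, tmp_path):
        genes = read_gff3(_write(tmp_path, "a.gff3", GFF))
        out = tmp_path / "out.gff3"
        write_gff3(genes, out)
        assert read_gff3(out) == genes

    def test_rank_density_per_chromosome(self, default_sim, tmp_path):
        out = tmp_path / "sim.gff3"
        write_gff3(default_sim.genes, out)
        genes = read_gff3(out)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g.rank)
        for chrom, ranks in by_chrom.items():
            assert sorted(ranks) == list(range(len(ranks))), chrom


class TestFasta:
    def test_single_record(self, tmp_path):
        recs = read_protein_fasta(_write(tmp_path, "p.faa", ">p1\nMKV\n"))
        assert recs == [ProteinRecord("p1", "p1", "MKV")]

    def test_wrapped_lines_concatenated(self, tmp_path):
        recs = read_protein_fasta(_write(tmp_path, "p.faa", ">p1\nMK\nVA\n"))
        assert recs[0].sequence == "MKVA"

    def test_gene_link_token(self, tmp_path):
        recs = read_protein_fasta(
            _write(tmp_path, "p.faa", ">p1 gene=g9\nMKV\n")
        )
        assert recs[0].gene_id == "g9"

    def test_round_trip_preserves_records(self, tmp_path):
        records = [
            ProteinRecord("p1", "g1", "MKVLLA"),
            ProteinRecord("p2", "g2", "W" * 130),
        ]
        path = tmp_path / "rt.faa"
        write_protein_fasta(records, path)
        assert read_protein_fasta(path) == records
        cds = [CdsRecord("g1", "ATGAAATAA")]
        cpath = tmp_path / "rt.fna"
        write_cds_fasta(cds, cpath)
        assert read_cds_fasta(cpath) == cds

    def test_empty_sequence_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_protein_fasta(_write(tmp_path, "p.faa", ">p1\n>p2\nMK\n"))


class TestCdsConsistency:
    def test_terminal_stop_trimmed(self):
        assert translate_cds(CdsRecord("g", "ATGAAATAA")) == "MK"

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="internal stop"):
            translate_cds(CdsRecord("g", "ATGTAAAAA"))

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            translate_cds(CdsRecord("g", "ATGA"))

    def test_simulated_dataset_is_consistent(self, default_sim):
        validate_cds_protein(default_sim.cds, default_sim.proteins)

    def test_mismatch_detected(self):
        with pytest.raises(ValueError, match="does not match"):
            validate_cds_protein(
                [CdsRecord("g1", "ATGAAA")], [ProteinRecord("p1", "g1", "MV")]
            )


class TestPrimerTable:
    def test_valid_row(self, tmp_path):
        path = _write(
            tmp_path, "pr.tsv",
            "name\tsequence\tlength\nSox4-F\tCATCAAGCGACCGATGAACG\t20\n",
        )
        (rec,) = read_primer_table(path)
        assert rec.computed_length == 20 and rec.is_valid

    def test_length_mismatch_flagged(self, tmp_path):
        path = _write(
            tmp_path, "pr.tsv",
            "name\tsequence\tlength\nX-F\tCATCAAGCGACCGATGAACG\t21\n",
        )
        (rec,) = read_primer_table(path)
        assert not rec.is_valid

    def test_non_acgt_rejected_with_row_name(self, tmp_path):
        path = _write(
            tmp_path, "pr.tsv", "name\tsequence\tlength\nBadP\tACGU\t4\n"
        )
        with pytest.raises(ValueError, match="BadP"):
            read_primer_table(path)
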