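"""Readers/writers: validation contracts, round trips, coordinate conversion."""

import pandas as pd
import pytest

from snofam import core_io
from snofam.core_io import (ConservationTrack, SamplePanel, SnoRNARecord,
                            ValidationError)


def _write_annotation(path, rows):
    header = "\t".join(core_io.ANNOTATION_COLUMNS)
    lines = [header] + ["\t".join(str(v) for v in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")


ROW = ("s1", "SNORD1", "CD", "RF0001", "ACGT", "chr1", 100, 104, "+", ".", "intergenic")


class TestAnnotation:
    def test_family_grouping(self, tmp_path):
        rows = [
            ("s1", "n1", "CD", "RF0001", "ACGT", "chr1", 0, 4, "+", ".", "intergenic"),
            ("s2", "n2", "CD", "RF0001", "ACGA", "chr1", 10, 14, "+", "G1", "coding"),
            ("s3", "n3", "CD", "RF0001", "ACGC", "chr1", 20, 24, "-", "G2", "noncoding"),
        ]
        f = tmp_path / "a.tsv"
        _write_annotation(f, rows)
        records, families = core_io.read_annotation(f)
        assert len(records) == 3
        assert len(families) == 1
        assert families[0].member_ids == ("s1", "s2", "s3")
        assert not families[0].is_singleton

    def test_mixed_box_type_in_family_rejected(self, tmp_path):
        rows = [
            ("s1", "n1", "CD", "RF0001", "ACGT", "chr1", 0, 4, "+", ".", "intergenic"),
            ("s2", "n2", "HACA", "RF0001", "ACGT", "chr1", 10, 14, "+", ".", "intergenic"),
        ]
        f = tmp_path / "a.tsv"
        _write_annotation(f, rows)
        with pytest.raises(ValidationError, match="RF0001"):
            core_io.read_annotation(f)

    def test_duplicate_id_rejected(self, tmp_path):
        f = tmp_path / "a.tsv"
        _write_annotation(f, [ROW, ROW])
        with pytest.raises(ValidationError, match="s1"):
            core_io.read_annotation(f)

    def test_empty_but_headered_file(self, tmp_path):
        f = tmp_path / "a.tsv"
        _write_annotation(f, [])
        records, families = core_io.read_annotation(f)
        assert records == [] and families == []

    def test_round_trip(self, tmp_path):
        rows = [
            ("s1", "n1", "HACA", "RF9", "ACGU", "chr2", 5, 9, "-", "G1", "coding"),
            ("s2", "n2", "HACA", "RF9", "acgt", "chr2", 50, 54, "+", ".", "intergenic"),
        ]
        f1, f2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        _write_annotation(f1, rows)
        records, _ = core_io.read_annotation(f1)
        # sequences normalized at ingest: uppercase, U -> T
        assert records[0].sequence == "ACGT"
        core_io.write_annotation(records, f2)
        records2, _ = core_io.read_annotation(f2)
        assert records == records2

    def test_record_invariants(self):
        with pytest.raises(ValidationError):
            SnoRNARecord("x", "x", "CD", "F", "ACGT", "chr1", 10, 10, "+")
        with pytest.raises(ValidationError):  # host iff not intergenic
            SnoRNARecord("x", "x", "CD", "F", "ACGT", "chr1", 0, 4, "+",
                         host_gene_id="G1", host_biotype="intergenic")


class TestAbundance:
    def test_round_trip_bit_identical(self, tmp_path, toy_panel, toy_matrix):
        f1, f2 = tmp_path / "m1.tsv", tmp_path / "m2.tsv"
        core_io.write_abundance(toy_matrix, f1)
        m = core_io.read_abundance(f1, toy_panel)
        core_io.write_abundance(m, f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_negative_value_rejected_with_cell_address(self, tmp_path, toy_panel):
        f = tmp_path / "m.tsv"
        f.write_text("snorna_id\tbrain_1\tbrain_2\tliver_1\tliver_2\n"
                     "s1\t1.0\t-1.0\t0.0\t0.0\n")
        with pytest.raises(ValidationError, match=r"s1.*brain_2"):
            core_io.read_abundance(f, toy_panel)

    def test_missing_panel_sample_rejected(self, tmp_path, toy_panel):
        f = tmp_path / "m.tsv"
        f.write_text("snorna_id\tbrain_1\tbrain_2\tliver_1\ns1\t1\t1\t1\n")
        with pytest.raises(ValidationError, match="liver_2"):
            core_io.read_abundance(f, toy_panel)

    def test_unknown_sample_rejected(self, tmp_path, toy_panel):
        f = tmp_path / "m.tsv"
        f.write_text("snorna_id\tbrain_1\tbrain_2\tliver_1\tliver_2\tkidney_1\n"
                     "s1\t1\t1\t1\t1\t1\n")
        with pytest.raises(ValidationError, match="kidney_1"):
            core_io.read_abundance(f, toy_panel)


class TestGtf:
    GTF = "\n".join([
        "\t".join(["chr1", "x", "gene", "1", "500", ".", "+", ".",
                   'gene_id "G1"; gene_biotype "protein_coding";']),
        "\t".join(["chr1", "x", "transcript", "1", "500", ".", "+", ".",
                   'gene_id "G1"; transcript_id "T1"; transcript_name "T1";']),
        "\t".join(["chr1", "x", "exon", "1", "100", ".", "+", ".",
                   'gene_id "G1"; transcript_id "T1";']),
        "\t".join(["chr1", "x", "exon", "201", "500", ".", "+", ".",
                   'gene_id "G1"; transcript_id "T1";']),
    ]) + "\n"

    def test_parse_and_coordinate_conversion(self, tmp_path):
        f = tmp_path / "g.gtf"
        f.write_text(self.GTF)
        model = core_io.read_gtf(f)
        gene = model.genes["G1"]
        t = gene.transcripts[0]
        assert t.exon_count == 2
        # GTF 1-based closed 1..100 -> internal 0-based half-open [0, 100)
        assert t.exons[0] == (0, 100)
        assert t.exons[1] == (200, 500)
        assert gene.biotype == "coding"

    def test_round_trip(self, tmp_path):
        f1, f2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        f1.write_text(self.GTF)
        model = core_io.read_gtf(f1)
        core_io.write_gtf(model, f2)
        assert core_io.read_gtf(f2).genes == model.genes

    def test_malformed_line_reports_line_number(self, tmp_path):
        f = tmp_path / "g.gtf"
        f.write_text(self.GTF + "chr1\tonly_two_fields\n")
        with pytest.raises(ValidationError, match="line 5"):
            core_io.read_gtf(f)

    def test_inverted_interval_rejected(self, tmp_path):
        f = tmp_path / "g.gtf"
        bad = self.GTF.replace("exon\t201\t500", "exon\t500\t201")
        f.write_text(bad)
        with pytest.raises(ValidationError, match="line 4"):
            core_io.read_gtf(f)


class TestTracks:
    def test_bedgraph_single_interval(self, tmp_path):
        f = tmp_path / "c.bedgraph"
        f.write_text("chr1\t0\t100\t0.8\n")
        track = core_io.read_bedgraph(f)
        assert track.intervals() == [("chr1", 0, 100, 0.8)]

    def test_bedgraph_overlap_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            ConservationTrack([("chr1", 0, 100, 0.5), ("chr1", 50, 150, 0.5)])

    def test_bedgraph_round_trip(self, tmp_path):
        f1, f2 = tmp_path / "a.bedgraph", tmp_path / "b.bedgraph"
        f1.write_text("chr1\t0\t100\t0.8000\nchr2\t10\t20\t0.1000\n")
        track = core_io.read_bedgraph(f1)
        core_io.write_bedgraph(track, f2)
        assert core_io.read_bedgraph(f2).intervals() == track.intervals()

    def test_bed_round_trip_and_dedup(self, tmp_path):
        f1, f2 = tmp_path / "a.bed", tmp_path / "b.bed"
        f1.write_text("chr1\t5\t6\nchr1\t5\t6\nchr1\t9\t11\n")
        snps = core_io.read_bed(f1)
        assert snps.sites() == [("chr1", 5), ("chr1", 9), ("chr1", 10)]
        core_io.write_bed(snps, f2)
        assert core_io.read_bed(f2).sites() == snps.sites()


class TestSamplePanel:
    def test_round_trip(self, tmp_path, toy_panel):
        f = tmp_path / "s.tsv"
        core_io.write_sample_panel(toy_panel, f)
        panel = core_io.read_sample_panel(f)
        assert panel == toy_panel

    def test_duplicate_sample_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            SamplePanel.from_pairs([("a", "brain"), ("a", "liver")])
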