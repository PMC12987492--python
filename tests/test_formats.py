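"""Wiggle/bedGraph/GFF parsing and the MasterTable/GFF/wiggle writers."""

import numpy as np
import pytest

from tsscall.errors import BoundsError, ParseError
from tsscall.formats import (read_bedgraph, read_fasta, read_gff,
                             read_wiggle, write_gff_output,
                             write_master_table, write_normalized_tracks)
from tsscall.model import (FORWARD, REVERSE, ConditionRecord, ConsolidatedTss,
                           ExperimentLayout, TssClassification)
from tsscall.synthetic import example_spec, generate_tracks

from conftest import make_pair


class TestReadWiggle:
    def test_variable_step_dense_with_zeros(self, tmp_path):
        path = tmp_path / "a.wig"
        path.write_text("variableStep chrom=c1\n3 5.0\n4 7.5\n")
        (track,) = read_wiggle(path, expected_length=6)
        assert track.replicon_id == "c1"
        assert track.values.tolist() == [0, 0, 5.0, 7.5, 0, 0]

    def test_fixed_step(self, tmp_path):
        path = tmp_path / "a.wig"
        path.write_text("fixedStep chrom=c1 start=2 step=1\n1\n2\n")
        (track,) = read_wiggle(path)
        assert track.value_at(2) == 1 and track.value_at(3) == 2
        assert track.value_at(1) == 0

    def test_negative_values_stored_absolute(self, tmp_path):
        path = tmp_path / "a.wig"
        path.write_text("variableStep chrom=c1\n10 -3.5\n")
        (track,) = read_wiggle(path)
        assert track.value_at(10) == 3.5

    def test_track_line_skipped_and_multiple_blocks(self, tmp_path):
        path = tmp_path / "a.wig"
        path.write_text('track type=wiggle_0 name="x"\n'
                        "variableStep chrom=c1\n2 1.0\n"
                        "variableStep chrom=c2\n1 4.0\n"
                        "variableStep chrom=c1\n5 2.0\n")
        tracks = {t.replicon_id: t for t in read_wiggle(path)}
        assert tracks["c1"].values.tolist() == [0, 1.0, 0, 0, 2.0]
        assert tracks["c2"].values.tolist() == [4.0]

    def test_malformed_declaration_names_line(self, tmp_path):
        path = tmp_path / "a.wig"
        path.write_text("variableStep chrom=c1\n1 1.0\nfixedStep chrom=c1\n")
        with pytest.raises(ParseError, match=":3"):
            read_wiggle(path)

    def test_position_beyond_expected_length(self, tmp_path):
        path = tmp_path / "a.wig"
        path.write_text("variableStep chrom=c1\n9 1.0\n")
        with pytest.raises(BoundsError):
            read_wiggle(path, expected_length=5)


class TestReadBedgraph:
    def test_interval_conversion(self, tmp_path):
        path = tmp_path / "a.bg"
        path.write_text("c1\t0\t3\t2.0\n")
        (track,) = read_bedgraph(path)
        assert track.values.tolist() == [2.0, 2.0, 2.0]

    def test_negative_value_absolute(self, tmp_path):
        path = tmp_path / "a.bg"
        path.write_text("c1\t5\t6\t-1.0\n")
        (track,) = read_bedgraph(path)
        assert track.value_at(6) == 1.0

    def test_empty_file(self, tmp_path):
        path = tmp_path / "a.bg"
        path.write_text("")
        assert read_bedgraph(path) == []

    def test_overlap_is_error(self, tmp_path):
        path = tmp_path / "a.bg"
        path.write_text("c1\t0\t5\t1.0\nc1\t3\t8\t2.0\n")
        with pytest.raises(ParseError, match="overlap"):
            read_bedgraph(path)

    def test_equivalent_to_wiggle(self, tmp_path):
        """The same profile encoded both ways loads identically."""
        wig = tmp_path / "a.wig"
        wig.write_text("variableStep chrom=c1\n3 5.0\n4 5.0\n7 1.5\n")
        bg = tmp_path / "a.bg"
        bg.write_text("c1\t2\t4\t5.0\nc1\t6\t7\t1.5\n")
        (tw,) = read_wiggle(wig, expected_length=8)
        (tb,) = read_bedgraph(bg, expected_length=8)
        np.testing.assert_array_equal(tw.values, tb.values)


class TestReadGff:
    def test_gene_row(self, tmp_path):
        path = tmp_path / "a.gff"
        path.write_text("##gff-version 3\n"
                        "c1\t.\tgene\t100\t400\t.\t+\t.\t"
                        "ID=g1;locus_tag=b0001;gene=thrL\n")
        (gene,) = read_gff(path)
        assert (gene.locus_tag, gene.name, gene.start, gene.end,
                gene.strand) == ("b0001", "thrL", 100, 400, FORWARD)

    def test_cds_fallback_when_no_gene_rows(self, tmp_path):
        path = tmp_path / "a.gff"
        path.write_text("c1\t.\tCDS\t10\t90\t.\t-\t.\t"
                        "ID=c1cds;product=hypothetical protein\n")
        (gene,) = read_gff(path)
        assert gene.locus_tag == "c1cds"
        assert gene.product == "hypothetical protein"
        assert gene.strand == REVERSE

    def test_id_fallback_and_child_cds_product(self, tmp_path):
        path = tmp_path / "a.gff"
        path.write_text("c1\t.\tgene\t5\t50\t.\t+\t.\tID=g9\n"
                        "c1\t.\tCDS\t5\t50\t.\t+\t.\t"
                        "ID=cds9;Parent=g9;product=widget synthase\n")
        (gene,) = read_gff(path)
        assert gene.locus_tag == "g9"
        assert gene.product == "widget synthase"

    def test_missing_columns(self, tmp_path):
        path = tmp_path / "a.gff"
        path.write_text("c1\tgene\t100\n")
        with pytest.raises(ParseError):
            read_gff(path)


def _tss(position=500, strand=FORWARD, conditions=("A", "B", "C"),
         classifications=None):
    records = {c: ConditionRecord(detected=True, enriched=True,
                                  step_height=10.0, step_factor=5.0,
                                  enrichment_factor=3.0, det_count=1,
                                  position=position)
               for c in conditions}
    t = ConsolidatedTss("c1", position, strand, records)
    t.classifications = classifications or [TssClassification("orphan")]
    return t


class TestMasterTable:
    def _layout(self, conditions):
        return ExperimentLayout(list(conditions),
                                {c: ["r1"] for c in conditions})

    def test_row_count_is_conditions_times_classes(self, tmp_path):
        t = _tss(classifications=[
            TssClassification("primary", "b1", "x", "p", 100, -100, 300),
            TssClassification("antisense", "b2", "y", "q")])
        path = tmp_path / "master.tsv"
        write_master_table([t], self._layout("ABC"), path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 1 + 3 * 2

    def test_empty_tss_list_writes_header_only(self, tmp_path):
        path = tmp_path / "master.tsv"
        write_master_table([], self._layout("A"), path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 1 and lines[0].startswith("SuperPos\t")

    def test_row_fields_match_two_decimal_convention(self, tmp_path):
        """A reverse-strand primary TSS renders position, strand, height
        and gene fields the way the tabular output is specified."""
        t = _tss(position=2099734, strand=REVERSE, conditions=("A",),
                 classifications=[TssClassification(
                     "primary", "b2028", "ugd",
                     "UDP-glucose 6-dehydrogenase", 60, -60, 1166)])
        t.records["A"].step_height = 316.07
        path = tmp_path / "master.tsv"
        write_master_table([t], self._layout("A"), path)
        row = path.read_text().strip().split("\n")[1].split("\t")
        assert "2099734" in row and "-" in row
        assert "316.07" in row and "b2028" in row and "ugd" in row

    def test_row_count_conservation(self, tmp_path):
        """Data rows == sum over TSS of (#conditions x #classifications)."""
        tss = [
            _tss(position=100, classifications=[
                TssClassification("orphan")]),
            _tss(position=300, classifications=[
                TssClassification("primary", "b1"),
                TssClassification("antisense", "b2"),
                TssClassification("internal", "b3")]),
        ]
        layout = self._layout("AB")
        path = tmp_path / "master.tsv"
        write_master_table(tss, layout, path)
        rows = path.read_text().strip().split("\n")[1:]
        assert len(rows) == 2 * 1 + 2 * 3


class TestGffOutput:
    def test_single_class_row(self, tmp_path):
        t = _tss(conditions=("A",), classifications=[
            TssClassification("primary", "b0001")])
        path = tmp_path / "a.gff"
        write_gff_output([t], "A", path)
        line = path.read_text().strip().split("\n")[1]
        fields = line.split("\t")
        assert fields[2] == "TSS"
        assert fields[3] == fields[4] == "500"
        assert fields[6] == "+"
        assert "locus_tag=b0001" in fields[8]

    def test_no_tss_for_condition(self, tmp_path):
        t = _tss(conditions=("A",))
        path = tmp_path / "b.gff"
        write_gff_output([t], "B", path)
        assert path.read_text().strip() == "##gff-version 3"

    def test_two_classes_serialized(self, tmp_path):
        t = _tss(conditions=("A",), classifications=[
            TssClassification("primary", "b1"),
            TssClassification("antisense", "b2")])
        path = tmp_path / "a.gff"
        write_gff_output([t], "A", path)
        attrs = path.read_text().strip().split("\n")[1].split("\t")[8]
        assert "antisense,primary" in attrs


class TestNormalizedTrackExport:
    def test_round_trip_and_file_count(self, tmp_path):
        spec = example_spec(n_conditions=2, n_replicates=2, noise=1.0, seed=5)
        pairs = generate_tracks(spec)
        written = write_normalized_tracks(pairs, tmp_path / "norm")
        assert len(written) == 2 * 2 * 2 * 2  # cond x rep x strand x library

        by_key = {p.key: p for p in pairs}
        for path in written:
            cond, rep, strand_slug, lib = path.stem.split("_")
            strand = FORWARD if strand_slug == "fwd" else REVERSE
            (track,) = read_wiggle(path, strand=strand)
            pair = by_key[(cond, rep, strand, "chr")]
            original = pair.enriched if lib == "enriched" else pair.control
            np.testing.assert_allclose(track.values,
                                       original.values[:track.length],
                                       atol=1e-6)
            # zero positions omitted: trailing zeros may shorten the track
            assert np.all(original.values[track.length:] == 0)

    def test_zero_positions_omitted(self, tmp_path):
        pair = make_pair([0, 5.0, 0, 2.0, 0])
        (path,) = [p for p in write_normalized_tracks([pair], tmp_path)
                   if "enriched" in p.name]
        body = [l for l in path.read_text().split("\n")
                if l and not l.startswith(("track", "variableStep"))]
        assert [l.split()[0] for l in body] == ["2", "4"]


def test_fasta_reader(tmp_path):
    path = tmp_path / "g.fa"
    path.write_text(">c1 description\nacgt\nACGT\n")
    assert read_fasta(path) == {"c1": "ACGTACGT"}
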