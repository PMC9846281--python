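"""Genome model: readers, coordinate conventions, sense-strand extraction."""

import warnings

import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO
from hypothesis import given, strategies as st

from mitochar.errors import CoordinateError, FormatError
from mitochar.model import (
    AnnotatedMitogenome,
    MitoFeature,
    feature_sequence,
    normalize_gene_name,
    read_feature_table,
    read_genbank,
    reverse_complement,
    write_feature_table,
)


def _write_genbank(path, seq, features):
    rec = SeqRecord(Seq(seq), id="SYNTH1", annotations={"molecule_type": "DNA"})
    rec.features = features
    SeqIO.write(rec, str(path), "genbank")


class TestReadGenbank:
    def test_strand_and_coordinate_conventions(self, tmp_path):
        """'+' CDS maps to strand H with 1-based inclusive coords;
        complement() maps to strand L; join across the origin gives
        start > end; name synonyms are normalised."""
        seq = "ATGAAATAA" + "C" * 91
        feats = [
            SeqFeature(SimpleLocation(0, 9, strand=1), type="CDS",
                       qualifiers={"gene": ["COI"]}),
            SeqFeature(SimpleLocation(9, 30, strand=-1), type="CDS",
                       qualifiers={"gene": ["nad6"]}),
            SeqFeature(SimpleLocation(30, 40, strand=1), type="tRNA",
                       qualifiers={"product": ["tRNA-Phe"],
                                   "anticodon": ["(pos:33..35,aa:Phe,seq:gaa)"]}),
            SeqFeature(SimpleLocation(40, 60, strand=1), type="D-loop"),
            SeqFeature(
                CompoundLocation([SimpleLocation(90, 100, strand=1),
                                  SimpleLocation(0, 6, strand=1)]),
                type="CDS", qualifiers={"gene": ["CYTB"]},
            ),
        ]
        path = tmp_path / "synth.gb"
        _write_genbank(path, seq, feats)
        g = read_genbank(path)

        assert g.length == 100
        cox1, nd6, trna, dloop, cytb = g.features
        assert (cox1.name, cox1.cls, cox1.start, cox1.end, cox1.strand) == (
            "COX1", "PCG", 1, 9, "H")
        assert (nd6.name, nd6.strand, nd6.start, nd6.end) == ("ND6", "L", 10, 30)
        assert trna.cls == "tRNA" and trna.anticodon == "GAA"
        assert dloop.cls == "noncoding"
        assert cytb.start == 91 and cytb.end == 6 and cytb.wraps_origin
        assert cytb.length(g.length) == 16

    def test_missing_sequence_is_a_format_error(self, tmp_path):
        path = tmp_path / "empty.gb"
        _write_genbank(path, "N" * 50, [])
        with pytest.raises(FormatError):
            read_genbank(path)


class TestFeatureTable:
    def test_bundled_table_parses_published_layout(self, table1):
        assert len(table1.features) == 39
        assert table1.length == 16592
        assert table1.class_counts() == {
            "PCG": 13, "tRNA": 22, "rRNA": 2, "noncoding": 2}
        assert not table1.has_sequence
        with pytest.raises(FormatError):
            feature_sequence(table1, table1.features[0])

    def test_round_trip_preserves_everything(self, tmp_path, synth_genome):
        genome, _ = synth_genome
        tsv, fasta = tmp_path / "f.tsv", tmp_path / "g.fasta"
        write_feature_table(genome, tsv, fasta)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            back = read_feature_table(tsv, fasta)
        assert back.seq == genome.seq
        assert back.features == genome.features

    def test_wraparound_row_and_comma_separated_coordinates(self, tmp_path):
        tsv = tmp_path / "wrap.tsv"
        tsv.write_text("name\tcls\tfrom\tto\tstrand\nX\tnoncoding\t16,590\t3\tH\n")
        fasta = tmp_path / "g.fasta"
        fasta.write_text(">g\n" + "A" * 16592 + "\n")
        g = read_feature_table(tsv, fasta)
        (x,) = g.features
        assert x.wraps_origin and x.length(g.length) == 6

    def test_header_only_table_with_sequence_is_empty_genome(self, tmp_path):
        tsv = tmp_path / "empty.tsv"
        tsv.write_text("name\tcls\tfrom\tto\tstrand\n")
        fasta = tmp_path / "g.fasta"
        fasta.write_text(">g\nACGTACGT\n")
        g = read_feature_table(tsv, fasta)
        assert g.features == [] and g.length == 8

    @pytest.mark.parametrize(
        "row,err",
        [
            ("X\tgene\t1\t5\tH", FormatError),  # unknown cls token
            ("X\tPCG\tone\t5\tH", FormatError),  # non-integer coordinate
            ("X\tPCG\t1\t5\tZ", FormatError),  # bad strand
        ],
    )
    def test_malformed_rows_raise(self, tmp_path, row, err):
        tsv = tmp_path / "bad.tsv"
        tsv.write_text("name\tcls\tfrom\tto\tstrand\n" + row + "\n")
        fasta = tmp_path / "g.fasta"
        fasta.write_text(">g\nACGTACGTAC\n")
        with pytest.raises(err):
            read_feature_table(tsv, fasta)

    def test_duplicate_names_warn_but_parse(self, tmp_path):
        tsv = tmp_path / "dup.tsv"
        tsv.write_text(
            "name\tcls\tfrom\tto\tstrand\n"
            "tRNA-Leu\ttRNA\t1\t3\tH\n"
            "tRNA-Leu\ttRNA\t5\t8\tH\n"
        )
        fasta = tmp_path / "g.fasta"
        fasta.write_text(">g\nACGTACGTAC\n")
        with pytest.warns(UserWarning, match="duplicate"):
            g = read_feature_table(tsv, fasta)
        assert len(g.features) == 2


class TestFeatureSequence:
    @pytest.mark.parametrize(
        "seq,start,end,strand,expected",
        [
            ("ATGC", 1, 4, "H", "ATGC"),
            ("ATGC", 1, 4, "L", "GCAT"),
            ("AAAAATTTTT", 9, 2, "H", "TTAA"),  # wrap: tail + head
            ("AAAAATTTTT", 9, 2, "L", "TTAA"[::-1].translate(
                str.maketrans("ACGT", "TGCA"))),
        ],
    )
    def test_sense_strand_extraction(self, seq, start, end, strand, expected):
        g = AnnotatedMitogenome(length=len(seq), seq=seq)
        f = MitoFeature("x", "noncoding", start, end, strand)
        assert feature_sequence(g, f) == expected

    def test_out_of_range_coordinates_raise(self):
        g = AnnotatedMitogenome(length=4, seq="ATGC")
        with pytest.raises(CoordinateError):
            MitoFeature("x", "tRNA", 2, 9, "H").length(g.length)

    @given(
        seq=st.text(alphabet="ACGT", min_size=6, max_size=120),
        data=st.data(),
    )
    def test_reverse_complement_involution(self, seq, data):
        """Reading a range on L equals the reverse complement of reading it
        on H, and reverse_complement is an involution."""
        start = data.draw(st.integers(1, len(seq)))
        end = data.draw(st.integers(1, len(seq)))
        g = AnnotatedMitogenome(length=len(seq), seq=seq)
        h = feature_sequence(g, MitoFeature("x", "tRNA", start, end, "H"))
        l = feature_sequence(g, MitoFeature("x", "tRNA", start, end, "L"))
        assert l == reverse_complement(h)
        assert reverse_complement(l) == h


def test_gene_name_normalisation_is_case_insensitive_and_extensible():
    assert normalize_gene_name("coi") == "COX1"
    assert normalize_gene_name("CytB") == "CYTB"
    assert normalize_gene_name("rrnS") == "12S-rRNA"
    assert normalize_gene_name("mystery-gene") == "mystery-gene"  # pass-through
    assert normalize_gene_name("foo", {"FOO": "BAR"}) == "BAR"
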