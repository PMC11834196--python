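"""Annotation parsing, coordinate mapping and 5'P end assignment."""

import numpy as np
import pandas as pd
import pytest

from ctrdseq import (
    SampleSheet,
    TranscriptModel,
    load_5p_ends,
    parse_gff,
    read_table,
    write_table,
)
from ctrdseq.annotation_io import GffParseError, SchemaError, read_profiles, write_profiles

GFF_HEADER = "##gff-version 3\n"


def write_gff(tmp_path, body, name="ann.gff3"):
    path = tmp_path / name
    path.write_text(GFF_HEADER + body)
    return path


PLUS_MRNA = """\
chr1\tsrc\tmRNA\t101\t400\t.\t+\t.\tID=T1;Parent=G1
chr1\tsrc\texon\t101\t400\t.\t+\t.\tParent=T1
chr1\tsrc\tCDS\t131\t367\t.\t+\t0\tParent=T1
chr1\tsrc\tstop_codon\t368\t370\t.\t+\t0\tParent=T1
"""

MINUS_MRNA = """\
chr1\tsrc\tmRNA\t101\t400\t.\t-\t.\tID=T2;Parent=G2
chr1\tsrc\texon\t101\t400\t.\t-\t.\tParent=T2
chr1\tsrc\tCDS\t131\t370\t.\t-\t0\tParent=T2
"""


class TestParseGff:
    def test_plus_strand_with_stop_codon_feature(self, tmp_path):
        (m,) = parse_gff(write_gff(tmp_path, PLUS_MRNA))
        assert m.strand == "+"
        assert m.length_t == 300
        assert m.cds_start_t == 30
        # stop_codon feature at genomic [367,370) -> transcript 367-100
        assert m.stop_codon_start_t == 267

    def test_minus_strand_cds_includes_stop(self, tmp_path):
        (m,) = parse_gff(write_gff(tmp_path, MINUS_MRNA))
        # transcript position 0 is genomic 399; first stop nt is genomic 132
        assert m.stop_codon_start_t == 399 - 132 == 267
        assert m.cds_start_t == 399 - 369 == 30

    def test_mrna_without_cds_skipped_with_warning(self, tmp_path):
        body = PLUS_MRNA + (
            "chr1\tsrc\tmRNA\t501\t700\t.\t+\t.\tID=T9;Parent=G9\n"
            "chr1\tsrc\texon\t501\t700\t.\t+\t.\tParent=T9\n"
        )
        with pytest.warns(UserWarning, match="no CDS"):
            models = parse_gff(write_gff(tmp_path, body))
        assert [m.transcript_id for m in models] == ["T1"]

    def test_malformed_line_names_line_number(self, tmp_path):
        path = write_gff(tmp_path, "chr1\tonly\tthree\n")
        with pytest.raises(GffParseError, match="line 2"):
            parse_gff(path)


class TestCoordinateMapping:
    def spliced_models(self):
        return [
            TranscriptModel("S1", "S1g", "chr1", "+", ((10, 40), (60, 90), (120, 135)),
                            cds_start_t=6, stop_codon_start_t=66),
            TranscriptModel("S2", "S2g", "chr1", "-", ((120, 150), (50, 95), (10, 25)),
                            cds_start_t=3, stop_codon_start_t=84),
            TranscriptModel("S3", "S3g", "chr2", "+", ((0, 7), (100, 140), (200, 260)),
                            cds_start_t=10, stop_codon_start_t=100),
            TranscriptModel("S4", "S4g", "chr2", "-", ((300, 420),),
                            cds_start_t=9, stop_codon_start_t=108),
        ]

    def brute_force_map(self, m):
        """Exhaustive genomic base -> transcript position lookup table."""
        bases = []
        for s, e in sorted(m.exons):
            bases.extend(range(s, e))
        if m.strand == "-":
            bases = bases[::-1]
        return {g: t for t, g in enumerate(bases)}

    def test_mapping_agrees_with_exhaustive_lookup(self):
        for m in self.spliced_models():
            table = self.brute_force_map(m)
            for g in range(min(table) - 2, max(table) + 3):
                assert m.to_transcript(g) == table.get(g), (m.transcript_id, g)
            for g, t in table.items():
                assert m.to_genomic(t) == g

    def test_round_trip_both_directions(self):
        for m in self.spliced_models():
            for t in range(m.length_t):
                assert m.to_transcript(m.to_genomic(t)) == t


class TestModelInvariants:
    def test_rejects_unsorted_exons(self):
        with pytest.raises(ValueError, match="5'->3'"):
            TranscriptModel("X", "X", "chr1", "+", ((60, 90), (10, 40)), 0, 30)

    def test_rejects_cds_outside_bounds(self):
        with pytest.raises(ValueError, match="out of bounds"):
            TranscriptModel("X", "X", "chr1", "+", ((0, 50),), 10, 48)

    def test_out_of_frame_flagged_not_rejected(self):
        m = TranscriptModel("X", "X", "chr1", "+", ((0, 100),), 10, 51)
        assert not m.frame_ok


def bed_line(chrom, start, end, strand, name="r"):
    return f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n"


class TestLoad5pEnds:
    def test_plus_read_increments_5p_position(self, tmp_path, plus_model):
        bed = tmp_path / "r.bed"
        bed.write_text(bed_line("chr1", 250, 300, "+"))
        profiles = load_5p_ends(bed, [plus_model], "lib")
        assert profiles["TPLUS.1"].counts[150] == 1
        assert profiles["TPLUS.1"].total == 1

    def test_minus_read_5p_end_is_rightmost_base(self, tmp_path, minus_model):
        bed = tmp_path / "r.bed"
        bed.write_text(bed_line("chr1", 250, 300, "-"))
        profiles = load_5p_ends(bed, [minus_model], "lib")
        # 5' end at genomic 299 -> transcript 399-299 = 100
        assert profiles["TMINUS.1"].counts[100] == 1

    def test_strand_mismatch_goes_to_discard_tally(self, tmp_path, minus_model):
        bed = tmp_path / "r.bed"
        bed.write_text(bed_line("chr1", 250, 300, "+"))
        profiles = load_5p_ends(bed, [minus_model], "lib")
        assert len(profiles) == 0
        assert profiles.n_discarded == 1

    def test_count_conservation(self, tmp_path, plus_model, minus_model):
        rng = np.random.default_rng(5)
        lines = []
        for _ in range(200):
            start = int(rng.integers(0, 600))
            strand = "+" if rng.random() < 0.5 else "-"
            lines.append(bed_line("chr1", start, start + 50, strand))
        bed = tmp_path / "r.bed"
        bed.write_text("".join(lines))
        profiles = load_5p_ends(bed, [plus_model, minus_model], "lib")
        assert profiles.n_assigned + profiles.n_discarded == 200
        assert sum(p.total for p in profiles.values()) == profiles.n_assigned

    def test_bam_input_matches_bed(self, tmp_path, plus_model):
        pysam = pytest.importorskip("pysam")
        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "chr1", "LN": 1000}]}
        bam = tmp_path / "r.bam"
        with pysam.AlignmentFile(bam, "wb", header=header) as fh:
            for i, (start, reverse) in enumerate([(110, False), (250, False), (250, True)]):
                a = pysam.AlignedSegment()
                a.query_name = f"read{i}"
                a.query_sequence = "A" * 50
                a.reference_id = 0
                a.reference_start = start
                a.cigarstring = "50M"
                a.flag = 16 if reverse else 0
                a.mapping_quality = 60
                fh.write(a)
        pysam.index(str(bam))
        profiles = load_5p_ends(bam, [plus_model], "lib")
        # + reads at 250 and 110 -> transcript 150 and 10; - read discarded
        assert profiles["TPLUS.1"].counts[150] == 1
        assert profiles["TPLUS.1"].counts[10] == 1
        assert profiles.n_discarded == 1

    def test_unindexed_bam_is_an_error(self, tmp_path, plus_model):
        pysam = pytest.importorskip("pysam")
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 1000}]}
        bam = tmp_path / "u.bam"
        with pysam.AlignmentFile(bam, "wb", header=header):
            pass
        with pytest.raises(ValueError, match="index"):
            load_5p_ends(bam, [plus_model], "lib")


class TestStrandSymmetry:
    def test_reverse_complemented_genome_gives_identical_profiles(self, tmp_path):
        """Flipping the genome and all strands leaves transcript profiles unchanged."""
        G = 1000  # genome length for coordinate reflection g -> G-1-g
        fwd = TranscriptModel("T", "T", "chr1", "+", ((100, 400),), 30, 267)
        rev = TranscriptModel("T", "T", "chr1", "-", ((600, 900),), 30, 267)
        rng = np.random.default_rng(7)
        starts = rng.integers(100, 380, size=100)
        fwd_bed = tmp_path / "fwd.bed"
        fwd_bed.write_text("".join(bed_line("chr1", s, s + 20, "+") for s in starts))
        # reflected reads: 5' end g maps to G-1-g, interval flips, strand flips
        rev_bed = tmp_path / "rev.bed"
        rev_bed.write_text(
            "".join(bed_line("chr1", G - 1 - (s + 19), G - s, "-") for s in starts)
        )
        p_fwd = load_5p_ends(fwd_bed, [fwd], "lib")
        p_rev = load_5p_ends(rev_bed, [rev], "lib")
        assert np.array_equal(p_fwd["T"].counts, p_rev["T"].counts)


class TestTables:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame({"transcript_id": ["A", "B"], "tsi": [1.5, 2.5]})
        path = tmp_path / "t.tsv"
        write_table(df, path)
        back = read_table(path, required=("transcript_id", "tsi"))
        pd.testing.assert_frame_equal(df, back)

    def test_empty_table_is_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["transcript_id", "tsi"])
        path = tmp_path / "t.tsv"
        write_table(df, path)
        assert path.read_text().strip() == "transcript_id\ttsi"

    def test_missing_column_raises_schema_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_table(pd.DataFrame({"transcript_id": ["A"]}), path)
        with pytest.raises(SchemaError, match="tsi"):
            read_table(path, required=("transcript_id", "tsi"))

    def test_extra_columns_preserved_with_warning(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_table(pd.DataFrame({"transcript_id": ["A"], "extra": [1]}), path)
        with pytest.warns(UserWarning, match="extra"):
            back = read_table(path, required=("transcript_id",))
        assert "extra" in back.columns

    def test_profile_tsv_round_trip(self, tmp_path, plus_model):
        from conftest import make_profile

        prof = make_profile(plus_model, positions=[0, 5, 5, 299])
        path = tmp_path / "p.tsv"
        write_profiles({"TPLUS.1": prof}, path)
        back = read_profiles(path, [plus_model], "lib1")
        assert np.array_equal(back["TPLUS.1"].counts, prof.counts)


class TestSampleSheet:
    def test_duplicate_replicate_rejected(self):
        df = pd.DataFrame(
            {"library_id": ["a", "b"], "genotype": ["Col0", "Col0"],
             "organ": ["shoot", "shoot"], "replicate": [1, 1]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            SampleSheet(df)

    def test_lookup_helpers(self):
        df = pd.DataFrame(
            {"library_id": ["a", "b", "c"], "genotype": ["Col0", "Col0", "xrn4"],
             "organ": ["shoot"] * 3, "replicate": [1, 2, 1]}
        )
        sheet = SampleSheet(df)
        assert sheet.genotypes == ["Col0", "xrn4"]
        assert sheet.libraries(genotype="Col0") == ["a", "b"]
        assert sheet.genotype_of("c") == "xrn4"
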