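"""Domain types, GTF/BED/TSV round-trips and design validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from calnc import io as cio
from calnc.types import (
    ExpressionMatrix,
    GtfParseError,
    HomologyHit,
    SampleDescriptor,
    TranscriptRecord,
    full_design,
)
from conftest import make_record


class TestTranscriptRecord:
    def test_two_exon_length(self):
        r = make_record(exons=[(1, 100), (201, 300)])
        assert r.length == 200
        assert r.n_exons == 2

    @pytest.mark.parametrize("exons,err", [
        ([(100, 1)], "inverted"),
        ([(1, 100), (50, 200)], "overlap"),
        ([], "exon"),
    ])
    def test_invalid_exons_rejected(self, exons, err):
        with pytest.raises(ValueError, match=err):
            TranscriptRecord("t", "l", "Chr1", 1, 300, "+", exons)

    def test_exons_sorted_on_construction(self):
        r = make_record(exons=[(201, 300), (1, 100)])
        assert r.exons == [(1, 100), (201, 300)]


class TestGtf:
    def test_round_trip_preserves_fields(self, tmp_path):
        recs = [
            make_record("t1", exons=[(1, 100), (201, 300)], class_code="u"),
            make_record("t2", chrom="Chr2", exons=[(50, 400)], strand="-",
                        class_code="j"),
            make_record("t3", exons=[(10, 500)], strand=".", class_code="="),
        ]
        path = tmp_path / "x.gtf"
        cio.write_gtf(recs, path)
        back = cio.read_transcripts(path)
        assert len(back) == 3
        for a, b in zip(recs, sorted(back, key=lambda r: r.transcript_id)):
            assert (a.chrom, a.start, a.end, a.strand) == (b.chrom, b.start, b.end, b.strand)
            assert a.exons == b.exons
            assert a.class_code == b.class_code

    def test_class_code_attribute_and_default(self, tmp_path):
        path = tmp_path / "x.gtf"
        path.write_text(
            'Chr1\tcl\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "a"; class_code "u";\n'
            'Chr1\tcl\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "b";\n'
        )
        recs = {r.transcript_id: r for r in cio.read_transcripts(path)}
        assert recs["a"].class_code == "u"
        assert recs["b"].class_code == "="   # absent attribute defaults to match

    def test_empty_file_gives_empty_list(self, tmp_path, caplog):
        path = tmp_path / "empty.gtf"
        path.write_text("")
        with caplog.at_level("WARNING"):
            assert cio.read_transcripts(path) == []
        assert "no transcripts" in caplog.text

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text(
            'Chr1\tcl\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "a";\n'
            "this is not a gtf line\n"
        )
        with pytest.raises(GtfParseError, match=":2"):
            cio.read_transcripts(path)

    def test_exon_without_transcript_id_errors(self, tmp_path):
        path = tmp_path / "orphan.gtf"
        path.write_text('Chr1\tcl\texon\t1\t100\t.\t+\t.\tgene_id "g";\n')
        with pytest.raises(GtfParseError, match="transcript_id"):
            cio.read_transcripts(path)

    @given(
        start=st.integers(min_value=1, max_value=10_000),
        lengths=st.lists(st.integers(min_value=1, max_value=500), min_size=1, max_size=5),
        gaps=st.lists(st.integers(min_value=1, max_value=300), min_size=4, max_size=4),
        strand=st.sampled_from("+-."),
        code=st.sampled_from("=iojux"),
    )
    def test_round_trip_property(self, tmp_path_factory, start, lengths, gaps, strand, code):
        """GTF write/read is the identity on coordinates, strand, class code."""
        exons, pos = [], start
        for ln, gap in zip(lengths, gaps + [1]):
            exons.append((pos, pos + ln - 1))
            pos += ln + gap
        rec = make_record("t", exons=exons, strand=strand, class_code=code)
        path = tmp_path_factory.mktemp("rt") / "x.gtf"
        cio.write_gtf([rec], path)
        (back,) = cio.read_transcripts(path)
        assert back.exons == rec.exons
        assert (back.start, back.end, back.strand, back.class_code) == (
            rec.start, rec.end, rec.strand, rec.class_code
        )


class TestBed:
    def test_coordinate_convention(self, tmp_path):
        """BED is 0-based half-open: GTF 1..100 becomes 0,100."""
        path = tmp_path / "x.bed"
        cio.write_bed([make_record("t1", exons=[(1, 100)], strand=".")], path)
        chrom, start, end, name, score, strand = path.read_text().split()
        assert (int(start), int(end)) == (0, 100)
        assert strand == "."

    def test_bed_starts_offset_by_one_from_gtf(self, tmp_path):
        recs = [make_record(f"t{i}", exons=[(i * 10 + 1, i * 10 + 100)]) for i in range(5)]
        gtf, bed = tmp_path / "x.gtf", tmp_path / "x.bed"
        cio.write_gtf(recs, gtf)
        cio.write_bed(recs, bed)
        gtf_starts = [r.start for r in cio.read_transcripts(gtf)]
        bed_starts = [int(line.split()[1]) for line in bed.read_text().splitlines()]
        assert [g - b for g, b in zip(gtf_starts, bed_starts)] == [1] * 5

    def test_empty_list_empty_file(self, tmp_path):
        path = tmp_path / "x.bed"
        cio.write_bed([], path)
        assert path.read_text() == ""


class TestExpression:
    def _write(self, tmp_path, columns, sheet_rows=None):
        samples = full_design(3)
        if sheet_rows is None:
            sheet_rows = [
                (s.sample_id, s.genotype, s.treatment, s.time_h, s.replicate)
                for s in samples
            ]
        pd.DataFrame(
            sheet_rows,
            columns=["sample_id", "genotype", "treatment", "time_h", "replicate"],
        ).to_csv(tmp_path / "sheet.tsv", sep="\t", index=False)
        df = pd.DataFrame(
            np.ones((3, len(columns))), index=["a", "b", "c"], columns=columns
        )
        df.to_csv(tmp_path / "fpkm.tsv", sep="\t", index_label="transcript_id")
        return tmp_path / "fpkm.tsv", tmp_path / "sheet.tsv"

    def test_full_design_reads_18_groups(self, tmp_path):
        cols = [s.sample_id for s in full_design(3)]
        mat = cio.read_expression(*self._write(tmp_path, cols))
        assert mat.values.shape == (3, 54)
        groups = mat.groups()
        assert len(groups) == 18
        assert all(len(v) == 3 for v in groups.values())

    def test_column_sheet_mismatch_names_sample(self, tmp_path):
        samples = full_design(3)
        sheet_rows = [
            (s.sample_id, s.genotype, s.treatment, s.time_h, s.replicate)
            for s in samples[:-1]
        ]
        paths = self._write(tmp_path, [s.sample_id for s in samples], sheet_rows)
        with pytest.raises(ValueError, match=samples[-1].sample_id):
            cio.read_expression(*paths)

    def test_negative_fpkm_rejected(self, tmp_path):
        mat_path, sheet_path = self._write(tmp_path, [s.sample_id for s in full_design(3)])
        df = pd.read_csv(mat_path, sep="\t", index_col=0)
        df.iloc[0, 0] = -1.0
        df.to_csv(mat_path, sep="\t", index_label="transcript_id")
        with pytest.raises(ValueError, match="negative"):
            cio.read_expression(mat_path, sheet_path)

    def test_duplicate_design_cell_rejected(self):
        s = SampleDescriptor("s1", "WT", "NaCl", 0, 1)
        s2 = SampleDescriptor("s2", "WT", "NaCl", 0, 1)
        df = pd.DataFrame(np.ones((1, 2)), index=["a"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionMatrix(df, [s, s2])


class TestTables:
    def test_homology_round_trip(self, tmp_path):
        hits = [HomologyHit("q1", "s1", 95.5, 1e-20), HomologyHit("q2", "s2", 80.0, 0.1)]
        path = tmp_path / "h.tsv"
        cio.write_homology(hits, path)
        assert cio.read_homology(path) == hits

    def test_identity_range_enforced(self):
        with pytest.raises(ValueError):
            HomologyHit("q", "s", 101.0, 1e-20)

    def test_coding_potential_round_trip(self, tmp_path, bundle):
        path = tmp_path / "cp.tsv"
        cio.write_coding_potential(bundle.profiles.values(), path)
        back = cio.read_coding_potential(path)
        assert back.keys() == bundle.profiles.keys()
        any_id = next(iter(back))
        assert back[any_id].verdicts == dict(bundle.profiles[any_id].verdicts)
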