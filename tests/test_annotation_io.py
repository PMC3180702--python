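"""Format readers/writers: BED12, GTF, bedGraph coverage, junctions, tracks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from txcomplexity import io as aio
from txcomplexity.genome import (
    GenomicInterval,
    JunctionTag,
    StrandedCoverage,
    ValidationError,
)

BED12_LINE = "chr1\t1000\t1700\ttx1|geneA\t0\t+\t1000\t1700\t0\t2\t100,200\t0,500\n"


class TestReadModels:
    def test_bed12_block_expansion(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text(BED12_LINE)
        ann = aio.read_models(p, format="bed12")
        t = ann.get("tx1")
        assert [(e.start, e.end) for e in t.exons] == [(1000, 1100), (1500, 1700)]
        assert t.gene_id == "geneA"
        assert t.span.start == 1000 and t.span.end == 1700

    def test_gtf_one_based_conversion(self, tmp_path):
        p = tmp_path / "m.gtf"
        p.write_text(
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        t = aio.read_models(p, format="gtf").get("t")
        assert (t.exons[0].start, t.exons[0].end) == (100, 200)

    def test_empty_file_empty_set(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(aio.read_models(p, format="bed12")) == 0

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text(BED12_LINE + "chr1\t10\t20\tbad\n")
        with pytest.raises(aio.ParseError, match=":2:"):
            aio.read_models(p, format="bed12")

    def test_invalid_block_structure_rejected(self, tmp_path):
        # blocks out of order violate the exon invariants
        bad = "chr1\t1000\t1700\tt|g\t0\t+\t1000\t1700\t0\t2\t100,200\t500,0\n"
        p = tmp_path / "bad.bed"
        p.write_text(bad)
        with pytest.raises(aio.ParseError):
            aio.read_models(p, format="bed12")

    def test_gtf_and_bed12_give_identical_model(self, tmp_path):
        bed = tmp_path / "m.bed"
        bed.write_text(BED12_LINE)
        gtf = tmp_path / "m.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t1001\t1100\t.\t+\t.\tgene_id "geneA"; transcript_id "tx1";\n'
            'chr1\tsrc\texon\t1501\t1700\t.\t+\t.\tgene_id "geneA"; transcript_id "tx1";\n'
            'chr1\tsrc\tCDS\t1001\t1700\t.\t+\t.\tgene_id "geneA"; transcript_id "tx1";\n'
        )
        a = aio.read_models(bed, format="bed12").get("tx1")
        b = aio.read_models(gtf, format="gtf").get("tx1")
        assert a.exons == b.exons
        assert a.span == b.span
        assert a.gene_id == b.gene_id

    def test_bed12_round_trip_identity(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text(BED12_LINE)
        ann = aio.read_models(p, format="bed12")
        q = tmp_path / "out.bed"
        aio.write_models_bed12(ann, q)
        assert aio.read_models(q, format="bed12").get("tx1").exons == ann.get("tx1").exons


class TestCoverageIO:
    def test_interval_value_expansion(self, tmp_path):
        plus = tmp_path / "p.bg"
        plus.write_text("chr1\t10\t13\t4\n")
        minus = tmp_path / "m.bg"
        minus.write_text("")
        cov = aio.read_coverage(plus, minus)
        arr = cov.counts("chr1", "+")
        assert list(arr[10:13]) == [4, 4, 4]
        assert arr[9] == 0  # no record at position 9

    def test_overlapping_records_rejected(self, tmp_path):
        plus = tmp_path / "p.bg"
        plus.write_text("chr1\t10\t20\t4\nchr1\t15\t25\t2\n")
        minus = tmp_path / "m.bg"
        minus.write_text("")
        with pytest.raises(aio.ParseError, match="overlapping"):
            aio.read_coverage(plus, minus)

    def test_negative_values_rejected(self, tmp_path):
        plus = tmp_path / "p.bg"
        plus.write_text("chr1\t10\t20\t-1\n")
        minus = tmp_path / "m.bg"
        minus.write_text("")
        with pytest.raises(aio.ParseError, match="negative"):
            aio.read_coverage(plus, minus)

    def test_write_merges_runs_and_omits_zeros(self, tmp_path):
        cov = StrandedCoverage({"chr1": 4}, 100)
        cov.add("chr1", "+", 0, np.array([0, 4, 4, 0]))
        aio.write_coverage(cov, tmp_path / "p.bg", tmp_path / "m.bg")
        assert (tmp_path / "p.bg").read_text() == "chr1\t1\t3\t4\n"
        assert (tmp_path / "m.bg").read_text() == ""

    def test_adjacent_runs_share_boundary(self, tmp_path):
        cov = StrandedCoverage({"chr1": 6}, 100)
        cov.add("chr1", "+", 0, np.array([2, 2, 5, 5, 0, 0]))
        aio.write_coverage(cov, tmp_path / "p.bg", tmp_path / "m.bg")
        assert (tmp_path / "p.bg").read_text() == "chr1\t0\t2\t2\nchr1\t2\t4\t5\n"

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=5), min_size=1, max_size=60)
    )
    def test_round_trip_preserves_every_count(self, values):
        import tempfile, os

        cov = StrandedCoverage({"chr1": len(values)}, max(1, sum(values)))
        cov.add("chr1", "+", 0, np.array(values))
        with tempfile.TemporaryDirectory() as d:
            p, m = os.path.join(d, "p.bg"), os.path.join(d, "m.bg")
            aio.write_coverage(cov, p, m)
            back = aio.read_coverage(p, m, library_total_tags=max(1, sum(values)))
            if sum(values) == 0:
                assert back.total_tags_stored() == 0
            else:
                got = back.counts("chr1", "+")
                padded = [int(got[i]) if i < len(got) else 0 for i in range(len(values))]
                assert padded == values


class TestJunctionIO:
    def test_counts_parsed(self, tmp_path):
        p = tmp_path / "j.bed"
        p.write_text("chr2\t104983310\t105003491\tskip5\t350\t+\n")
        (j,) = aio.read_junctions(p)
        assert j.tag_count == 350
        assert j.donor_end < j.acceptor_start

    def test_inverted_boundaries_rejected(self, tmp_path):
        p = tmp_path / "j.bed"
        p.write_text("chr1\t500\t400\tx\t10\t+\n")
        with pytest.raises(aio.ParseError):
            aio.read_junctions(p)

    def test_nonpositive_count_rejected(self, tmp_path):
        p = tmp_path / "j.bed"
        p.write_text("chr1\t100\t200\tx\t0\t+\n")
        with pytest.raises(aio.ParseError):
            aio.read_junctions(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "j.bed"
        p.write_text("")
        assert aio.read_junctions(p) == []

    def test_round_trip(self, tmp_path):
        js = [
            JunctionTag("chr1", "+", 100, 200, 7),
            JunctionTag("chr1", "-", 50, 400, 2),
        ]
        p = tmp_path / "j.bed"
        aio.write_junctions(js, p)
        back = aio.read_junctions(p)
        assert [(j.donor_end, j.acceptor_start, j.tag_count, j.strand) for j in back] == [
            (50, 400, 2, "-"),
            (100, 200, 7, "+"),
        ]


class TestWriteTrack:
    def test_deterministic_order_and_header(self, tmp_path):
        recs = [
            (GenomicInterval("chr1", 100, 200, "+"), "b", 2.0),
            (GenomicInterval("chr1", 100, 300, "+"), "a", 1.0),
            (GenomicInterval("chr1", 50, 80, "-"), "c", 3.0),
        ]
        out = tmp_path / "t.bed"
        aio.write_track(recs, out, track_name="calls")
        lines = out.read_text().splitlines()
        assert lines[0].startswith("track ")
        names = [l.split("\t")[3] for l in lines[1:]]
        assert names == ["c", "a", "b"]  # (chrom, start, name)

    def test_empty_call_set_header_only(self, tmp_path):
        out = tmp_path / "t.bed"
        aio.write_track([], out)
        assert out.read_text().startswith("track ")
        assert len(out.read_text().splitlines()) == 1
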