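"""I/O contracts: coordinate conversions, round trips, error behavior."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from sjkit.formats import (
    AnnotationSet,
    GenomeAccessor,
    GenomicInterval,
    IntegrityError,
    ParseError,
    SJRecord,
    SJTable,
    TranscriptModel,
    read_gtf,
    read_isoform_alignments,
    read_star_sj,
    write_bed12,
    write_gtf,
)
from conftest import tm


@st.composite
def transcript_models(draw):
    n_ex = draw(st.integers(1, 6))
    strand = draw(st.sampled_from("+-"))
    pos = draw(st.integers(0, 500))
    exons = []
    for _ in range(n_ex):
        length = draw(st.integers(1, 200))
        exons.append((pos, pos + length))
        pos += length + draw(st.integers(4, 300))
    tid = draw(st.from_regex(r"t[a-z0-9]{1,8}", fullmatch=True))
    return TranscriptModel.from_coords(tid, "g_" + tid, "chr1", strand, exons)


class TestGenomicInterval:
    def test_rejects_inverted_and_empty(self):
        with pytest.raises(IntegrityError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(IntegrityError):
            GenomicInterval("", 0, 5)

    def test_transcript_requires_positive_introns(self):
        with pytest.raises(IntegrityError):
            tm("t", [(0, 100), (100, 200)])


class TestGTF:
    def test_one_based_conversion_and_sorting(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tx\texon\t401\t500\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            "chr1\tx\tCDS\t101\t150\t.\t+\t.\t"
            'gene_id "g1"; transcript_id "t1";\n'
        )
        ann = read_gtf(str(gtf))
        (t,) = list(ann.transcripts())
        assert t.exon_coords == ((100, 200), (400, 500))

    def test_missing_transcript_id_names_line(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text('chr1\tx\texon\t1\t10\t.\t+\t.\tgene_id "g1";\n')
        with pytest.raises(ParseError, match=":1"):
            read_gtf(str(gtf))

    def test_mixed_strand_transcript_rejected(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tx\texon\t1\t10\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tx\texon\t21\t30\t.\t-\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(IntegrityError):
            read_gtf(str(gtf))

    def test_write_is_deterministic(self, tmp_path, toy_annotation):
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_gtf(toy_annotation, str(p1))
        write_gtf(toy_annotation, str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    @given(st.lists(transcript_models(), max_size=5, unique_by=lambda t: t.transcript_id))
    def test_round_trip_identity(self, txs):
        import tempfile, os

        genes = {}
        for t in txs:
            genes.setdefault(t.gene_id, []).append(t)
        ann = AnnotationSet(genes=genes)
        with tempfile.TemporaryDirectory() as tmp:
            path = os.path.join(tmp, "rt.gtf")
            write_gtf(ann, path)
            back = read_gtf(path)
        assert {
            t.transcript_id: (t.gene_id, t.strand, t.exon_coords)
            for t in ann.transcripts()
        } == {
            t.transcript_id: (t.gene_id, t.strand, t.exon_coords)
            for t in back.transcripts()
        }


class TestStarSJ:
    def test_coordinate_and_strand_conversion(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text(
            "chr1\t101\t200\t1\t1\t1\t12\t3\t40\n"
            "chr1\t301\t400\t2\t2\t0\t7\t0\t25\n"
            "chr1\t501\t600\t0\t0\t0\t4\t0\t20\n"
        )
        t = read_star_sj(str(p))
        rec = t.lookup("chr1", "+", 100, 200)
        assert rec is not None and rec.unique_reads == 12
        assert t.lookup("chr1", "-", 300, 400).unique_reads == 7
        # strand-code-0 rows answer queries from both strands
        assert t.lookup("chr1", "+", 500, 600) is not None
        assert t.lookup("chr1", "-", 500, 600) is not None

    def test_duplicate_rows_keep_max_support(self):
        t = SJTable()
        j = GenomicInterval("chr1", 100, 200, "+")
        t.add(SJRecord(j, unique_reads=3))
        t.add(SJRecord(j, unique_reads=9))
        t.add(SJRecord(j, unique_reads=5))
        assert t.lookup("chr1", "+", 100, 200).unique_reads == 9

    def test_non_integer_coordinate_raises(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text("chr1\tabc\t200\t1\t1\t1\t12\t3\t40\n")
        with pytest.raises(ParseError):
            read_star_sj(str(p))


class TestBED12:
    def test_block_arithmetic(self, tmp_path):
        p = tmp_path / "iso.bed"
        p.write_text(
            "chr1\t100\t500\tiso1\t0\t+\t100\t500\t0\t2\t100,100\t0,300\n"
        )
        (t,) = read_isoform_alignments(str(p))
        assert t.exon_coords == ((100, 200), (400, 500))
        assert t.transcript_id == "iso1"

    def test_single_block_is_mono_exon(self, tmp_path):
        p = tmp_path / "iso.bed"
        p.write_text("chr1\t10\t90\tg9|iso2\t0\t-\t10\t90\t0\t1\t80\t0\n")
        (t,) = read_isoform_alignments(str(p))
        assert t.n_exons == 1 and t.gene_id == "g9" and t.strand == "-"

    def test_undefined_strand_skipped(self, tmp_path):
        p = tmp_path / "iso.bed"
        p.write_text(
            "chr1\t0\t50\tbad\t0\t.\t0\t50\t0\t1\t50\t0\n"
            "chr1\t100\t150\tok\t0\t+\t100\t150\t0\t1\t50\t0\n"
        )
        out = read_isoform_alignments(str(p))
        assert [t.transcript_id for t in out] == ["ok"]

    def test_inconsistent_block_count_raises(self, tmp_path):
        p = tmp_path / "iso.bed"
        p.write_text("chr1\t0\t50\tx\t0\t+\t0\t50\t0\t2\t50\t0\n")
        with pytest.raises(ParseError):
            read_isoform_alignments(str(p))

    @given(st.lists(transcript_models(), max_size=5, unique_by=lambda t: t.transcript_id))
    def test_round_trip(self, txs):
        import tempfile, os

        with tempfile.TemporaryDirectory() as tmp:
            path = os.path.join(tmp, "rt.bed")
            write_bed12(txs, path)
            back = read_isoform_alignments(path)
        assert {
            (t.transcript_id, t.gene_id, t.strand, t.exon_coords) for t in txs
        } == {
            (t.transcript_id, t.gene_id, t.strand, t.exon_coords) for t in back
        }


class TestGenomeAccessor:
    def test_fetch_semantics(self):
        g = GenomeAccessor({"c1": "acgt"})
        assert g.fetch("c1", 1, 3) == "CG"
        assert g.fetch("c1", 0, 4) == "ACGT"
        with pytest.raises(LookupError):
            g.fetch("nope", 0, 1)
        with pytest.raises(ValueError):
            g.fetch("c1", 0, 5)
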