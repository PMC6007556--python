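"""FASTA/FASTQ readers and the SAM writer (round-tripped through pysam)."""

import gzip

import pysam
import pytest

from scafflink.mapper import PairPlacement, ReadScore
from scafflink.samio import format_pair, sam_header, write_sam
from scafflink.seqio import read_fasta, read_fastq, read_pairs, write_fasta, write_fastq


def test_fasta_wrapped_and_unwrapped(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">c1\nACGTACGT\nACGT\n>c2\nTTTT\n")
    recs = list(read_fasta(p))
    assert recs == [("c1", "ACGTACGTACGT"), ("c2", "TTTT")]


def test_fasta_crlf_equals_lf(tmp_path):
    lf = tmp_path / "lf.fa"
    crlf = tmp_path / "crlf.fa"
    lf.write_text(">c1\nACGT\nAC\n")
    crlf.write_bytes(b">c1\r\nACGT\r\nAC\r\n")
    assert list(read_fasta(lf)) == list(read_fasta(crlf))


def test_fasta_gzip_transparent(tmp_path):
    p = tmp_path / "a.fa.gz"
    with gzip.open(p, "wt") as fh:
        fh.write(">c1\nACGT\n")
    assert list(read_fasta(p)) == [("c1", "ACGT")]


def test_empty_file_yields_empty_stream(tmp_path):
    p = tmp_path / "empty.fa"
    p.write_text("")
    assert list(read_fasta(p)) == []


def test_fastq_roundtrip(tmp_path):
    p = tmp_path / "r.fq"
    write_fastq(p, [("r1", "ACGT", "IIII"), ("r2", "TTAA", "!!II")])
    assert list(read_fastq(p)) == [("r1", "ACGT", "IIII"), ("r2", "TTAA", "!!II")]


def test_malformed_fastq_is_an_error(tmp_path):
    p = tmp_path / "bad.fq"
    p.write_text("@r1\nACGT\n+\nII\n")  # quality length mismatch
    with pytest.raises(ValueError, match="malformed"):
        list(read_fastq(p))


def test_read_pairs_two_files_and_interleaved(tmp_path):
    f1, f2, inter = tmp_path / "1.fa", tmp_path / "2.fa", tmp_path / "i.fa"
    write_fasta(f1, [("p1/1", "AAAA"), ("p2/1", "CCCC")])
    write_fasta(f2, [("p1/2", "GGGG"), ("p2/2", "TTTT")])
    write_fasta(inter, [("p1/1", "AAAA"), ("p1/2", "GGGG"), ("p2/1", "CCCC"), ("p2/2", "TTTT")])
    assert list(read_pairs(f1, f2)) == list(read_pairs(inter)) == [("AAAA", "GGGG"), ("CCCC", "TTTT")]


def _placement(f_start=100, r_start=3000, contig_f=0, contig_r=0, L=100, rescued=False):
    f = ReadScore(score=10, contig_id=contig_f, start=f_start, strand="+", read_length=L)
    r = ReadScore(score=10, contig_id=contig_r, start=r_start, strand="-", read_length=L)
    same = contig_f == contig_r
    insert = (r_start + L - f_start) if same else None
    return PairPlacement(
        forward=f, reverse=r,
        rescued=rescued, rescued_read="reverse" if rescued else None,
        observed_insert=insert, orientation="FR" if same else None,
    )


def test_sam_coordinates_and_tlen(tmp_path):
    """0-based 100/3000 becomes POS 101/3001 with outer-distance TLEN."""
    path = tmp_path / "out.sam"
    write_sam(path, [("p1", _placement(), "A" * 100, None, "C" * 100, None)], ["c1"], [10_000])
    with pysam.AlignmentFile(str(path), "r") as sam:
        recs = list(sam.fetch(until_eof=True))
    a, b = recs
    assert (a.reference_start, b.reference_start) == (100, 3000)
    assert a.pos + 1 == 101 and b.pos + 1 == 3001
    assert a.template_length == 3000 and b.template_length == -3000
    assert a.is_read1 and b.is_read2
    assert not a.is_reverse and b.is_reverse
    assert a.mate_is_reverse and not b.mate_is_reverse
    assert a.cigarstring == "100M"
    assert a.mapping_quality == 60


def test_sam_rescued_record_tagged(tmp_path):
    path = tmp_path / "out.sam"
    write_sam(path, [("p1", _placement(rescued=True), "A" * 100, None, "C" * 100, None)], ["c1"], [10_000])
    with pysam.AlignmentFile(str(path), "r") as sam:
        a, b = list(sam.fetch(until_eof=True))
    assert not a.has_tag("XR")
    assert b.has_tag("XR") and b.get_tag("XR") == 1
    assert b.mapping_quality == 30 and a.mapping_quality == 60


def test_sam_cross_contig_pair(tmp_path):
    path = tmp_path / "out.sam"
    pl = _placement(f_start=9900, r_start=50, contig_f=0, contig_r=1)
    write_sam(path, [("p1", pl, "A" * 100, None, "C" * 100, None)], ["c1", "c2"], [10_000, 10_000])
    with pysam.AlignmentFile(str(path), "r") as sam:
        a, b = list(sam.fetch(until_eof=True))
    assert a.reference_name == "c1" and a.next_reference_name == "c2"
    assert a.template_length == 0
    assert not a.is_proper_pair


def test_sam_header_only_when_no_placements(tmp_path):
    path = tmp_path / "out.sam"
    n = write_sam(path, [], ["c1"], [500])
    assert n == 0
    with pysam.AlignmentFile(str(path), "r") as sam:
        assert sam.references == ("c1",)
        assert list(sam.fetch(until_eof=True)) == []


def test_sam_contig_name_collision_is_an_error():
    with pytest.raises(ValueError, match="collision"):
        sam_header(["c1", "c1"], [10, 10])


def test_sam_positions_within_reference_bounds(tmp_path, small_genome, small_index):
    """Every emitted coordinate is 1-based and within the @SQ length."""
    from scafflink import map_pair
    from scafflink.kmers import revcomp

    placements = []
    for s in range(0, 40_000, 4000):
        qf = small_genome[s : s + 100]
        qr = revcomp(small_genome[s + 2900 : s + 3000])
        p = map_pair(qf, qr, small_index)
        placements.append((f"p{s}", p, qf, None, qr, None))
    path = tmp_path / "out.sam"
    write_sam(path, placements, small_index.contig_names, small_index.contig_lengths)
    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam.fetch(until_eof=True):
            assert 1 <= rec.pos + 1 <= 50_000
            assert rec.reference_start + rec.query_length <= 50_000
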