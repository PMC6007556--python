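"""Window scoring and pair placement, checked against a naive oracle."""

import numpy as np
import pytest

from scafflink import MapperParams, collect_hits, map_pair, rescue_pair, score_read, revcomp
from scafflink.libparams import LibraryParams
from scafflink.mapper import Hit, _inferred_start
from scafflink.simdata import simulate_genome


def naive_best_window(hits, read_length, k):
    """O(H^2) scan: for every anchor hit, count same-location hits whose
    inferred starts fall in [start, start + read_length)."""
    best = 0
    for a in hits:
        sa = _inferred_start(a, read_length, k)
        count = sum(
            1
            for b in hits
            if b.contig_id == a.contig_id
            and b.strand == a.strand
            and sa <= _inferred_start(b, read_length, k) < sa + read_length
        )
        best = max(best, count)
    return best


def random_hits(rng, n, n_contigs=3, span=500):
    return [
        Hit(
            contig_id=int(rng.integers(0, n_contigs)),
            coordinate=int(rng.integers(0, span)),
            strand=rng.choice(["+", "-"]),
            read_offset=int(rng.integers(0, 80)),
        )
        for _ in range(n)
    ]


@pytest.mark.parametrize("seed", range(8))
def test_window_score_matches_naive_scan(seed):
    rng = np.random.default_rng(seed)
    for _ in range(100):
        hits = random_hits(rng, int(rng.integers(0, 15)))
        rs = score_read(hits, read_length=100, k=21)
        assert rs.score == naive_best_window(hits, 100, 21)


def test_empty_hits_score_zero():
    rs = score_read([], 100, 21)
    assert rs.score == 0 and rs.contig_id is None


def test_consistent_hits_score_full():
    hits = [Hit(0, 100 + i, "+", i) for i in range(10)]
    rs = score_read(hits, 100, 21)
    assert rs.score == 10 and not rs.ambiguous
    assert rs.contig_id == 0 and rs.start == 100 and rs.strand == "+"


def test_tie_on_two_contigs_is_ambiguous():
    hits = [Hit(0, 100 + i, "+", i) for i in range(5)] + [
        Hit(1, 300 + i, "+", i) for i in range(5)
    ]
    rs = score_read(hits, 100, 21)
    assert rs.score == 5 and rs.ambiguous and rs.effective_score == 0


def test_overlapping_window_ties_are_not_ambiguous():
    """Hits spread across overlapping windows at one location stay unique."""
    hits = [Hit(0, 100, "+", 0), Hit(0, 160, "+", 10)]
    rs = score_read(hits, 100, 21)
    assert not rs.ambiguous


def test_collect_hits_from_unique_region(small_genome, small_index):
    read = small_genome[5000:5100]
    hits = collect_hits(read, small_index, capacity=10)
    assert len(hits) == 10
    assert all(h.contig_id == 0 and h.strand == "+" for h in hits)
    assert [h.coordinate for h in hits] == list(range(5000, 5010))


def test_collect_hits_all_n_read(small_index):
    assert collect_hits("N" * 100, small_index, 10) == []


def test_collect_hits_respects_capacity(small_genome, small_index):
    assert len(collect_hits(small_genome[200:400], small_index, capacity=7)) == 7


def test_reads_from_exact_repeat_are_never_placed(repeat_genome):
    """A read wholly inside a planted repeat has no unique k-mers."""
    from scafflink import IndexSpec, build_index

    genome, repeats = repeat_genome
    idx = build_index([("g", genome)], IndexSpec(k=21))
    s, e = repeats[0]
    read = genome[s + 100 : s + 200]
    assert collect_hits(read, idx, 10) == []
    mate = genome[s + 2000 : s + 2100]
    assert map_pair(read, mate, idx) is None


def test_perfect_pair_reports_true_location(small_genome, small_index):
    start, insert, L = 10_000, 3000, 100
    qf = small_genome[start : start + L]
    qr = revcomp(small_genome[start + insert - L : start + insert])
    p = map_pair(qf, qr, small_index)
    assert p is not None and not p.rescued
    assert p.forward.start == start and p.forward.strand == "+"
    assert p.reverse.start == start + insert - L and p.reverse.strand == "-"
    assert p.orientation == "FR" and p.observed_insert == insert


def test_strand_symmetry(small_genome, small_index):
    """Mapping the reverse-complemented pair mirrors the placement."""
    start, insert, L = 22_000, 2500, 100
    qf = small_genome[start : start + L]
    qr = revcomp(small_genome[start + insert - L : start + insert])
    p = map_pair(qf, qr, small_index)
    q = map_pair(revcomp(qr), revcomp(qf), small_index)
    assert q is not None
    # the mirrored pair swaps positions and flips strands; the positional
    # orientation label flips with it
    assert q.observed_insert == insert and q.orientation == "RF"
    assert q.forward.start == p.reverse.start and q.reverse.start == p.forward.start
    assert q.forward.strand == "+" and q.reverse.strand == "-"


def test_report_threshold_monotonicity(small_genome, small_index, rng):
    """Raising the report threshold never places more pairs."""
    pairs = []
    for _ in range(50):
        s = int(rng.integers(0, len(small_genome) - 3000))
        pairs.append(
            (small_genome[s : s + 100], revcomp(small_genome[s + 2900 : s + 3000]))
        )
    counts = []
    for threshold in (3, 5, 7, 9):
        params = MapperParams(min_report_score=threshold)
        counts.append(sum(map_pair(qf, qr, small_index, params) is not None for qf, qr in pairs))
    assert counts == sorted(counts, reverse=True)


def _rescue_setup(small_genome, small_index):
    """A pair whose mate has only 4 k-mers: below report, rescuable."""
    start, insert, L = 30_000, 3000, 100
    qf = small_genome[start : start + L]
    mate_len = 21 + 3  # exactly 4 k-mers
    qr = revcomp(small_genome[start + insert - mate_len : start + insert])
    lib = LibraryParams(mean_insert=3000, sd_insert=300, orientation="FR")
    return qf, qr, lib, start, insert


def test_rescue_places_short_scoring_mate(small_genome, small_index):
    qf, qr, lib, start, insert = _rescue_setup(small_genome, small_index)
    p = map_pair(qf, qr, small_index, MapperParams(lib=lib))
    assert p is not None and p.rescued and p.rescued_read == "reverse"
    assert p.observed_insert == insert and p.orientation == "FR"


def test_no_rescue_without_library(small_genome, small_index):
    qf, qr, lib, *_ = _rescue_setup(small_genome, small_index)
    assert map_pair(qf, qr, small_index, MapperParams(lib=None)) is None


def test_rescue_rejects_wrong_distance(small_genome, small_index):
    qf, qr, lib, start, insert = _rescue_setup(small_genome, small_index)
    far_lib = LibraryParams(mean_insert=9000, sd_insert=100, orientation="FR")
    assert map_pair(qf, qr, small_index, MapperParams(lib=far_lib)) is None


def test_rescue_rejects_wrong_orientation(small_genome, small_index):
    qf, _, lib, start, insert = _rescue_setup(small_genome, small_index)
    mate_len = 24
    flipped = small_genome[start + insert - mate_len : start + insert]  # not revcomped: FF
    assert map_pair(qf, flipped, small_index, MapperParams(lib=lib)) is None


def test_rescue_score_threshold(small_genome, small_index):
    """A mate with fewer hits than the rescue minimum stays unplaced."""
    qf, _, lib, start, insert = _rescue_setup(small_genome, small_index)
    mate_len = 21 + 2  # 3 k-mers < rescue minimum of 4
    qr = revcomp(small_genome[start + insert - mate_len : start + insert])
    assert map_pair(qf, qr, small_index, MapperParams(lib=lib)) is None
    rescued = rescue_pair(
        map_pair(qf, revcomp(small_genome[start + insert - 100 : start + insert]), small_index).forward,
        qr,
        small_index,
        MapperParams(lib=lib),
    )
    assert rescued is None


def test_forward_gate_blocks_pair(small_genome, small_index):
    """A forward read at or below the gate aborts before the mate."""
    start = 15_000
    qf = small_genome[start : start + 23]  # 3 k-mers: not > 3
    qr = revcomp(small_genome[start + 2900 : start + 3000])
    assert map_pair(qf, qr, small_index) is None
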