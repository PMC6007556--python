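"""Alignment-free placement of read pairs on contigs.

A read is located by looking up its k-mers in the unique-k-mer index
(both strands, via canonical hashing), collecting up to a fixed number
of hits, and scoring each candidate location as the maximum number of
hits whose inferred read starts fall inside a window as wide as the
read. A pair is reported when both reads clear a score threshold at an
unambiguous location; otherwise the better-placed read is fixed and the
mate is rescued by restricting its hits to the insert-size and
orientation expected from the library.

A read tied for the maximum score at two distinct genomic locations is
ambiguous and treated as score 0 — only confidently unique placements
feed the scaffolding graph.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, TYPE_CHECKING

from .index import UniqueKmerIndex
from .kmers import canonical_hashes

if TYPE_CHECKING:  # pragma: no cover
    from .libparams import LibraryParams

ORIENTATIONS = ("FR", "RF", "FF", "RR")


@dataclass(frozen=True)
class MapperParams:
    """Thresholds of the placement algorithm.

    Score thresholds ``min_fwd_score`` and ``min_report_score`` are strict
    ("larger than"); ``min_rescue_score`` is inclusive (a minimum). The
    short-read defaults are capacity 10, gate 3, report 5, rescue 4; long
    synthetic reads use capacity 20 and report 15.
    """

    hit_capacity: int = 10
    min_fwd_score: int = 3
    min_report_score: int = 5
    min_rescue_score: int = 4
    lib: Optional["LibraryParams"] = None
    rescue_sd_window: float = 3.0

    def __post_init__(self) -> None:
        if self.hit_capacity < 1:
            raise ValueError("hit_capacity must be >= 1")
        for name in ("min_fwd_score", "min_report_score", "min_rescue_score"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class Hit:
    """One unique-k-mer match between a read and a contig.

    ``strand`` is '+' when the read's k-mer (as written) matches the
    contig forward strand, '-' otherwise; ``read_offset`` is the k-mer
    start within the read.
    """

    contig_id: int
    coordinate: int
    strand: str
    read_offset: int


@dataclass(frozen=True)
class ReadScore:
    """Best-window score of one read and its winning location."""

    score: int
    contig_id: int | None = None
    start: int | None = None  # leftmost inferred read start, clamped
    strand: str | None = None
    ambiguous: bool = False
    rep_hit: Hit | None = None
    read_length: int = 0

    @property
    def effective_score(self) -> int:
        """Score used for gating: ambiguity collapses it to 0."""
        return 0 if self.ambiguous else self.score

    @property
    def end(self) -> int:
        return self.start + self.read_length


@dataclass(frozen=True)
class PairPlacement:
    """A mated placement of two reads, ready for SAM emission."""

    forward: ReadScore
    reverse: ReadScore
    rescued: bool = False
    rescued_read: str | None = None  # 'forward' or 'reverse' when rescued
    observed_insert: int | None = None
    orientation: str | None = None

    @property
    def same_contig(self) -> bool:
        return self.forward.contig_id == self.reverse.contig_id


def collect_hits(read: str, index: UniqueKmerIndex, capacity: int) -> list[Hit]:
    """Look up the read's k-mers left to right, keeping the first
    ``capacity`` index hits (fingerprint-verified)."""
    k = index.k
    if len(read) < k:
        return []
    offsets, hashes, fwd_canon = canonical_hashes(read, k)
    if hashes.size == 0:
        return []
    found, cids, coords, strands = index.lookup_hashes(hashes)
    hits: list[Hit] = []
    for i in range(hashes.size):
        if not found[i]:
            continue
        # read k-mer matches contig forward iff both, or neither, of the
        # query and the stored occurrence are in canonical orientation
        forward_match = bool(fwd_canon[i]) == (int(strands[i]) == 0)
        hits.append(
            Hit(
                contig_id=int(cids[i]),
                coordinate=int(coords[i]),
                strand="+" if forward_match else "-",
                read_offset=int(offsets[i]),
            )
        )
        if len(hits) >= capacity:
            break
    return hits


def _inferred_start(hit: Hit, read_length: int, k: int) -> int:
    """Contig position where the read would start, given this hit."""
    if hit.strand == "+":
        return hit.coordinate - hit.read_offset
    return hit.coordinate + hit.read_offset + k - read_length


def score_read(hits: Sequence[Hit], read_length: int, k: int) -> ReadScore:
    """Maximum number of hits inside any window of width ``read_length``.

    Hits are grouped by (contig, strand) and sorted by inferred read
    start; a window anchored at each hit counts the hits starting within
    ``read_length`` bases of it. If the maximum is attained at two
    distinct genomic locations (different contig/strand, or windows that
    do not overlap), the read is ambiguous. Ties between overlapping
    windows at one location are not ambiguity.
    """
    if not hits:
        return ReadScore(score=0)
    keyed = sorted(
        ((h.contig_id, h.strand, _inferred_start(h, read_length, k), h) for h in hits),
        key=lambda t: (t[0], t[1], t[2], t[3].read_offset),
    )
    best = 0
    # windows achieving the running maximum: (contig, strand, win_start, hits)
    best_windows: list[tuple[int, str, int, list[Hit]]] = []
    i = 0
    n = len(keyed)
    while i < n:
        cid, strand, start, _ = keyed[i]
        j = i
        while j < n and keyed[j][0] == cid and keyed[j][1] == strand and keyed[j][2] < start + read_length:
            j += 1
        count = j - i
        if count > best:
            best = count
            best_windows = [(cid, strand, start, [t[3] for t in keyed[i:j]])]
        elif count == best:
            best_windows.append((cid, strand, start, [t[3] for t in keyed[i:j]]))
        i += 1
    # cluster best windows into genomic locations: same contig+strand and
    # overlapping window intervals collapse into one location
    clusters: list[tuple[int, str, int, int, list[Hit]]] = []  # cid, strand, lo, hi, hits
    for cid, strand, start, whits in best_windows:
        merged = False
        for idx, (ccid, cstrand, lo, hi, chits) in enumerate(clusters):
            if ccid == cid and cstrand == strand and start < hi and start + read_length > lo:
                clusters[idx] = (ccid, cstrand, min(lo, start), max(hi, start + read_length), chits + whits)
                merged = True
                break
        if not merged:
            clusters.append((cid, strand, start, start + read_length, whits))
    ambiguous = len(clusters) > 1
    cid, strand, lo, _, chits = clusters[0]
    rep = min(chits, key=lambda h: h.read_offset)
    start = max(_inferred_start(rep, read_length, k), 0)
    return ReadScore(
        score=best,
        contig_id=cid,
        start=start,
        strand=strand,
        ambiguous=ambiguous,
        rep_hit=rep,
        read_length=read_length,
    )


def _clamp_score(rs: ReadScore, contig_lengths) -> ReadScore:
    """Clamp the inferred start so the read lies within its contig."""
    if rs.contig_id is None:
        return rs
    limit = int(contig_lengths[rs.contig_id]) - rs.read_length
    start = min(max(rs.start, 0), max(limit, 0))
    return replace(rs, start=start)


def pair_geometry(
    r1: ReadScore, r2: ReadScore
) -> tuple[Optional[str], Optional[int]]:
    """Orientation label and outer insert of a same-contig pair.

    Orientation is FR when the forward-strand read starts at or left of
    the reverse-strand read, RF when it starts to the right; FF/RR when
    both reads share a strand. The insert is the outer distance, leftmost
    read start to rightmost read end.
    """
    if r1.contig_id != r2.contig_id:
        return None, None
    insert = max(r1.end, r2.end) - min(r1.start, r2.start)
    if r1.strand == r2.strand:
        orientation = "FF" if r1.strand == "+" else "RR"
    else:
        fwd, rev = (r1, r2) if r1.strand == "+" else (r2, r1)
        orientation = "FR" if fwd.start <= rev.start else "RF"
    return orientation, insert


def rescue_pair(
    fixed: ReadScore,
    mate: str,
    index: UniqueKmerIndex,
    params: MapperParams,
) -> ReadScore | None:
    """Place a low-scoring mate by fixing its well-placed partner.

    The mate's hits are restricted to those implying a same-contig pair
    within ``mean +- rescue_sd_window * sd`` of the library insert and in
    the library orientation; the surviving hits are window-scored and the
    placement is returned iff it reaches ``min_rescue_score``.
    """
    lib = params.lib
    if lib is None:
        return None
    hits = collect_hits(mate, index, params.hit_capacity)
    if not hits:
        return None
    k = index.k
    lo = lib.mean_insert - params.rescue_sd_window * lib.sd_insert
    hi = lib.mean_insert + params.rescue_sd_window * lib.sd_insert
    accepted: list[Hit] = []
    for h in hits:
        if h.contig_id != fixed.contig_id:
            continue
        candidate = ReadScore(
            score=1,
            contig_id=h.contig_id,
            start=max(_inferred_start(h, len(mate), k), 0),
            strand=h.strand,
            rep_hit=h,
            read_length=len(mate),
        )
        orientation, insert = pair_geometry(fixed, candidate)
        if orientation == lib.orientation and lo <= insert <= hi:
            accepted.append(h)
    if not accepted:
        return None
    rs = score_read(accepted, len(mate), k)
    if rs.ambiguous or rs.score < params.min_rescue_score:
        return None
    return _clamp_score(rs, index.contig_lengths)


def map_pair(
    qf: str,
    qr: str,
    index: UniqueKmerIndex,
    params: MapperParams | None = None,
) -> PairPlacement | None:
    """Place one read pair; None when the pair cannot be confidently placed.

    The forward read gates the pair: unless its score is larger than
    ``min_fwd_score`` the mate is never examined. Both reads above
    ``min_report_score`` at unambiguous locations report directly;
    otherwise rescue is attempted from the better-scored read.
    """
    if params is None:
        params = MapperParams()
    if not qf or not qr:
        return None
    k = index.k
    f_hits = collect_hits(qf, index, params.hit_capacity)
    f_score = score_read(f_hits, len(qf), k)
    if f_score.effective_score <= params.min_fwd_score:
        return None
    r_hits = collect_hits(qr, index, params.hit_capacity)
    r_score = score_read(r_hits, len(qr), k)
    if (
        f_score.effective_score > params.min_report_score
        and r_score.effective_score > params.min_report_score
    ):
        fsc = _clamp_score(f_score, index.contig_lengths)
        rsc = _clamp_score(r_score, index.contig_lengths)
        orientation, insert = pair_geometry(fsc, rsc)
        return PairPlacement(
            forward=fsc,
            reverse=rsc,
            rescued=False,
            observed_insert=insert,
            orientation=orientation,
        )
    # rescue from the better-scored read (tie -> forward)
    if params.lib is None:
        return None
    if f_score.effective_score >= r_score.effective_score:
        anchor, mate_seq, rescued_name = f_score, qr, "reverse"
    else:
        anchor, mate_seq, rescued_name = r_score, qf, "forward"
    if anchor.effective_score <= params.min_report_score:
        return None
    anchor = _clamp_score(anchor, index.contig_lengths)
    rescued = rescue_pair(anchor, mate_seq, index, params)
    if rescued is None:
        return None
    fsc, rsc = (anchor, rescued) if rescued_name == "reverse" else (rescued, anchor)
    orientation, insert = pair_geometry(fsc, rsc)
    return PairPlacement(
        forward=fsc,
        reverse=rsc,
        rescued=True,
        rescued_read=rescued_name,
        observed_insert=insert,
        orientation=orientation,
    )
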