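"""SAM emission for placed read pairs.

One record per placed read, positioned at the leftmost inferred read
start of its winning window (derived from a single representative unique
k-mer). No base-level alignment is computed, so the CIGAR is a
full-length match placeholder and MAPQ encodes only how the read was
placed: 60 for a score-reported read, 30 for a rescued one (tagged
XR:i:1). Unplaced pairs are not emitted — downstream scaffolders consume
mapped pairs only.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from pathlib import Path

from .mapper import PairPlacement, ReadScore

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80

MAPQ_REPORTED = 60
MAPQ_RESCUED = 30
RESCUE_TAG = "XR:i:1"


def sam_header(
    contig_names: Sequence[str], contig_lengths: Sequence[int], command: str | None = None
) -> str:
    if len(set(contig_names)) != len(contig_names):
        raise ValueError("contig name collision in header")
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for name, length in zip(contig_names, contig_lengths):
        lines.append(f"@SQ\tSN:{name}\tLN:{int(length)}")
    pg = "@PG\tID:scafflink\tPN:scafflink"
    if command:
        pg += f"\tCL:{command}"
    lines.append(pg)
    return "\n".join(lines) + "\n"


def _record(
    qname: str,
    this: ReadScore,
    mate: ReadScore,
    first: bool,
    seq: str,
    qual: str | None,
    contig_names: Sequence[str],
    same_contig: bool,
    tlen: int,
    rescued: bool,
) -> str:
    flag = FLAG_PAIRED | (FLAG_FIRST if first else FLAG_SECOND)
    if same_contig:
        flag |= FLAG_PROPER
    if this.strand == "-":
        flag |= FLAG_REVERSE
    if mate.strand == "-":
        flag |= FLAG_MATE_REVERSE
    rname = contig_names[this.contig_id]
    rnext = "=" if same_contig else contig_names[mate.contig_id]
    fields = [
        qname,
        str(flag),
        rname,
        str(this.start + 1),  # SAM is 1-based
        str(MAPQ_RESCUED if rescued else MAPQ_REPORTED),
        f"{this.read_length}M",
        rnext,
        str(mate.start + 1),
        str(tlen),
        seq if seq else "*",
        qual if qual else "*",
    ]
    if rescued:
        fields.append(RESCUE_TAG)
    return "\t".join(fields)


def format_pair(
    qname: str,
    placement: PairPlacement,
    contig_names: Sequence[str],
    seq1: str = "",
    qual1: str | None = None,
    seq2: str = "",
    qual2: str | None = None,
) -> tuple[str, str]:
    """Render the two SAM records of one placed pair.

    TLEN carries the signed outer insert on same-contig pairs (positive
    on the leftmost mate, ties going to the first read); cross-contig
    pairs get TLEN 0.
    """
    f, r = placement.forward, placement.reverse
    same = placement.same_contig
    if same:
        insert = placement.observed_insert
        if r.start < f.start:
            tlen_f, tlen_r = -insert, insert
        else:  # tie: the first-in-pair read takes the positive sign
            tlen_f, tlen_r = insert, -insert
    else:
        tlen_f = tlen_r = 0
    rec1 = _record(
        qname, f, r, True, seq1, qual1, contig_names, same, tlen_f,
        rescued=placement.rescued and placement.rescued_read == "forward",
    )
    rec2 = _record(
        qname, r, f, False, seq2, qual2, contig_names, same, tlen_r,
        rescued=placement.rescued and placement.rescued_read == "reverse",
    )
    return rec1, rec2


def write_sam(
    path: str | Path,
    placements: Iterable[tuple[str, PairPlacement, str, str | None, str, str | None]],
    contig_names: Sequence[str],
    contig_lengths: Sequence[int],
    command: str | None = None,
) -> int:
    """Write a SAM file from (qname, placement, seq1, qual1, seq2, qual2)
    tuples; returns the number of pairs written."""
    n = 0
    with open(path, "w") as out:
        out.write(sam_header(contig_names, contig_lengths, command))
        for qname, placement, seq1, qual1, seq2, qual2 in placements:
            rec1, rec2 = format_pair(qname, placement, contig_names, seq1, qual1, seq2, qual2)
            out.write(rec1 + "\n")
            out.write(rec2 + "\n")
            n += 1
    return n
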