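"""Scaffolding-graph construction and scaffold-join evaluation.

Contigs are nodes; a read pair whose two reads place uniquely on
different contigs contributes to an edge between them. Each edge carries
the number of supporting pairs (weight), the relative orientation of the
two contigs, and a gap estimate: the library insert minus the distance
each read sits from its contig end, averaged over supporting pairs.
Edges below a minimum weight are dropped as likely chimeric.

Scaffold joins (adjacent oriented contigs in a proposed layout) are
scored against a known true layout with bit-wise error flags:

    0  correct pair of contigs
    1  same reference, wrong orientation
    2  contigs from different references
    4  same reference, wrong distance apart
    5  = 4+1  wrong orientation and distance
    8  same reference, wrong order
    12 = 8+4  wrong order and distance

and summarized as Recall = TP/P, Precision = TP/(TP+FP) and their
harmonic mean (F-score), with P the number of truly adjacent contig
pairs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from collections.abc import Iterable, Sequence
from pathlib import Path

import pandas as pd

from .libparams import LibraryParams
from .mapper import PairPlacement

DEFAULT_MIN_WEIGHT = 3
DEFAULT_GAP_TOLERANCE = 1000


@dataclass(frozen=True)
class ScaffoldEdge:
    """Weighted, oriented, distanced link between two contigs.

    ``end_u``/``end_v`` name which end of each contig faces the junction
    ('R' = right/3' end of the forward strand, 'L' = left/5' end);
    ``relative_orientation`` is 'same' when a scaffold walking u then v
    keeps both forward (ends R-L or L-R) and 'opposite' otherwise.
    """

    contig_u: str
    contig_v: str
    end_u: str
    end_v: str
    relative_orientation: str
    weight: int
    distance_estimate: float


@dataclass(frozen=True)
class JoinEvaluation:
    """Per-join error flags and the derived recall/precision/F-score."""

    flags: tuple[int, ...]
    P: int
    TP: int
    FP: int
    recall: float
    precision: float
    f_score: float


@dataclass(frozen=True)
class TruthEntry:
    reference: str
    start: int
    end: int
    strand: str


def build_graph(
    placements: Iterable[PairPlacement],
    lib: LibraryParams,
    contig_names: Sequence[str],
    contig_lengths: Sequence[int],
    min_weight: int = DEFAULT_MIN_WEIGHT,
) -> list[ScaffoldEdge]:
    """Aggregate cross-contig placements into scaffold edges.

    Only pairs whose reads sit on two different contigs contribute. The
    per-pair gap estimate is ``lib.mean_insert`` minus the two read-to-
    contig-end distances; edges supported by fewer than ``min_weight``
    pairs are dropped.
    """
    acc: dict[tuple[int, str, int, str], list[float]] = defaultdict(list)
    for p in placements:
        if p.same_contig:
            continue
        sides = []
        for score in (p.forward, p.reverse):
            if score.strand == "+":
                end = "R"
                span = int(contig_lengths[score.contig_id]) - score.start
            else:
                end = "L"
                span = score.end
            sides.append((score.contig_id, end, span))
        (u, eu, su), (v, ev, sv) = sides
        if u > v:
            (u, eu, su), (v, ev, sv) = (v, ev, sv), (u, eu, su)
        acc[(u, eu, v, ev)].append(lib.mean_insert - su - sv)
    edges = []
    for (u, eu, v, ev), gaps in sorted(acc.items()):
        if len(gaps) < min_weight:
            continue
        edges.append(
            ScaffoldEdge(
                contig_u=contig_names[u],
                contig_v=contig_names[v],
                end_u=eu,
                end_v=ev,
                relative_orientation="same" if eu != ev else "opposite",
                weight=len(gaps),
                distance_estimate=float(sum(gaps) / len(gaps)),
            )
        )
    return edges


def edges_to_tsv(edges: Iterable[ScaffoldEdge], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "contig_u": e.contig_u,
                "contig_v": e.contig_v,
                "end_u": e.end_u,
                "end_v": e.end_v,
                "orientation": e.relative_orientation,
                "weight": e.weight,
                "distance": round(e.distance_estimate, 2),
            }
            for e in edges
        ],
        columns=["contig_u", "contig_v", "end_u", "end_v", "orientation", "weight", "distance"],
    )
    df.to_csv(path, sep="\t", index=False)


# -- truth layouts and join classification ------------------------------


def read_truth_layout(path: str | Path) -> dict[str, TruthEntry]:
    """Read a tab-separated true layout: reference, contig, start, end, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"reference": str, "contig": str, "strand": str})
    required = {"reference", "contig", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"truth layout must have columns {sorted(required)}")
    return {
        row.contig: TruthEntry(row.reference, int(row.start), int(row.end), row.strand)
        for row in df.itertuples()
    }


def potential_joins(truth: dict[str, TruthEntry]) -> int:
    """Number of truly adjacent contig pairs: per reference, contigs
    ordered by start, n-1 joins each."""
    by_ref: dict[str, int] = defaultdict(int)
    for entry in truth.values():
        by_ref[entry.reference] += 1
    return sum(max(n - 1, 0) for n in by_ref.values())


def classify_join(
    a: tuple[str, str],
    b: tuple[str, str],
    gap: float,
    truth: dict[str, TruthEntry],
    gap_tolerance: float = DEFAULT_GAP_TOLERANCE,
) -> int:
    """Error flag of one scaffold join between oriented contigs a and b."""
    (name_a, o_a), (name_b, o_b) = a, b
    for name in (name_a, name_b):
        if name not in truth:
            raise KeyError(f"contig {name!r} not present in the truth layout")
    ta, tb = truth[name_a], truth[name_b]
    if ta.reference != tb.reference:
        return 2
    # direction the scaffold walks the reference through each contig:
    # +1 when the scaffold orientation matches the truth strand
    dir_a = 1 if o_a == ta.strand else -1
    dir_b = 1 if o_b == tb.strand else -1
    order_ok = (tb.start > ta.start) if dir_a == 1 else (tb.start < ta.start)
    true_gap = (tb.start - ta.end) if dir_a == 1 else (ta.start - tb.end)
    distance_ok = abs(gap - true_gap) <= gap_tolerance
    if not order_ok:
        return 8 if distance_ok else 12
    if dir_a != dir_b:
        return 1 if distance_ok else 5
    return 0 if distance_ok else 4


def classify_joins(
    scaffolds: Iterable[Sequence[tuple[str, str, float | None]]],
    truth: dict[str, TruthEntry],
    gap_tolerance: float = DEFAULT_GAP_TOLERANCE,
) -> JoinEvaluation:
    """Evaluate every adjacent pair in each scaffold against the truth.

    Each scaffold is a sequence of (contig, orientation, gap_to_next)
    triples; the last gap is ignored. TP counts flag-0 joins, FP the
    rest; P is the number of truly adjacent pairs in the layout.
    """
    flags: list[int] = []
    for scaffold in scaffolds:
        for (name_a, o_a, gap), (name_b, o_b, _) in zip(scaffold, scaffold[1:]):
            flags.append(
                classify_join((name_a, o_a), (name_b, o_b), 0.0 if gap is None else gap, truth, gap_tolerance)
            )
    P = potential_joins(truth)
    TP = sum(1 for f in flags if f == 0)
    FP = len(flags) - TP
    recall, precision, f = f_score(P, TP, FP)
    return JoinEvaluation(
        flags=tuple(flags), P=P, TP=TP, FP=FP, recall=recall, precision=precision, f_score=f
    )


def f_score(P: int, TP: int, FP: int) -> tuple[float, float, float]:
    """Join recall TP/P, precision TP/(TP+FP) and their harmonic mean."""
    if P == 0:
        raise ValueError("no potential joins: P must be > 0")
    if not (0 <= TP <= P) or FP < 0:
        raise ValueError("require 0 <= TP <= P and FP >= 0")
    recall = TP / P
    precision = TP / (TP + FP) if TP + FP > 0 else 0.0
    if TP == 0:
        return recall, precision, 0.0
    return recall, precision, 2 * recall * precision / (recall + precision)


def placements_from_sam(path: str | Path) -> tuple[list[PairPlacement], list[str], list[int]]:
    """Reconstruct pair placements from a SAM file written by this package.

    Returns (placements, contig_names, contig_lengths). Records are
    paired by query name; orphan records are ignored.
    """
    import pysam

    from .mapper import ReadScore, pair_geometry

    with pysam.AlignmentFile(str(path), "r") as sam:
        names = list(sam.references)
        lengths = [int(x) for x in sam.lengths]
        pending: dict[str, "pysam.AlignedSegment"] = {}
        placements: list[PairPlacement] = []
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            other = pending.pop(rec.query_name, None)
            if other is None:
                pending[rec.query_name] = rec
                continue
            first, second = (other, rec) if other.is_read1 else (rec, other)
            scores = []
            rescued_read = None
            for which, r in (("forward", first), ("reverse", second)):
                scores.append(
                    ReadScore(
                        score=0,
                        contig_id=r.reference_id,
                        start=r.reference_start,
                        strand="-" if r.is_reverse else "+",
                        read_length=r.infer_read_length() or len(r.query_sequence or ""),
                    )
                )
                if r.has_tag("XR"):
                    rescued_read = which
            f, s = scores
            orientation, insert = pair_geometry(f, s)
            placements.append(
                PairPlacement(
                    forward=f,
                    reverse=s,
                    rescued=rescued_read is not None,
                    rescued_read=rescued_read,
                    observed_insert=insert,
                    orientation=orientation,
                )
            )
    return placements, names, lengths


def read_scaffolds_tsv(path: str | Path) -> list[list[tuple[str, str, float | None]]]:
    """Read scaffolds as TSV with columns scaffold, contig, orientation, gap_to_next."""
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "contig": str, "orientation": str})
    scaffolds = []
    for _, grp in df.groupby("scaffold", sort=False):
        scaffolds.append(
            [
                (r.contig, r.orientation, None if pd.isna(r.gap_to_next) else float(r.gap_to_next))
                for r in grp.itertuples()
            ]
        )
    return scaffolds
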