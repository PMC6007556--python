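"""Synthetic mate-pairs cut from long reads.

Long reads carry long-range linking information but are too error-rich
for direct unique-k-mer placement over their full length. Instead, two
short windows (default 200 bp) are cut from each read at a nominal outer
distance D and emitted as a forward-reverse pair; sliding the cut point
by a fixed step (default 100 bp) tiles the read, and several D values
yield several synthetic libraries from the same data. The pairs are then
placed with the standard pair mapper using long-read thresholds.

D is the outer distance: the span from the first base of the forward
read to the last base of the reverse read is exactly D, so on error-free
reads the observed insert of a placed pair equals D.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Iterable, Iterator

from .index import UniqueKmerIndex
from .kmers import revcomp
from .mapper import MapperParams, PairPlacement, map_pair


@dataclass(frozen=True)
class SyntheticSpec:
    """Extraction and mapping parameters for synthetic mate-pair libraries."""

    insert_sizes: tuple[int, ...]
    read_length: int = 200
    step: int = 100
    min_score: int = 15
    min_rescue_score: int = 4
    hit_capacity: int = 20

    def __post_init__(self) -> None:
        object.__setattr__(self, "insert_sizes", tuple(self.insert_sizes))
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        for d in self.insert_sizes:
            if d < 2 * self.read_length:
                raise ValueError(
                    f"insert size {d} is smaller than two read lengths "
                    f"({2 * self.read_length})"
                )


@dataclass(frozen=True)
class SyntheticPair:
    """One synthetic pair: forward window and reverse-complemented mate.

    ``qr`` is stored reverse-complemented so the emitted pair is
    physically forward-reverse, like a paired-end library.
    """

    qf: str
    qr: str
    library_tag: int  # nominal outer distance D
    source_read_id: str
    source_offset: int

    @property
    def name(self) -> str:
        """Pair name encoding provenance: <read>:<offset>:<D>."""
        return f"{self.source_read_id}:{self.source_offset}:{self.library_tag}"


def extract_pairs(
    read_id: str, sequence: str, spec: SyntheticSpec
) -> Iterator[SyntheticPair]:
    """Cut synthetic pairs from one long read.

    For each insert size D and each offset s in {0, step, 2*step, ...}
    with s + D <= len(read), the forward read is read[s : s+rl] and the
    reverse read is the reverse complement of read[s+D-rl : s+D]. Reads
    shorter than D yield nothing for that D.
    """
    rl = spec.read_length
    L = len(sequence)
    for d in spec.insert_sizes:
        for s in range(0, L - d + 1, spec.step):
            yield SyntheticPair(
                qf=sequence[s : s + rl],
                qr=revcomp(sequence[s + d - rl : s + d]),
                library_tag=d,
                source_read_id=read_id,
                source_offset=s,
            )


def n_pairs(read_length: int, d: int, step: int) -> int:
    """Closed-form pair count for one read and one insert size."""
    if read_length < d:
        return 0
    return (read_length - d) // step + 1


def mapper_params_for(
    spec: SyntheticSpec, lib=None, min_fwd_score: int = 3
) -> MapperParams:
    """Long-read mapping thresholds: capacity 20, report 15, rescue 4."""
    return MapperParams(
        hit_capacity=spec.hit_capacity,
        min_fwd_score=min_fwd_score,
        min_report_score=spec.min_score,
        min_rescue_score=spec.min_rescue_score,
        lib=lib,
    )


def map_long_read_pairs(
    long_reads: Iterable[tuple[str, str]],
    index: UniqueKmerIndex,
    spec: SyntheticSpec,
    libs: dict[int, "object"] | None = None,
) -> Iterator[tuple[SyntheticPair, PairPlacement]]:
    """Extract and place synthetic pairs from ``(read_id, sequence)`` reads.

    Each placed pair is yielded with its extraction record; the
    ``library_tag`` routes it to its per-D output. ``libs`` maps D to
    estimated LibraryParams to enable pair rescue per library.
    """
    params_by_d = {
        d: mapper_params_for(spec, lib=(libs or {}).get(d)) for d in spec.insert_sizes
    }
    for read_id, seq in long_reads:
        for pair in extract_pairs(read_id, seq, spec):
            placement = map_pair(pair.qf, pair.qr, index, params_by_d[pair.library_tag])
            if placement is not None:
                yield pair, placement
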