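"""Synthetic genomes, reads and ground truth for the whole pipeline.

Everything the other modules consume can be generated here with known
truth: a random genome with planted exact repeats, a fragmentation into
contigs with a true layout, Illumina-like mate pairs (Gaussian insert,
forward-reverse, optional substitution errors and a contamination
fraction of short wrong-orientation pairs, mimicking circularization
failures in real mate-pair protocols), and long reads with technology-
flavoured error mixes: nanopore-like reads are deletion-dominant,
PacBio-like reads substitution-dominant, at ~15% total error by default.

All randomness flows through one ``numpy.random.Generator`` (PCG64)
seeded explicitly, so every output is bit-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# error-type mixes (deletion, substitution, insertion)
ERROR_PROFILES = {
    "ont": (0.60, 0.25, 0.15),
    "pacbio": (0.15, 0.60, 0.25),
}


@dataclass(frozen=True)
class IlluminaConfig:
    read_len: int = 100
    insert_mean: float = 3000.0
    insert_sd: float = 300.0
    n_pairs: int = 10_000
    error_rate: float = 0.0
    contamination_fraction: float = 0.0
    contaminant_mean: float = 300.0
    contaminant_sd: float = 50.0


@dataclass(frozen=True)
class LongReadConfig:
    mean_len: float = 10_000.0
    len_sd: float = 1_000.0
    n_reads: int = 100
    error_rate: float = 0.0
    profile: str = "ont"

    def __post_init__(self) -> None:
        if self.profile not in ERROR_PROFILES:
            raise ValueError(f"unknown error profile {self.profile!r}")


@dataclass(frozen=True)
class PairTruth:
    start: int  # leftmost genome coordinate of the fragment
    insert: int
    orientation: str
    contaminant: bool


@dataclass(frozen=True)
class LongReadTruth:
    start: int  # genome start of the error-free template
    template_len: int
    read_len: int


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_genome(
    length: int,
    repeat_spec: Sequence[tuple[int, int]] = (),
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[str, list[tuple[int, int]]]:
    """Random i.i.d. genome with exact repeats planted verbatim.

    ``repeat_spec`` lists (repeat_length, copies); each repeat unit is
    copied to random non-overlapping positions. Returns the genome and
    the planted repeat intervals as (start, end) pairs.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    total_repeat = sum(rl * c for rl, c in repeat_spec)
    if total_repeat > length:
        raise ValueError("planted repeats exceed the genome length")
    genome = np.frombuffer(_random_seq(rng, length).encode(), dtype=np.uint8).copy()
    occupied: list[tuple[int, int]] = []
    for rep_len, copies in repeat_spec:
        unit = np.frombuffer(_random_seq(rng, rep_len).encode(), dtype=np.uint8)
        placed = 0
        attempts = 0
        while placed < copies:
            attempts += 1
            if attempts > 10_000:
                raise ValueError("could not place repeats without overlap")
            start = int(rng.integers(0, length - rep_len + 1))
            iv = (start, start + rep_len)
            if any(iv[0] < e and iv[1] > s for s, e in occupied):
                continue
            genome[iv[0] : iv[1]] = unit
            occupied.append(iv)
            placed += 1
    return genome.tobytes().decode(), sorted(occupied)


def fragment_genome(
    genome: str,
    n_contigs: int | None = None,
    breakpoints: Sequence[int] | None = None,
    reference: str = "ref1",
    prefix: str = "contig",
) -> tuple[list[tuple[str, str]], list[tuple[str, str, int, int, str]]]:
    """Tile the genome into contiguous non-overlapping contigs.

    Either equal tiles (``n_contigs``) or explicit internal breakpoints.
    Returns the contigs and a truth layout of rows
    (reference, contig, start, end, strand); contigs are all cut on the
    forward strand.
    """
    if breakpoints is None:
        if n_contigs is None or n_contigs < 1:
            raise ValueError("give n_contigs or breakpoints")
        edges = np.linspace(0, len(genome), n_contigs + 1).astype(int).tolist()
    else:
        edges = [0, *sorted(breakpoints), len(genome)]
    contigs = []
    layout = []
    for i, (s, e) in enumerate(zip(edges, edges[1:]), start=1):
        if e <= s:
            raise ValueError("breakpoints must be strictly increasing within the genome")
        name = f"{prefix}{i}"
        contigs.append((name, genome[s:e]))
        layout.append((reference, name, s, e, "+"))
    return contigs, layout


def write_layout_tsv(layout, path) -> None:
    with open(path, "w") as out:
        out.write("reference\tcontig\tstart\tend\tstrand\n")
        for ref, name, s, e, strand in layout:
            out.write(f"{ref}\t{name}\t{s}\t{e}\t{strand}\n")


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    n = int(hit.sum())
    if n:
        # substitute with a uniformly different base
        idx = np.nonzero(hit)[0]
        codes = np.searchsorted(BASES, arr[idx])
        arr[idx] = BASES[(codes + rng.integers(1, 4, size=n)) % 4]
    return arr.tobytes().decode()


def simulate_illumina_pairs(
    genome: str,
    config: IlluminaConfig,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[list[tuple[str, str]], list[PairTruth]]:
    """Forward-reverse pairs with Gaussian insert from random positions.

    A ``contamination_fraction`` of pairs instead gets a short insert
    (~N(300, 50)) and a non-FR orientation (RF), like circularization
    failures. Inserts are truncated below at twice the read length.
    Returns (pairs, truths) with pairs as (forward, reverse) sequences.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    L = config.read_len
    pairs: list[tuple[str, str]] = []
    truths: list[PairTruth] = []
    for _ in range(config.n_pairs):
        contaminant = rng.random() < config.contamination_fraction
        if contaminant:
            insert = int(round(rng.normal(config.contaminant_mean, config.contaminant_sd)))
        else:
            insert = int(round(rng.normal(config.insert_mean, config.insert_sd)))
        insert = max(insert, 2 * L)
        start = int(rng.integers(0, len(genome) - insert + 1))
        frag = genome[start : start + insert]
        if contaminant:  # RF: reads point outward
            qf = _revcomp(frag[:L])
            qr = frag[-L:]
        else:  # FR
            qf = frag[:L]
            qr = _revcomp(frag[-L:])
        qf = _substitute(qf, config.error_rate, rng)
        qr = _substitute(qr, config.error_rate, rng)
        pairs.append((qf, qr))
        truths.append(PairTruth(start, insert, "RF" if contaminant else "FR", contaminant))
    return pairs, truths


def _apply_long_read_errors(
    template: str, rate: float, profile: str, rng: np.random.Generator
) -> str:
    if rate <= 0:
        return template
    p_del, p_sub, p_ins = ERROR_PROFILES[profile]
    arr = np.frombuffer(template.encode(), dtype=np.uint8)
    u = rng.random(arr.size)
    kind = np.full(arr.size, -1, dtype=np.int8)  # -1 none, 0 del, 1 sub, 2 ins
    err = u < rate
    v = rng.random(arr.size)
    kind[err & (v < p_del)] = 0
    kind[err & (v >= p_del) & (v < p_del + p_sub)] = 1
    kind[err & (v >= p_del + p_sub)] = 2
    arr = arr.copy()
    sub_idx = np.nonzero(kind == 1)[0]
    if sub_idx.size:
        codes = np.searchsorted(BASES, arr[sub_idx])
        arr[sub_idx] = BASES[(codes + rng.integers(1, 4, size=sub_idx.size)) % 4]
    kept = kind != 0
    out = arr[kept]
    ins_idx = np.nonzero(kind == 2)[0]
    if ins_idx.size:
        # position of each kept base in the deletion-compressed array;
        # the inserted base goes immediately before it
        pos_in_out = (np.cumsum(kept) - 1)[ins_idx]
        ins_bases = BASES[rng.integers(0, 4, size=ins_idx.size)]
        out = np.insert(out, pos_in_out, ins_bases)
    return out.tobytes().decode()


def simulate_long_reads(
    genome: str,
    config: LongReadConfig,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[list[tuple[str, str]], list[LongReadTruth]]:
    """Long reads with technology-flavoured errors from random positions.

    Lengths ~ N(mean_len, len_sd) truncated positive. The nanopore-like
    profile splits the error budget 60/25/15 across deletion /
    substitution / insertion; the PacBio-like profile 60/25/15 across
    substitution / insertion / deletion. Returns (reads, truths) with
    reads as (read_id, sequence).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    truths: list[LongReadTruth] = []
    for i in range(config.n_reads):
        length = int(round(rng.normal(config.mean_len, config.len_sd)))
        length = min(max(length, 100), len(genome))
        start = int(rng.integers(0, len(genome) - length + 1))
        template = genome[start : start + length]
        seq = _apply_long_read_errors(template, config.error_rate, config.profile, rng)
        read_id = f"longread{i + 1}"
        reads.append((read_id, seq))
        truths.append(LongReadTruth(start=start, template_len=length, read_len=len(seq)))
    return reads, truths
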