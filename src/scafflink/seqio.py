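"""FASTA/FASTQ reading and writing (gzip-transparent), via Biopython."""

from __future__ import annotations

import gzip
from collections.abc import Iterable, Iterator
from pathlib import Path

from Bio import SeqIO


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) for every record; wrapped lines, CRLF and
    gzip are handled transparently."""
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fasta"):
                yield rec.id, str(rec.seq)
        except ValueError as exc:
            raise ValueError(f"malformed FASTA in {path}: {exc}") from exc


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (name, sequence, quality-string) for every record."""
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
                yield rec.id, str(rec.seq), qual
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc


def read_sequences(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from FASTA or FASTQ, sniffed from the first byte."""
    with _open_text(path) as handle:
        first = handle.read(1)
    if first == ">":
        yield from read_fasta(path)
    elif first == "@":
        for name, seq, _ in read_fastq(path):
            yield name, seq
    elif first == "":
        return
    else:
        raise ValueError(f"{path}: not FASTA or FASTQ (starts with {first!r})")


def read_pairs(
    path1: str | Path, path2: str | Path | None = None
) -> Iterator[tuple[str, str]]:
    """Yield (forward, reverse) sequences from two files or one interleaved file."""
    if path2 is not None:
        it1 = read_sequences(path1)
        it2 = read_sequences(path2)
        for (_, qf), (_, qr) in zip(it1, it2):
            yield qf, qr
    else:
        it = read_sequences(path1)
        for (_, qf), (_, qr) in zip(it, it):
            yield qf, qr


def read_named_pairs(
    path1: str | Path, path2: str | Path | None = None
) -> Iterator[tuple[str, str, str]]:
    """Like read_pairs but keeps the forward read's name (suffix-stripped)."""
    if path2 is not None:
        it1 = read_sequences(path1)
        it2 = read_sequences(path2)
        pairs = zip(it1, it2)
    else:
        it = read_sequences(path1)
        pairs = zip(it, it)
    for (name, qf), (_, qr) in pairs:
        for suffix in ("/1", "/2"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
                break
        yield name, qf, qr


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as out:
        for name, seq in records:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as out:
        for name, seq, qual in records:
            out.write(f"@{name}\n{seq}\n+\n{qual}\n")
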