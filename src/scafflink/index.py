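"""Static unique-k-mer dictionary with fingerprint-controlled membership.

The index stores, for every k-mer occurring exactly once (canonically,
counting both strands) across the contig set, its contig of origin,
0-based coordinate and strand, addressable by the k-mer's canonical
64-bit hash. Lookups of stored keys always succeed; lookups of absent
keys are rejected by a 16-bit per-key fingerprint, so they succeed
falsely only with probability ~2^-16 — the behaviour of a minimal
perfect hash backed by a probabilistic dictionary. Here the hash table
itself is an exact sorted array (construction internals of a true MPHF
are not reproduced), and an absent key is routed to a pseudo-random
occupied slot before the fingerprint comparison so the false-positive
rate is faithfully emulated.

Payload widths mirror the compact layout: 32-bit contig id, 32-bit
coordinate, 1-bit strand, 16-bit fingerprint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

import numpy as np

from .kmers import canonical_hashes, fingerprint16, slot_hash

_FORMAT_VERSION = 1
_MAX_U32 = 2**32 - 1
DEFAULT_CHUNK_SIZE = 5_000_000  # bases per construction chunk


@dataclass(frozen=True)
class IndexSpec:
    """Construction parameters of the unique-k-mer index."""

    k: int
    fingerprint_bits: int = 16
    capacity_hint: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 256:
            raise ValueError(f"k must be in [1, 256], got {self.k}")
        if self.fingerprint_bits != 16:
            raise ValueError("only 16-bit fingerprints are supported")


@dataclass(frozen=True)
class KmerRecord:
    """Single occurrence of a unique k-mer: contig, coordinate, strand.

    ``strand`` is 0 when the canonical form of the k-mer was read on the
    contig's forward strand, 1 otherwise.
    """

    contig_id: int
    coordinate: int
    strand: int


@dataclass
class UniqueKmerIndex:
    """Queryable static map from canonical unique k-mers to their location."""

    spec: IndexSpec
    contig_names: list[str]
    contig_lengths: np.ndarray  # int64, one per contig
    _hashes: np.ndarray = field(repr=False)  # uint64, sorted
    _fingerprints: np.ndarray = field(repr=False)  # uint16, aligned
    _contig_ids: np.ndarray = field(repr=False)  # uint32
    _coordinates: np.ndarray = field(repr=False)  # uint32
    _strands: np.ndarray = field(repr=False)  # uint8

    @property
    def n_keys(self) -> int:
        return int(self._hashes.size)

    @property
    def k(self) -> int:
        return self.spec.k

    # -- queries ---------------------------------------------------------

    def lookup_hashes(
        self, hashes: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Batch membership query by canonical hash.

        Returns ``(found, contig_ids, coordinates, strands)``. A key that
        is present always reports its true record; an absent key passes
        the fingerprint gate (returning the record of an arbitrary slot)
        with probability ~2^-16.
        """
        q = np.ascontiguousarray(hashes, dtype=np.uint64)
        pos = np.searchsorted(self._hashes, q)
        pos_c = np.minimum(pos, self.n_keys - 1)
        present = self._hashes[pos_c] == q
        slot = np.where(present, pos_c, slot_hash(q, self.n_keys))
        found = self._fingerprints[slot] == fingerprint16(q)
        return (
            found,
            self._contig_ids[slot].astype(np.int64),
            self._coordinates[slot].astype(np.int64),
            self._strands[slot],
        )

    def lookup(self, kmer: str) -> KmerRecord | None:
        """Query one k-mer string (either strand). None if not a member."""
        if len(kmer) != self.spec.k:
            raise ValueError(
                f"query length {len(kmer)} does not match index k={self.spec.k}"
            )
        _, hashes, _ = canonical_hashes(kmer, self.spec.k)
        if hashes.size == 0:  # non-ACGT symbols: never indexed, never found
            return None
        found, cid, coord, strand = self.lookup_hashes(hashes)
        if not found[0]:
            return None
        return KmerRecord(int(cid[0]), int(coord[0]), int(strand[0]))

    # -- persistence -----------------------------------------------------

    def save(self, path: str) -> None:
        """Write the index to a single .npz archive with a versioned header."""
        header = {
            "format_version": _FORMAT_VERSION,
            "k": self.spec.k,
            "fingerprint_bits": self.spec.fingerprint_bits,
            "n_keys": self.n_keys,
            "contig_names": self.contig_names,
            "contig_lengths": [int(x) for x in self.contig_lengths],
        }
        np.savez(
            path,
            header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
            hashes=self._hashes,
            fingerprints=self._fingerprints,
            contig_ids=self._contig_ids,
            coordinates=self._coordinates,
            strands=self._strands,
        )

    @classmethod
    def load(cls, path: str) -> "UniqueKmerIndex":
        with np.load(path) as data:
            header = json.loads(bytes(data["header"]).decode())
            if header.get("format_version") != _FORMAT_VERSION:
                raise ValueError(
                    f"unsupported index format version: {header.get('format_version')}"
                )
            return cls(
                spec=IndexSpec(k=header["k"], fingerprint_bits=header["fingerprint_bits"]),
                contig_names=list(header["contig_names"]),
                contig_lengths=np.asarray(header["contig_lengths"], dtype=np.int64),
                _hashes=data["hashes"],
                _fingerprints=data["fingerprints"],
                _contig_ids=data["contig_ids"],
                _coordinates=data["coordinates"],
                _strands=data["strands"],
            )


def build_index(
    contigs: Sequence[tuple[str, str]] | Iterable[tuple[str, str]],
    spec: IndexSpec,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> UniqueKmerIndex:
    """Build the unique-k-mer index from ``(name, sequence)`` pairs.

    Contigs are scanned in chunks of ``chunk_size`` bases (with a k-1
    overlap so no k-mer is lost at a boundary); the result is identical
    for any chunk size. Exactly the canonical k-mers of frequency 1 become
    keys; each key's payload records its single occurrence.
    """
    k = spec.k
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    names: list[str] = []
    lengths: list[int] = []
    h_parts: list[np.ndarray] = []
    cid_parts: list[np.ndarray] = []
    coord_parts: list[np.ndarray] = []
    strand_parts: list[np.ndarray] = []
    for cid, (name, seq) in enumerate(contigs):
        if cid > _MAX_U32:
            raise ValueError("contig count exceeds the 32-bit id space")
        if len(seq) - k > _MAX_U32:
            raise ValueError(
                f"contig {name!r} is too long: coordinates must fit in 32 bits"
            )
        names.append(name)
        lengths.append(len(seq))
        for start in range(0, max(len(seq) - k + 1, 1), chunk_size):
            sub = seq[start : start + chunk_size + k - 1]
            offsets, hashes, fwd_canon = canonical_hashes(sub, k)
            if hashes.size == 0:
                continue
            h_parts.append(hashes)
            cid_parts.append(np.full(hashes.size, cid, dtype=np.uint32))
            coord_parts.append((offsets + start).astype(np.uint32))
            strand_parts.append(np.where(fwd_canon, 0, 1).astype(np.uint8))
    if not names:
        raise ValueError("at least one contig is required")
    if len(set(names)) != len(names):
        raise ValueError("duplicate contig names in input")
    if not h_parts:
        raise ValueError(
            f"no unique {k}-mers found: all contigs are shorter than k={k} "
            "or contain no ACGT-only k-mers"
        )
    all_h = np.concatenate(h_parts)
    all_cid = np.concatenate(cid_parts)
    all_coord = np.concatenate(coord_parts)
    all_strand = np.concatenate(strand_parts)
    uniq, counts = np.unique(all_h, return_counts=True)
    singletons = uniq[counts == 1]
    if singletons.size == 0:
        raise ValueError(
            f"no unique {k}-mers found: every {k}-mer occurs more than once; "
            "try a larger k"
        )
    keep = np.isin(all_h, singletons)
    h = all_h[keep]
    order = np.argsort(h, kind="stable")
    return UniqueKmerIndex(
        spec=spec,
        contig_names=names,
        contig_lengths=np.asarray(lengths, dtype=np.int64),
        _hashes=h[order],
        _fingerprints=fingerprint16(h[order]),
        _contig_ids=all_cid[keep][order],
        _coordinates=all_coord[keep][order],
        _strands=all_strand[keep][order],
    )
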