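"""Canonical k-mer encoding, hashing and counting.

Every k-mer is reduced to its canonical form — the lexicographic minimum of
the k-mer and its reverse complement — so that a sequence and its reverse
complement produce identical keys. Canonical k-mers are hashed to 64 bits;
for k <= 32 the k-mer is packed 2 bits/base into a uint64 and passed through
the splitmix64 finalizer (documented constants below), for larger k the
first 8 bytes of a blake2b digest of the canonical string are used. Both
paths are strand-canonical and spread keys uniformly over [0, 2^64).

K-mers containing any symbol outside {A, C, G, T} (case-insensitive) are
skipped entirely: they are neither counted, indexed nor queried.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from collections.abc import Iterable, Iterator

import numpy as np

MAX_PACKED_K = 32

# base -> 2-bit code; 255 marks non-ACGT
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCATGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (non-ACGT left untouched)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer (Steele et al. constants), vectorized on uint64."""
    with np.errstate(over="ignore"):
        x = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return x ^ (x >> np.uint64(31))


def fingerprint16(hashes: np.ndarray) -> np.ndarray:
    """16-bit fingerprints: low 16 bits of an xorshift64* remix of the key hash.

    Constants are the standard xorshift64* shifts (12, 25, 27) and the
    Vigna multiplier 0x2545F4914F6CDD1D.
    """
    x = np.asarray(hashes, dtype=np.uint64)
    with np.errstate(over="ignore"):
        x = x ^ (x >> np.uint64(12))
        x = x ^ (x << np.uint64(25))
        x = x ^ (x >> np.uint64(27))
        x = x * np.uint64(0x2545F4914F6CDD1D)
    return (x & np.uint64(0xFFFF)).astype(np.uint16)


def slot_hash(hashes: np.ndarray, n_slots: int) -> np.ndarray:
    """Pseudo-random slot in [0, n_slots) for a key hash.

    Used to emulate the behaviour of a minimal perfect hash on keys absent
    from the static set: any query lands on some occupied slot, where its
    fingerprint is compared against the stored one.
    """
    remixed = _splitmix64(np.asarray(hashes, dtype=np.uint64) ^ np.uint64(0xA5A5A5A5A5A5A5A5))
    return (remixed % np.uint64(n_slots)).astype(np.int64)


def _encode_bases(sequence: str) -> np.ndarray:
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def encode_kmers(sequence: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pack every valid k-mer of ``sequence`` into canonical uint64 codes.

    Returns ``(offsets, canonical_codes, forward_is_canonical)`` where
    ``offsets`` are the 0-based start positions of k-mers free of non-ACGT
    symbols, ``canonical_codes`` the 2-bit-packed canonical form and
    ``forward_is_canonical`` a bool array telling which strand the canonical
    form was read from. Requires k <= 32.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > MAX_PACKED_K:
        raise ValueError(f"packed encoding supports k <= {MAX_PACKED_K}")
    n = len(sequence) - k + 1
    if n <= 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    codes = _encode_bases(sequence)
    valid_base = codes != 255
    # a window is valid iff all k of its bases are valid
    csum = np.concatenate(([0], np.cumsum(valid_base)))
    window_valid = (csum[k:] - csum[:-k]) == k
    offsets = np.nonzero(window_valid)[0].astype(np.int64)
    if offsets.size == 0:
        return offsets, np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    b = np.where(valid_base, codes, 0).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for j in range(k):
            fwd = (fwd << np.uint64(2)) | b[j : j + n]
            # reverse complement reads positions k-1-j, complemented
            rc = (rc << np.uint64(2)) | (np.uint64(3) - b[k - 1 - j : k - 1 - j + n])
    fwd = fwd[offsets]
    rc = rc[offsets]
    forward_is_canonical = fwd <= rc
    canonical = np.where(forward_is_canonical, fwd, rc)
    return offsets, canonical, forward_is_canonical


def _hash_large_k(sequence: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fallback canonical hashing for k > 32 via blake2b digests."""
    offsets, hashes, fwd_canon = [], [], []
    for i in range(len(sequence) - k + 1):
        w = sequence[i : i + k].upper()
        if any(c not in "ACGT" for c in w):
            continue
        rc = revcomp(w)
        canon = min(w, rc)
        h = int.from_bytes(hashlib.blake2b(canon.encode(), digest_size=8).digest(), "little")
        offsets.append(i)
        hashes.append(h)
        fwd_canon.append(canon == w)
    return (
        np.asarray(offsets, dtype=np.int64),
        np.asarray(hashes, dtype=np.uint64),
        np.asarray(fwd_canon, dtype=bool),
    )


def canonical_hashes(sequence: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Strand-canonical 64-bit hash of every valid k-mer.

    Returns ``(offsets, hashes, forward_is_canonical)``; a k-mer and its
    reverse complement always hash identically. Sequences shorter than k
    yield empty arrays.
    """
    if k > MAX_PACKED_K:
        return _hash_large_k(sequence, k)
    offsets, canonical, fwd_canon = encode_kmers(sequence, k)
    return offsets, _splitmix64(canonical), fwd_canon


def random_canonical_kmer_hashes(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Canonical hashes of ``n`` uniform random k-mers (k <= 32).

    Draws each k-mer as a packed 2-bit code (uniform bases), computes the
    reverse-complement code, canonicalizes and hashes — the same pipeline
    a k-mer string would take, vectorized for bulk membership studies.
    """
    if k > MAX_PACKED_K:
        raise ValueError(f"supported for k <= {MAX_PACKED_K}")
    code = rng.integers(0, 4**k, size=n, dtype=np.int64).astype(np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    three = np.uint64(3)
    with np.errstate(over="ignore"):
        for j in range(k):
            base = (code >> np.uint64(2 * j)) & three  # base at position k-1-j
            rc |= (three - base) << np.uint64(2 * (k - 1 - j))
    return _splitmix64(np.minimum(code, rc))


def canonical_hash_stream(sequence: str, k: int) -> Iterator[tuple[int, int]]:
    """Yield ``(offset, hash)`` for every valid k-mer, left to right."""
    offsets, hashes, _ = canonical_hashes(sequence, k)
    for off, h in zip(offsets.tolist(), hashes.tolist()):
        yield off, h


def count_canonical_kmers(contigs: Iterable[str], k: int) -> Counter:
    """Count canonical k-mer hashes over a set of contigs.

    A k-mer and its reverse complement share one canonical key, so the
    count aggregates occurrences on both strands. Contigs shorter than k
    contribute nothing.
    """
    counts: Counter = Counter()
    any_contig = False
    for seq in contigs:
        any_contig = True
        _, hashes, _ = canonical_hashes(seq, k)
        if hashes.size:
            uniq, c = np.unique(hashes, return_counts=True)
            for h, n in zip(uniq.tolist(), c.tolist()):
                counts[h] += n
    if not any_contig:
        raise ValueError("at least one contig is required")
    return counts
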