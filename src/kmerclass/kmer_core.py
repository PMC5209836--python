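"""Canonical 2-bit k-mer encoding.

A k-mer over {A, C, G, T} is packed into a single unsigned 64-bit integer
at 2 bits per base under the order-preserving map A=0, C=1, G=2, T=3, with
the first base in the most significant occupied bit pair.  Under this map
integer comparison of two equal-length codes is identical to lexicographic
comparison of the base strings, so the *canonical* k-mer — the
lexicographically smaller of a k-mer and its reverse complement, the single
representative stored and queried for both strands — is simply
``min(code, revcomp(code))``.

k is capped at 31 so a code occupies at most 62 bits of one machine word.
Any character outside {A,C,G,T} (after uppercasing) is treated as
ambiguous: reads are split at ambiguous positions and fragments shorter
than k, which contain no complete k-mer, are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "SequenceSegment",
    "encode_kmer",
    "decode_kmer",
    "reverse_complement",
    "canonical",
    "split_on_ambiguous",
    "extract_canonical_kmers",
    "encode_bases",
]

MAX_K = 31
_BASES = "ACGT"

# 256-entry lookup: A/a=0, C/c=1, G/g=2, T/t=3, everything else = 255 (ambiguous).
_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i


def _check_k(k: int) -> None:
    if not isinstance(k, (int, np.integer)) or not 1 <= k <= MAX_K:
        raise ValueError(f"k must be an integer in [1, {MAX_K}], got {k!r}")


@dataclass(frozen=True)
class SequenceSegment:
    """A maximal run of unambiguous bases within a read.

    ``offset`` is the 0-based start position of the run in the original
    read; ``bases`` is uppercase and contains only A/C/G/T.
    """

    read_id: str | None
    offset: int
    bases: str

    def __len__(self) -> int:
        return len(self.bases)


def encode_bases(bases: str) -> np.ndarray:
    """Map a base string to a uint8 array of 2-bit codes (255 = ambiguous)."""
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    return _BASE_LUT[arr]


def encode_kmer(bases: str) -> int:
    """Pack a k-mer string into its raw (non-canonical) 2-bit code.

    Raises ``ValueError`` naming the offending character and position if
    the input is empty, longer than 31, or contains an ambiguous base.
    """
    k = len(bases)
    if k == 0:
        raise ValueError("cannot encode an empty k-mer")
    _check_k(k)
    codes = encode_bases(bases)
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"ambiguous character {bases[pos]!r} at position {pos} in k-mer {bases!r}"
        )
    value = 0
    for c in codes:
        value = (value << 2) | int(c)
    return value


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`: unpack a raw code into its base string."""
    _check_k(k)
    code = int(code)
    if not 0 <= code < 4**k:
        raise ValueError(f"code {code} out of range for k={k}")
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


def reverse_complement(code: int | np.ndarray, k: int):
    """Reverse-complement a raw 2-bit code (or array of codes).

    An involution: applying it twice returns the input.
    """
    _check_k(k)
    scalar = np.isscalar(code) or (isinstance(code, np.ndarray) and code.ndim == 0)
    c = np.asarray(code, dtype=np.uint64).copy()
    if np.any(c >= np.uint64(4**k)):
        raise ValueError(f"code out of range for k={k}")
    rc = np.zeros_like(c)
    three = np.uint64(3)
    two = np.uint64(2)
    for _ in range(k):
        rc = (rc << two) | ((c & three) ^ three)
        c = c >> two
    return int(rc) if scalar else rc


def canonical(code: int | np.ndarray, k: int):
    """Canonical form of a raw code: ``min(code, reverse_complement(code))``.

    Idempotent, and identical for a k-mer and its reverse complement.
    """
    scalar = np.isscalar(code) or (isinstance(code, np.ndarray) and code.ndim == 0)
    rc = reverse_complement(code, k)
    res = np.minimum(np.asarray(code, dtype=np.uint64), np.asarray(rc, dtype=np.uint64))
    return int(res) if scalar else res


def split_on_ambiguous(
    read_bases: str, k: int, read_id: str | None = None
) -> list[SequenceSegment]:
    """Split a read at ambiguous characters into k-mer-bearing segments.

    The read is uppercased, cut at every character outside {A,C,G,T}, and
    every maximal unambiguous run of length >= k is returned with its
    original offset.  Runs shorter than k contain no complete k-mer and
    are discarded; an empty result is valid.
    """
    _check_k(k)
    if not read_bases:
        return []
    upper = read_bases.upper()
    codes = encode_bases(upper)
    ok = codes != 255
    # boundaries of maximal True runs
    padded = np.concatenate(([False], ok, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return [
        SequenceSegment(read_id=read_id, offset=int(s), bases=upper[s:e])
        for s, e in zip(starts, ends)
        if e - s >= k
    ]


def extract_canonical_kmers(segment: SequenceSegment | str, k: int) -> np.ndarray:
    """All consecutive canonical k-mer codes of a segment, left to right.

    Returns exactly ``len(segment) - k + 1`` uint64 codes, duplicates
    preserved.  The caller must have filtered segments shorter than k.
    """
    _check_k(k)
    bases = segment.bases if isinstance(segment, SequenceSegment) else segment
    if len(bases) < k:
        raise ValueError(f"segment of length {len(bases)} shorter than k={k}")
    codes = encode_bases(bases)
    if np.any(codes == 255):
        raise ValueError("segment contains ambiguous characters; split first")
    windows = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.uint64)
    powers = np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64)
    raw = (windows * powers).sum(axis=1, dtype=np.uint64)
    return canonical(raw, k)


def iter_read_kmers(
    read_bases: str, k: int, read_id: str | None = None
) -> Iterator[np.ndarray]:
    """Yield one canonical-code array per k-mer-bearing segment of a read."""
    for seg in split_on_ambiguous(read_bases, k, read_id=read_id):
        yield extract_canonical_kmers(seg, k)
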