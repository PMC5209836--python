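"""Discriminative-k-mer index: build, sample, partition, serialize.

The index holds every canonical k-mer that occurs in *exactly one* target
across all reference genomes (a target may group several genomes, e.g. all
genomes of one genus).  k-mers shared by multiple targets carry no
discriminative signal and are removed.

The in-memory layout is flat and bucketed.  A packed k-mer code is split
into a *remainder*, which selects a hash bucket (see :func:`bucket_of`),
and a *quotient* (the high bits), which is the key stored in the bucket.  All buckets live consecutively in one contiguous key array and one
parallel target-id array; a pointer array, the prefix sum of the bucket
sizes, gives the start of each bucket.  Within a bucket quotients are
unique and sorted ascending, so a lookup is a binary search over a short
span.  Because entries are ordered by (bucket, quotient), the whole key
array is also globally sorted under the combined key
``(bucket << quotient_bits) | quotient``, which lets a batch of queries be
resolved with one vectorized ``searchsorted``.

Two derived views share the lookup contract:

* :func:`apply_sampling` keeps only every s-th bucket (bucket number
  divisible by s), trading sensitivity for memory — queries into skipped
  buckets miss immediately.
* :func:`partition_index` splits the arrays into chunks of contiguous
  bucket ranges with locally rebased pointers, so an index larger than
  working memory can be queried one chunk at a time and the partial
  scores merged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from kmerclass.kmer_core import MAX_K, extract_canonical_kmers, split_on_ambiguous

__all__ = [
    "MISS",
    "TargetTable",
    "DiscriminativeIndex",
    "IndexChunk",
    "IndexFormatError",
    "IndexCorruptionError",
    "bucket_of",
    "code_of",
    "collect_kmer_targets",
    "build_index",
    "partition_index",
    "apply_sampling",
    "save_index",
    "load_index",
]

#: Sentinel returned by lookups for absent (or out-of-chunk) k-mers.
MISS = -1

_FORMAT_VERSION = 1
_HEADER_FILE = "header.json"
_ARRAY_FILES = {"keys": "keys.npy", "values": "values.npy", "pointers": "pointers.npy"}


def bucket_of(codes: int | np.ndarray, bucket_bits: int) -> int | np.ndarray:
    """Hash bucket of a canonical code: ``(code ^ (code >> b)) & (2^b - 1)``.

    The plain low-order bits of *canonical* codes are not uniform — the
    canonical choice (min of k-mer and reverse complement) biases the
    trailing bases toward A/C — so the high bits are XOR-folded in to even
    out bucket occupancy.  The split stays lossless: with quotient
    ``q = code >> b``, the code is ``(q << b) | (bucket ^ (q & mask))``.
    """
    scalar = np.isscalar(codes)
    c = np.asarray(codes, dtype=np.uint64)
    mask = np.uint64((1 << bucket_bits) - 1)
    res = (c ^ (c >> np.uint64(bucket_bits))) & mask
    return int(res) if scalar else res


def code_of(quotient: int | np.ndarray, bucket: int | np.ndarray, bucket_bits: int):
    """Inverse of the (quotient, bucket) split: reconstruct the stored code."""
    q = np.asarray(quotient, dtype=np.uint64)
    bkt = np.asarray(bucket, dtype=np.uint64)
    mask = np.uint64((1 << bucket_bits) - 1)
    res = (q << np.uint64(bucket_bits)) | (bkt ^ (q & mask))
    return int(res) if np.isscalar(quotient) else res


class IndexFormatError(ValueError):
    """Header of an on-disk index is missing, unreadable, or incompatible."""


class IndexCorruptionError(ValueError):
    """On-disk arrays disagree with the header (truncated or inconsistent)."""


@dataclass(frozen=True)
class TargetTable:
    """Mapping between 0-based integer target ids and user-facing labels.

    ``entries[i]`` is ``(label, genome_files)`` for target id ``i``; labels
    are unique and ids are assigned by order of first appearance.
    """

    labels: tuple[str, ...]
    genome_files: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("target labels must be unique")
        if len(self.labels) != len(self.genome_files):
            raise ValueError("labels and genome_files must have equal length")

    @property
    def n_targets(self) -> int:
        return len(self.labels)

    def label(self, target_id: int) -> str:
        return self.labels[target_id]

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]]) -> "TargetTable":
        """Build from (genome_file, label) pairs; ids by first appearance of label."""
        labels: list[str] = []
        files: dict[str, list[str]] = {}
        for path, label in pairs:
            if label not in files:
                labels.append(label)
                files[label] = []
            files[label].append(path)
        return cls(tuple(labels), tuple(tuple(files[l]) for l in labels))


def _combined_keys(keys: np.ndarray, pointers: np.ndarray, k: int, bucket_bits: int,
                   bucket_start: int) -> np.ndarray:
    """Globally sorted combined key (bucket << quotient_bits) | quotient."""
    sizes = np.diff(pointers)
    buckets = np.repeat(
        np.arange(bucket_start, bucket_start + sizes.size, dtype=np.uint64), sizes
    )
    shift = np.uint64(2 * k - bucket_bits)
    return (buckets << shift) | keys


class _BucketedLookup:
    """Shared lookup machinery for a full index and a chunk."""

    k: int
    bucket_bits: int
    keys: np.ndarray
    values: np.ndarray
    pointers: np.ndarray
    bucket_start: int  # first bucket covered (0 for a full index)

    @property
    def n_entries(self) -> int:
        return int(self.keys.size)

    @property
    def _comb(self) -> np.ndarray:
        cached = getattr(self, "_comb_cache", None)
        if cached is None:
            cached = _combined_keys(
                self.keys, self.pointers, self.k, self.bucket_bits, self.bucket_start
            )
            object.__setattr__(self, "_comb_cache", cached)
        return cached

    def _covers(self, bucket: np.ndarray) -> np.ndarray:
        n_local = self.pointers.size - 1
        return (bucket >= self.bucket_start) & (bucket < self.bucket_start + n_local)

    def lookup_many(self, codes: np.ndarray) -> np.ndarray:
        """Vectorized lookup: target id per code, ``MISS`` where absent.

        Codes must already be canonical; this hot path does not re-check.
        """
        codes = np.asarray(codes, dtype=np.uint64)
        out = np.full(codes.shape, MISS, dtype=np.int64)
        if codes.size == 0 or self.n_entries == 0:
            return out
        b = np.uint64(self.bucket_bits)
        bucket = bucket_of(codes, self.bucket_bits)
        shift = np.uint64(2 * self.k - self.bucket_bits)
        sel = self._covers(bucket)
        qcomb = (bucket[sel] << shift) | (codes[sel] >> b)
        pos = np.searchsorted(self._comb, qcomb)
        pos_c = np.minimum(pos, self._comb.size - 1)
        hit = self._comb[pos_c] == qcomb
        res = np.full(qcomb.shape, MISS, dtype=np.int64)
        res[hit] = self.values[pos_c[hit]]
        out[sel] = res
        return out

    def lookup(self, code: int) -> int:
        """Target id storing ``code``, or ``MISS``.

        Raises ``ValueError`` if ``code`` is not canonical — querying a
        non-canonical code is always a caller bug.
        """
        from kmerclass.kmer_core import canonical

        code = int(code)
        if canonical(code, self.k) != code:
            raise ValueError(f"lookup requires a canonical code, got {code}")
        return int(self.lookup_many(np.array([code], dtype=np.uint64))[0])


@dataclass(frozen=True)
class DiscriminativeIndex(_BucketedLookup):
    """Flat bucketed index of discriminative canonical k-mers.

    ``pointers`` has length ``2**bucket_bits + 1`` and is the prefix sum of
    bucket sizes; ``keys[pointers[i]:pointers[i+1]]`` are the sorted
    quotients of bucket ``i`` and ``values`` the parallel target ids.
    """

    k: int
    bucket_bits: int
    keys: np.ndarray
    values: np.ndarray
    pointers: np.ndarray
    target_table: TargetTable
    sampling_factor: int = 1
    bucket_start: int = field(default=0, init=False)

    @property
    def n_buckets(self) -> int:
        return 1 << self.bucket_bits

    def bucket_sizes(self) -> np.ndarray:
        return np.diff(self.pointers)


@dataclass(frozen=True)
class IndexChunk(_BucketedLookup):
    """A contiguous bucket range of an index with locally rebased pointers.

    Lookups for codes whose bucket falls outside ``bucket_range`` return
    ``MISS``; concatenating the chunks of one partition in bucket order
    reproduces the parent arrays exactly.
    """

    k: int
    bucket_bits: int
    bucket_range: tuple[int, int]  # half-open [first_bucket, last_bucket)
    keys: np.ndarray
    values: np.ndarray
    pointers: np.ndarray
    target_table: TargetTable

    @property
    def bucket_start(self) -> int:  # type: ignore[override]
        return self.bucket_range[0]


def collect_kmer_targets(target_table: TargetTable, k: int) -> dict[int, set[int]]:
    """Collect every canonical k-mer of every genome with its target set.

    Genomes are read as FASTA (multi-record allowed; all records of one
    file belong to that file's target), uppercased, split at ambiguous
    characters, and windowed into canonical codes.  The result maps each
    canonical code to the set of target ids it occurs in — the builder
    intermediate from which shared k-mers are filtered.
    """
    if not isinstance(k, (int, np.integer)) or not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k!r}")
    if target_table.n_targets == 0:
        raise ValueError("target table is empty: at least one target required")
    occ: dict[int, set[int]] = {}
    for tid, files in enumerate(target_table.genome_files):
        target_codes: set[int] = set()
        for path in files:
            p = Path(path)
            if not p.exists():
                raise IOError(f"genome file not found: {path}")
            n_records = 0
            try:
                for record in SeqIO.parse(str(p), "fasta"):
                    n_records += 1
                    for seg in split_on_ambiguous(str(record.seq), k):
                        target_codes.update(
                            extract_canonical_kmers(seg, k).tolist()
                        )
            except ValueError as exc:
                raise IOError(f"failed to parse FASTA {path}: {exc}") from exc
            if n_records == 0:
                raise IOError(f"empty or non-FASTA file: {path}")
        for code in target_codes:
            occ.setdefault(code, set()).add(tid)
    return occ


def build_index(
    occ: dict[int, set[int]],
    k: int,
    bucket_bits: int,
    target_table: TargetTable,
) -> DiscriminativeIndex:
    """Filter shared k-mers and lay out the flat bucketed index.

    Keeps exactly the k-mers whose target set has size 1 (the
    discriminative ones).  Bucket of code c is :func:`bucket_of`; the
    stored key is the quotient ``c >> bucket_bits``; pointers are the
    prefix sum of bucket sizes; quotients sorted within buckets.
    """
    if not 0 <= bucket_bits <= 2 * k:
        raise ValueError(
            f"bucket_bits must be in [0, 2k]={2 * k}, got {bucket_bits}"
        )
    disc = [(c, next(iter(ts))) for c, ts in occ.items() if len(ts) == 1]
    n_buckets = 1 << bucket_bits
    if disc:
        codes = np.array([c for c, _ in disc], dtype=np.uint64)
        tids = np.array([t for _, t in disc], dtype=np.uint32)
        bucket = bucket_of(codes, bucket_bits)
        quot = codes >> np.uint64(bucket_bits)
        order = np.lexsort((quot, bucket))
        bucket, quot, tids = bucket[order], quot[order], tids[order]
        sizes = np.bincount(bucket.astype(np.int64), minlength=n_buckets)
    else:
        quot = np.empty(0, dtype=np.uint64)
        tids = np.empty(0, dtype=np.uint32)
        sizes = np.zeros(n_buckets, dtype=np.int64)
    pointers = np.zeros(n_buckets + 1, dtype=np.int64)
    np.cumsum(sizes, out=pointers[1:])
    return DiscriminativeIndex(
        k=k,
        bucket_bits=bucket_bits,
        keys=quot,
        values=tids,
        pointers=pointers,
        target_table=target_table,
        sampling_factor=1,
    )


def partition_index(index: DiscriminativeIndex, n_chunks: int) -> list[IndexChunk]:
    """Split the index into chunks of contiguous bucket ranges.

    Boundaries are placed greedily on the pointer (prefix-sum) array so
    entry counts are as balanced as contiguous bucket ranges allow; the
    ranges are disjoint and cover all buckets.
    """
    n_buckets = index.n_buckets
    if not 1 <= n_chunks <= n_buckets:
        raise ValueError(f"n_chunks must be in [1, {n_buckets}], got {n_chunks}")
    total = index.n_entries
    boundaries = [0]
    for j in range(1, n_chunks):
        ideal = total * j / n_chunks
        pos = int(np.searchsorted(index.pointers, ideal, side="left"))
        # pick the neighbouring bucket boundary closest to the ideal count
        if pos > 0 and abs(int(index.pointers[pos - 1]) - ideal) < abs(
            int(index.pointers[min(pos, n_buckets)]) - ideal
        ):
            pos -= 1
        pos = min(max(pos, boundaries[-1]), n_buckets)
        boundaries.append(pos)
    boundaries.append(n_buckets)
    chunks = []
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        p_lo, p_hi = int(index.pointers[lo]), int(index.pointers[hi])
        chunks.append(
            IndexChunk(
                k=index.k,
                bucket_bits=index.bucket_bits,
                bucket_range=(lo, hi),
                keys=index.keys[p_lo:p_hi],
                values=index.values[p_lo:p_hi],
                pointers=index.pointers[lo : hi + 1] - index.pointers[lo],
                target_table=index.target_table,
            )
        )
    return chunks


def apply_sampling(index: DiscriminativeIndex, s: int) -> DiscriminativeIndex:
    """Keep only the buckets whose number is divisible by s.

    s=1 returns content equal to the input (the whole database).  For
    s>1 whole buckets are skipped: their pointer spans collapse to empty,
    so queries into them miss immediately.  The factor is recorded on the
    result.
    """
    if not isinstance(s, (int, np.integer)) or s < 1:
        raise ValueError(f"sampling factor must be an integer >= 1, got {s!r}")
    s = int(s)
    if s == 1:
        return DiscriminativeIndex(
            k=index.k,
            bucket_bits=index.bucket_bits,
            keys=index.keys.copy(),
            values=index.values.copy(),
            pointers=index.pointers.copy(),
            target_table=index.target_table,
            sampling_factor=1,
        )
    sizes = index.bucket_sizes()
    bucket_ids = np.arange(index.n_buckets, dtype=np.int64)
    kept_sizes = np.where(bucket_ids % s == 0, sizes, 0)
    entry_buckets = np.repeat(bucket_ids, sizes)
    keep = entry_buckets % s == 0
    pointers = np.zeros(index.n_buckets + 1, dtype=np.int64)
    np.cumsum(kept_sizes, out=pointers[1:])
    return DiscriminativeIndex(
        k=index.k,
        bucket_bits=index.bucket_bits,
        keys=index.keys[keep],
        values=index.values[keep],
        pointers=pointers,
        target_table=index.target_table,
        sampling_factor=s,
    )


def save_index(index: DiscriminativeIndex, directory: str | Path) -> None:
    """Write the index as a self-describing header plus three flat arrays.

    The header (JSON) records format version, k, bucket_bits, entry count
    and the target table; keys/values/pointers are stored as little-endian
    ``.npy`` arrays, mirroring the in-memory layout for fast loading.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = {
        "format_version": _FORMAT_VERSION,
        "k": index.k,
        "bucket_bits": index.bucket_bits,
        "n_entries": index.n_entries,
        "targets": [
            {"label": lab, "genome_files": list(files)}
            for lab, files in zip(index.target_table.labels, index.target_table.genome_files)
        ],
    }
    (directory / _HEADER_FILE).write_text(json.dumps(header, indent=1))
    np.save(directory / _ARRAY_FILES["keys"], index.keys.astype("<u8"))
    np.save(directory / _ARRAY_FILES["values"], index.values.astype("<u4"))
    np.save(directory / _ARRAY_FILES["pointers"], index.pointers.astype("<i8"))


def load_index(directory: str | Path, s: int = 1) -> DiscriminativeIndex:
    """Load an index directory, applying the sampling factor at read time.

    ``load_index(d, s)`` equals ``apply_sampling(load_index(d, 1), s)``.
    Raises :class:`IndexFormatError` on a bad header and
    :class:`IndexCorruptionError` when the arrays disagree with it.
    """
    directory = Path(directory)
    header_path = directory / _HEADER_FILE
    if not header_path.exists():
        raise IndexFormatError(f"no index header at {header_path}")
    try:
        header = json.loads(header_path.read_text())
    except json.JSONDecodeError as exc:
        raise IndexFormatError(f"unreadable index header: {exc}") from exc
    if header.get("format_version") != _FORMAT_VERSION:
        raise IndexFormatError(
            f"unsupported format version {header.get('format_version')!r}"
        )
    k = header.get("k")
    bucket_bits = header.get("bucket_bits")
    if not isinstance(k, int) or not 1 <= k <= MAX_K:
        raise IndexFormatError(f"invalid k in header: {k!r}")
    if not isinstance(bucket_bits, int) or not 0 <= bucket_bits <= 2 * k:
        raise IndexFormatError(f"invalid bucket_bits in header: {bucket_bits!r}")
    table = TargetTable(
        tuple(t["label"] for t in header["targets"]),
        tuple(tuple(t["genome_files"]) for t in header["targets"]),
    )
    try:
        keys = np.load(directory / _ARRAY_FILES["keys"]).astype(np.uint64)
        values = np.load(directory / _ARRAY_FILES["values"]).astype(np.uint32)
        pointers = np.load(directory / _ARRAY_FILES["pointers"]).astype(np.int64)
    except (OSError, ValueError) as exc:
        raise IndexCorruptionError(f"unreadable index arrays: {exc}") from exc
    n = header.get("n_entries")
    if keys.size != n or values.size != n or pointers.size != (1 << bucket_bits) + 1:
        raise IndexCorruptionError(
            f"array sizes (keys={keys.size}, values={values.size}, "
            f"pointers={pointers.size}) disagree with header (n_entries={n}, "
            f"bucket_bits={bucket_bits})"
        )
    if int(pointers[-1]) != n or np.any(np.diff(pointers) < 0):
        raise IndexCorruptionError("pointer array is not a valid prefix sum")
    index = DiscriminativeIndex(
        k=k,
        bucket_bits=bucket_bits,
        keys=keys,
        values=values,
        pointers=pointers,
        target_table=table,
        sampling_factor=1,
    )
    return apply_sampling(index, s) if s != 1 else index
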