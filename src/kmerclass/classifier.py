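"""Query, merge, finalize: read scoring against the discriminative index.

A read is pre-processed once — uppercased, split at ambiguous characters,
sub-k fragments discarded, remaining windows canonicalized — and its
canonical codes are queried against the index.  Every successful lookup is
a *hit* for the stored target; because indexed k-mers are discriminative,
each k-mer hits at most one target and the per-read hit total never
exceeds the number of k-mers queried.

When the index is queried in chunks (contiguous bucket ranges), each chunk
produces a *compacted* partial score list — (target, hits) pairs with all
zero counters dropped — and the partial lists are merged by per-target
addition, an associative and commutative fold whose identity is the empty
list.  The final step picks the two best targets: the read is assigned to
the target with the most hits, with confidence h1/(h1+h2) from the best
and second-best counts (1.0 when nothing else scored, exactly 0.5 on a
two-way tie, the lowest possible value) and gamma = h1/n_kmers.  Ties are
broken deterministically toward the smaller target id.  Results are
invariant to how the work is split into chunks and batches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from kmerclass.database import DiscriminativeIndex, IndexChunk, partition_index
from kmerclass.kmer_core import extract_canonical_kmers, split_on_ambiguous

__all__ = [
    "EncodedRead",
    "ScoreList",
    "ReadResult",
    "encode_read",
    "query_reads",
    "merge_score_lists",
    "finalize",
    "classify",
]


@dataclass(frozen=True)
class EncodedRead:
    """A read reduced to its canonical k-mer codes (all segments pooled)."""

    read_id: str
    length: int
    k: int
    codes: np.ndarray  # uint64, length == n_kmers

    @property
    def n_kmers(self) -> int:
        return int(self.codes.size)


@dataclass(frozen=True)
class ScoreList:
    """Compacted per-read scores: (target_id, hits) pairs, hits >= 1.

    Pairs are sorted by target id and target ids are unique; zero counters
    carry no information and are never stored.
    """

    read_id: str
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        tids = [t for t, _ in self.pairs]
        if any(h < 1 for _, h in self.pairs):
            raise ValueError("score list must not contain zero-hit pairs")
        if tids != sorted(set(tids)):
            raise ValueError("score list pairs must be sorted by unique target id")

    @property
    def total_hits(self) -> int:
        return sum(h for _, h in self.pairs)


@dataclass(frozen=True)
class ReadResult:
    """Per-read assignment with confidence.

    ``best_target is None`` marks an unclassified read (no valid k-mer or
    no hit anywhere); confidence and gamma are then undefined (``None``).
    """

    read_id: str
    length: int
    n_kmers: int
    total_hits: int
    best_target: int | None
    best_score: int
    second_target: int | None
    second_score: int
    confidence: float | None
    gamma: float | None
    scores: ScoreList | None = None


def encode_read(read_id: str, bases: str, k: int) -> EncodedRead:
    """Pre-process one read into its pooled canonical k-mer codes."""
    segments = split_on_ambiguous(bases, k, read_id=read_id)
    if segments:
        codes = np.concatenate([extract_canonical_kmers(s, k) for s in segments])
    else:
        codes = np.empty(0, dtype=np.uint64)
    return EncodedRead(read_id=read_id, length=len(bases), k=k, codes=codes)


def query_reads(
    reads: Sequence[EncodedRead],
    part: DiscriminativeIndex | IndexChunk,
) -> list[ScoreList]:
    """Score a batch of encoded reads against one index part.

    ``hits[t]`` counts, with multiplicity, the read's canonical k-mers
    that resolve to target t in this part; misses (including buckets
    outside a chunk's range) contribute nothing.  Output is compacted.
    """
    for r in reads:
        if r.k != part.k:
            raise ValueError(
                f"read {r.read_id!r} encoded with k={r.k} but index has k={part.k}"
            )
    if not reads:
        return []
    codes = np.concatenate([r.codes for r in reads]) if reads else np.empty(0, np.uint64)
    counts_per_read = np.array([r.n_kmers for r in reads], dtype=np.int64)
    read_idx = np.repeat(np.arange(len(reads), dtype=np.int64), counts_per_read)
    vals = part.lookup_many(codes)
    hit = vals >= 0
    n_targets = part.target_table.n_targets
    combined = read_idx[hit] * n_targets + vals[hit]
    uniq, counts = np.unique(combined, return_counts=True)
    out_pairs: list[list[tuple[int, int]]] = [[] for _ in reads]
    for key, cnt in zip(uniq.tolist(), counts.tolist()):
        out_pairs[key // n_targets].append((key % n_targets, cnt))
    return [
        ScoreList(read_id=r.read_id, pairs=tuple(p))
        for r, p in zip(reads, out_pairs)
    ]


def merge_score_lists(a: ScoreList, b: ScoreList) -> ScoreList:
    """Per-target sum of two partial score lists for the same read.

    Associative and commutative; the empty list is the identity.
    """
    if a.read_id != b.read_id:
        raise ValueError(f"cannot merge scores of reads {a.read_id!r} and {b.read_id!r}")
    merged: dict[int, int] = dict(a.pairs)
    for tid, h in b.pairs:
        merged[tid] = merged.get(tid, 0) + h
    return ScoreList(
        read_id=a.read_id, pairs=tuple(sorted(merged.items()))
    )


def finalize(
    scores: ScoreList,
    n_kmers: int,
    length: int,
    keep_scores: bool = False,
) -> ReadResult:
    """Turn a fully merged score list into a read assignment.

    Best and second-best are the two largest hit counts, ties broken
    toward the smaller target id for both ranks.  confidence = h1/(h1+h2)
    (1.0 when h2 == 0, exactly 0.5 on a two-way tie); gamma = h1/n_kmers.
    A read with no k-mers or no hits is unclassified, not an error.
    """
    kept = scores if keep_scores else None
    if n_kmers == 0 or not scores.pairs:
        return ReadResult(
            read_id=scores.read_id,
            length=length,
            n_kmers=n_kmers,
            total_hits=scores.total_hits,
            best_target=None,
            best_score=0,
            second_target=None,
            second_score=0,
            confidence=None,
            gamma=None,
            scores=kept,
        )
    ranked = sorted(scores.pairs, key=lambda p: (-p[1], p[0]))
    best_target, h1 = ranked[0]
    if len(ranked) > 1:
        second_target, h2 = ranked[1]
    else:
        second_target, h2 = None, 0
    return ReadResult(
        read_id=scores.read_id,
        length=length,
        n_kmers=n_kmers,
        total_hits=scores.total_hits,
        best_target=best_target,
        best_score=h1,
        second_target=second_target,
        second_score=h2,
        confidence=h1 / (h1 + h2) if h2 else 1.0,
        gamma=h1 / n_kmers,
        scores=kept,
    )


def classify(
    reads_source: Iterable[tuple[str, str]],
    index: DiscriminativeIndex,
    n_chunks: int = 1,
    n_batches: int = 1,
    keep_scores: bool = False,
) -> list[ReadResult]:
    """Full pipeline: batch, query each index chunk, merge, finalize.

    ``reads_source`` yields ``(read_id, bases)`` in input order.  The
    input is cut into ``n_batches`` consecutive batches; each batch is
    queried against each of the ``n_chunks`` index parts in turn and the
    partial score lists folded with :func:`merge_score_lists`.  The output
    preserves input order and is invariant to both knobs.
    """
    if n_chunks < 1:
        raise ValueError(f"n_chunks must be >= 1, got {n_chunks}")
    if n_batches < 1:
        raise ValueError(f"n_batches must be >= 1, got {n_batches}")
    reads = list(reads_source)
    chunks = partition_index(index, min(n_chunks, index.n_buckets))
    results: list[ReadResult] = []
    for batch in np.array_split(np.arange(len(reads)), min(n_batches, max(len(reads), 1))):
        encoded = [encode_read(reads[i][0], reads[i][1], index.k) for i in batch]
        if not encoded:
            continue
        merged: list[ScoreList] | None = None
        for chunk in chunks:
            partial = query_reads(encoded, chunk)
            if merged is None:
                merged = partial
            else:
                merged = [merge_score_lists(m, p) for m, p in zip(merged, partial)]
        assert merged is not None
        results.extend(
            finalize(m, r.n_kmers, r.length, keep_scores=keep_scores)
            for m, r in zip(merged, encoded)
        )
    return results
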