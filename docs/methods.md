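# Methods

## Model and assumptions

A *target* is a flat classification unit: one label covering one or more
reference genome FASTA files. The method assumes that exact k-mer
identity with a reference is the unit of evidence — no alignment, no
mismatches within a k-mer, no taxonomy tree, no lowest-common-ancestor
logic. A k-mer is informative only if it occurs in exactly one target
(*discriminative*); shared k-mers are discarded at build time, which
makes every query hit attributable to a single target and bounds the
per-read hit total by the number of k-mers queried.

Reads and references are treated strand-symmetrically through *canonical*
k-mers: each window is replaced by the lexicographic minimum of itself
and its reverse complement. Codes are packed 2 bits per base (A=0, C=1,
G=2, T=3, first base most significant), so integer comparison equals
lexicographic comparison and canonicalization is `min(code, revcomp)`.
k is capped at 31 to keep a code within 62 bits of one 64-bit word.

Any character outside {A,C,G,T} (after uppercasing) is treated as
ambiguous, not only `N`: real data contains other IUPAC codes, and
splitting at all of them is the conservative generalization. Reads are
split at ambiguous positions; fragments shorter than k contain no
complete k-mer and are discarded. A read with no valid k-mer (or no hit)
is still reported, as an unclassified row, so the output stays alignable
with the input.

## Index layout

All entries live in three flat arrays: sorted quotient keys, parallel
target ids, and a pointer array of length `2^b + 1` (the prefix sum of
bucket sizes, `b` = `bucket_bits`, default 16). The bucket of a code is

    bucket(c) = (c ^ (c >> b)) & (2^b - 1)

and the stored key is the quotient `c >> b`. The split is lossless: the
code is recoverable as `(q << b) | (bucket ^ (q & mask))`. A plain
low-bits remainder was measured first and rejected: canonical selection
biases the trailing bases of stored codes toward A/C, making low-bit
bucket occupancy non-uniform (e.g. the fraction of entries in buckets
divisible by 6 was 0.207 rather than 1/6). XOR-folding the high bits into
the remainder restores uniform occupancy (measured 0.166) while keeping
the quotient/remainder structure and the flat layout.

Within a bucket quotients are unique and sorted. Because entries are
ordered by (bucket, quotient), the whole table is globally sorted under
the combined key `(bucket << (2k−b)) | quotient`, and a batch of queries
is resolved with a single vectorized binary search; a per-bucket linear
scan would be contract-equivalent.

Occurrence counts per target are collected during construction but
discarded after the shared-k-mer filter: classification increments hit
counters by one per query hit regardless of how often the k-mer occurs in
the genome, so multiplicities affect nothing downstream. A k-mer
occurring many times within *one* target remains discriminative — only
cross-target sharing removes it.

## Chunking, batching, sampling

- **Chunks** are contiguous bucket ranges with locally rebased pointers.
  Boundaries are placed greedily on the prefix-sum array, so entry counts
  are as balanced as contiguous ranges allow. Querying chunk by chunk and
  merging the compacted (target, hits) lists by per-target addition is an
  associative, commutative fold with the empty list as identity; results
  are therefore invariant to the number of chunks and to input batching,
  which the tests check bit-for-bit on written result files.
- **Sampling** with factor s keeps exactly the buckets whose number is
  divisible by s (s = 1 keeps everything). It is applied at load time;
  a sampled index is a strict subset of the full one, so per-read hit
  counts can only decrease.
- Counters are Python/NumPy 64-bit integers; narrow-counter overflow
  semantics are an accelerator optimization, not part of the method.

## Assignment and ties

Best and second-best targets are the two largest hit counts, both ranks
breaking ties toward the smaller target id. The tie rule is a documented
implementation choice: when several targets reach the same score the data
cannot distinguish them, and the reported confidence h₁/(h₁+h₂) is then
the lowest possible value (exactly 0.5 for a two-way tie). h₂ = 0 gives
confidence 1.0. γ = h₁/n_kmers uses the number of k-mers actually
queried as denominator; the per-read hit total is also retained so other
ratios can be recomputed from the extended output.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 31 (27 with `--light`) | k-mer length, in bases; ≤ 31 |
| bucket_bits | 16 | log2 of the bucket count; 2^16 keeps the pointer array at ~0.5 MB while keeping buckets short at desk scale |
| s | 1 | sampling factor; keep every s-th bucket |
| n_chunks | 1 | number of database parts queried per batch |
| n_batches | 16 | number of input batches |

The defaults mirror full-mode usage; tests and examples use k = 15 with
10 kb genomes so that the k-mer space (4^15) still dwarfs the total
sequence and chance cross-target collisions stay negligible, while builds
take milliseconds.

## Synthetic data: what it does and does not emulate

The generator draws i.i.d. uniform A/C/G/T genomes (one per target),
optionally prefixed with one shared block copied verbatim into every
genome (`shared_fraction`), and samples reads uniformly over targets,
positions and strands with i.i.d. substitution errors and i.i.d. 'N'
masking. This gives exact control over the two properties the algorithm
depends on — which k-mers are shared and how reads are perturbed — and
makes ground truth exact.

It deliberately does *not* emulate real genomes or sequencers: no GC
bias, no repeat families, no indels, no platform error profiles.
Passing tests therefore demonstrate algorithmic correctness (the right
k-mers are indexed, counted, merged and ranked), not field accuracy on
real communities, which depends on reference completeness and genome
similarity structure.

Default study conditions used throughout tests and the acceptance
script: 5 targets × 10 kb, shared_fraction 0.2, 1000 reads × 100 bp,
error rate 1%, fixed seeds. Under these conditions reads falling wholly
inside the shared block (≈19% of positions) are unclassified by
construction; with no shared block and no errors, recovery is expected to
be perfect because a misassignment would require a cross-target k-mer
collision (probability ≈ total k-mers / 4^15 per k-mer).

## Numerical and degenerate cases

- Empty occurrence map → an index with all buckets empty and an all-zero
  pointer array; lookups miss.
- Genomes shorter than k contribute nothing; an all-ambiguous read
  yields an unclassified row, not an error.
- `n_chunks` is clamped to the bucket count; a sampling factor larger
  than the bucket count keeps only bucket 0.
- Serialization is a JSON header (format version, k, bucket_bits, entry
  count, target table) plus three little-endian `.npy` arrays; loading
  validates version, parameter ranges, array lengths against the header,
  and the prefix-sum property, distinguishing format errors from
  corruption.

## Known limitations

- k > 31 would need multi-word codes; not supported.
- Targets are flat labels: no taxonomy, no abundance estimation.
- The on-disk format is this package's own; it does not read databases
  produced by other classifiers.
- Express/spaced-seed modes and accelerator execution are out of scope;
  the chunk/merge pipeline reproduces the input/output contract of
  multi-device querying sequentially.
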