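"""Shared fixtures and independent string-level oracles.

The oracles deliberately work on base *strings* (Python ``min``, slicing,
dict counting) so they share no code with the packed-integer
implementation they check.
"""

from __future__ import annotations

import pytest

from kmerclass.database import TargetTable, build_index, collect_kmer_targets
from kmerclass.io_formats import read_targets_definition
from kmerclass.synthetic import generate_community, write_community

_COMP = str.maketrans("ACGT", "TGCA")


def rc_str(s: str) -> str:
    """String-level reverse complement."""
    return s.translate(_COMP)[::-1]


def canon_str(s: str) -> str:
    """String-level canonical k-mer: lexicographic min of s and rc(s)."""
    r = rc_str(s)
    return s if s <= r else r


def segment_kmers_str(seq: str, k: int) -> list[str]:
    """Canonical k-mer strings of one unambiguous sequence, in order."""
    return [canon_str(seq[i : i + k]) for i in range(len(seq) - k + 1)]


def read_kmers_str(seq: str, k: int) -> list[str]:
    """Canonical k-mer strings of a read: uppercase, split at non-ACGT."""
    seq = seq.upper()
    out: list[str] = []
    run = []
    for ch in seq + "!":  # sentinel flushes the last run
        if ch in "ACGT":
            run.append(ch)
        else:
            if len(run) >= k:
                out.extend(segment_kmers_str("".join(run), k))
            run = []
    return out


def brute_force_discriminative(genomes: list[str], k: int) -> dict[str, int]:
    """Naive discriminative map: canonical k-mer string -> its sole target."""
    per_target = [set(segment_kmers_str(g.upper(), k)) for g in genomes]
    owners: dict[str, set[int]] = {}
    for tid, kmers in enumerate(per_target):
        for km in kmers:
            owners.setdefault(km, set()).add(tid)
    return {km: next(iter(ts)) for km, ts in owners.items() if len(ts) == 1}


def brute_force_hits(read: str, k: int, disc: dict[str, int]) -> dict[int, int]:
    """Naive per-target hit counts for one read (multiplicity counted)."""
    hits: dict[int, int] = {}
    for km in read_kmers_str(read, k):
        tid = disc.get(km)
        if tid is not None:
            hits[tid] = hits.get(tid, 0) + 1
    return hits


# --- standard synthetic communities -------------------------------------

STANDARD_SEED = 1234
STANDARD_K = 15
STANDARD_BUCKET_BITS = 16


@pytest.fixture(scope="session")
def community():
    """5 targets x 10 kb, 20% shared block, 1000 x 100 bp reads at 1% error."""
    return generate_community(
        n_targets=5,
        genome_length=10_000,
        shared_fraction=0.2,
        n_reads=1000,
        read_length=100,
        error_rate=0.01,
        seed=STANDARD_SEED,
    )


@pytest.fixture(scope="session")
def clean_community():
    """Error-free community with no shared block (perfect-recovery regime)."""
    return generate_community(
        n_targets=5,
        genome_length=10_000,
        shared_fraction=0.0,
        n_reads=1000,
        read_length=100,
        error_rate=0.0,
        seed=STANDARD_SEED + 1,
    )


def _index_for(com, k=STANDARD_K, bucket_bits=STANDARD_BUCKET_BITS):
    table = TargetTable(
        com.target_table.labels, com.target_table.genome_files
    )
    occ = {}
    for tid, genome in enumerate(com.genomes):
        from kmerclass.kmer_core import extract_canonical_kmers, split_on_ambiguous

        for seg in split_on_ambiguous(genome, k):
            for code in extract_canonical_kmers(seg, k).tolist():
                occ.setdefault(code, set()).add(tid)
    return build_index(occ, k, bucket_bits, table)


@pytest.fixture(scope="session")
def index(community):
    """Discriminative index over the standard community (k=15)."""
    return _index_for(community)


@pytest.fixture(scope="session")
def clean_index(clean_community):
    return _index_for(clean_community)


@pytest.fixture(scope="session")
def community_on_disk(tmp_path_factory, community):
    """The standard community written out as FASTA/FASTQ/targets/truth."""
    directory = tmp_path_factory.mktemp("community")
    return write_community(community, directory)


@pytest.fixture(scope="session")
def disk_index(community_on_disk):
    """Index built through the file-based path (targets file -> FASTA)."""
    table = read_targets_definition(community_on_disk["targets"])
    occ = collect_kmer_targets(table, STANDARD_K)
    return build_index(occ, STANDARD_K, STANDARD_BUCKET_BITS, table)
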