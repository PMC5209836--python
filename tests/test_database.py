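"""Index construction, lookup, partitioning, sampling, serialization."""

import json

import numpy as np
import pytest

from kmerclass.database import (
    MISS,
    bucket_of,
    code_of,
    IndexCorruptionError,
    IndexFormatError,
    TargetTable,
    apply_sampling,
    build_index,
    collect_kmer_targets,
    load_index,
    partition_index,
    save_index,
)
from kmerclass.kmer_core import canonical, encode_kmer
from tests.conftest import canon_str


def _write_fasta(path, seqs):
    with open(path, "wt") as fh:
        for i, s in enumerate(seqs):
            fh.write(f">rec{i}\n{s}\n")
    return str(path)


def _table(tmp_path, genomes_per_target):
    """One FASTA per target holding that target's sequences."""
    files, labels = [], []
    for tid, seqs in enumerate(genomes_per_target):
        labels.append(f"t{tid}")
        files.append((_write_fasta(tmp_path / f"t{tid}.fasta", seqs),))
    return TargetTable(tuple(labels), tuple(files))


class TestCollect:
    def test_reverse_complement_genomes_collapse_to_one_key(self, tmp_path):
        table = _table(tmp_path, [["AAAAC"], ["GTTTT"]])
        occ = collect_kmer_targets(table, 5)
        assert occ == {encode_kmer("AAAAC"): {0, 1}}
        assert canon_str("GTTTT") == "AAAAC"

    def test_single_genome_windows(self, tmp_path):
        table = _table(tmp_path, [["ACGTA"]])
        occ = collect_kmer_targets(table, 3)
        expected = {encode_kmer(canon_str(km)) for km in ("ACG", "CGT", "GTA")}
        assert set(occ) == expected
        assert all(ts == {0} for ts in occ.values())

    def test_genome_shorter_than_k_gives_empty_map(self, tmp_path):
        table = _table(tmp_path, [["ACG"]])
        assert collect_kmer_targets(table, 5) == {}

    def test_ambiguous_characters_split_genomes(self, tmp_path):
        table = _table(tmp_path, [["ACGNTGA"]])
        occ = collect_kmer_targets(table, 3)
        expected = {encode_kmer(canon_str(km)) for km in ("ACG", "TGA")}
        assert set(occ) == expected

    def test_missing_and_empty_files_error(self, tmp_path):
        with pytest.raises(IOError, match="not found"):
            collect_kmer_targets(TargetTable(("x",), (("nope.fasta",),)), 5)
        empty = tmp_path / "empty.fasta"
        empty.write_text("")
        with pytest.raises(IOError, match="empty"):
            collect_kmer_targets(TargetTable(("x",), ((str(empty),),)), 5)


class TestBuild:
    table2 = TargetTable(("a", "b"), (("a.fa",), ("b.fa",)))

    def test_shared_kmers_removed(self):
        c1, c2, c3 = 5, 9, 17
        occ = {c1: {0}, c2: {0, 1}, c3: {1}}
        idx = build_index(occ, 5, 3, self.table2)
        assert idx.n_entries == 2
        stored = {
            code_of(int(q), b, 3): int(v)
            for b in range(8)
            for q, v in zip(
                idx.keys[idx.pointers[b] : idx.pointers[b + 1]],
                idx.values[idx.pointers[b] : idx.pointers[b + 1]],
            )
        }
        assert stored == {c1: 0, c3: 1}

    def test_empty_map_gives_zero_pointers(self):
        idx = build_index({}, 5, 4, self.table2)
        assert idx.n_entries == 0
        assert np.all(idx.pointers == 0)
        assert idx.pointers.size == 17

    def test_prefix_sum_matches_naive_bucketing(self):
        rng = np.random.default_rng(0)
        codes = rng.choice(4**7, size=100, replace=False)
        occ = {int(c): {int(i % 2)} for i, c in enumerate(codes)}
        idx = build_index(occ, 7, 4, self.table2)
        assert idx.n_entries == 100
        assert idx.pointers[16] == 100
        naive = np.bincount([bucket_of(c, 4) for c in occ], minlength=16)
        assert np.array_equal(np.diff(idx.pointers), naive)
        # within-bucket quotients unique and sorted
        for b in range(16):
            q = idx.keys[idx.pointers[b] : idx.pointers[b + 1]]
            assert np.all(np.diff(q.astype(np.int64)) > 0) or q.size <= 1

    def test_bucket_bits_bounds(self):
        with pytest.raises(ValueError):
            build_index({}, 3, 7, self.table2)  # b > 2k
        with pytest.raises(ValueError):
            build_index({}, 3, -1, self.table2)


class TestLookup:
    def _small_index(self):
        occ = {int(canonical(c, 5)): {t} for c, t in [(5, 0), (170, 1), (333, 0)]}
        return build_index(occ, 5, 4, TargetTable(("a", "b"), (("a",), ("b",))))

    def test_membership_and_miss(self):
        idx = self._small_index()
        assert idx.lookup(int(canonical(170, 5))) == 1
        assert idx.lookup(int(canonical(5, 5))) == 0
        absent = int(canonical(7, 5))
        if absent not in {int(canonical(c, 5)) for c in (5, 170, 333)}:
            assert idx.lookup(absent) == MISS

    def test_non_canonical_code_rejected(self):
        idx = self._small_index()
        bad = encode_kmer("TTTTT")  # canonical form is AAAAA
        with pytest.raises(ValueError, match="canonical"):
            idx.lookup(bad)

    def test_chunk_misses_out_of_range_bucket(self, index):
        chunks = partition_index(index, 2)
        lo, hi = chunks[0].bucket_range
        # a stored code whose bucket is outside chunk 0's range
        sizes = np.diff(index.pointers)
        bucket_of_entry = np.repeat(np.arange(index.n_buckets), sizes)
        outside = bucket_of_entry >= hi
        assert outside.any()
        i = int(np.nonzero(outside)[0][0])
        code = code_of(int(index.keys[i]), int(bucket_of_entry[i]), index.bucket_bits)
        assert index.lookup_many(np.array([code], dtype=np.uint64))[0] != MISS
        assert chunks[0].lookup_many(np.array([code], dtype=np.uint64))[0] == MISS
        assert chunks[1].lookup_many(np.array([code], dtype=np.uint64))[0] != MISS


class TestPartition:
    def test_single_chunk_is_identity(self, index):
        (chunk,) = partition_index(index, 1)
        assert chunk.bucket_range == (0, index.n_buckets)
        assert np.array_equal(chunk.keys, index.keys)
        assert np.array_equal(chunk.values, index.values)
        assert np.array_equal(chunk.pointers, index.pointers)

    def test_everything_in_bucket_zero(self):
        codes = [c for c in range(4**5) if bucket_of(c, 2) == 0][:10]
        occ = {c: {0} for c in codes}
        idx = build_index(occ, 5, 2, TargetTable(("a",), (("a",),)))
        chunks = partition_index(idx, 2)
        assert chunks[0].n_entries == 10
        assert chunks[1].n_entries == 0

    @pytest.mark.parametrize("n_chunks", [1, 2, 4, 7])
    def test_partition_is_lossless(self, index, n_chunks):
        chunks = partition_index(index, n_chunks)
        ranges = [c.bucket_range for c in chunks]
        assert ranges[0][0] == 0 and ranges[-1][1] == index.n_buckets
        assert all(a[1] == b[0] for a, b in zip(ranges, ranges[1:]))
        assert np.array_equal(np.concatenate([c.keys for c in chunks]), index.keys)
        assert np.array_equal(np.concatenate([c.values for c in chunks]), index.values)
        # rebased pointers re-concatenate to the parent prefix sum
        rebuilt = [np.asarray([0])]
        offset = 0
        for c in chunks:
            rebuilt.append(c.pointers[1:] + offset)
            offset += c.n_entries
        assert np.array_equal(np.concatenate(rebuilt), index.pointers)

    def test_out_of_range_chunk_count(self, index):
        with pytest.raises(ValueError):
            partition_index(index, 0)
        with pytest.raises(ValueError):
            partition_index(index, index.n_buckets + 1)


class TestSampling:
    def test_s1_is_identity(self, index):
        out = apply_sampling(index, 1)
        assert np.array_equal(out.keys, index.keys)
        assert np.array_equal(out.values, index.values)
        assert np.array_equal(out.pointers, index.pointers)
        assert out.sampling_factor == 1

    def test_keeps_every_second_bucket(self):
        # construct codes giving bucket sizes [3, 1, 2, 4] for b=2
        sizes = [3, 1, 2, 4]
        occ: dict[int, set[int]] = {}
        remaining = list(sizes)
        for c in range(4**5):
            b = bucket_of(c, 2)
            if remaining[b]:
                remaining[b] -= 1
                occ[c] = {0}
            if not any(remaining):
                break
        idx = build_index(occ, 5, 2, TargetTable(("a",), (("a",),)))
        assert np.array_equal(np.diff(idx.pointers), sizes)
        sampled = apply_sampling(idx, 2)
        assert sampled.n_entries == 3 + 2
        assert np.array_equal(np.diff(sampled.pointers), [3, 0, 2, 0])
        assert sampled.sampling_factor == 2

    def test_degenerate_factor_keeps_only_bucket_zero(self, index):
        s = index.n_buckets + 1
        sampled = apply_sampling(index, s)
        assert sampled.n_entries == int(index.pointers[1])

    @pytest.mark.parametrize("s", [2, 3, 6])
    def test_sampling_is_a_subset(self, index, s):
        sampled = apply_sampling(index, s)
        full = set(zip(index.keys.tolist(), index.values.tolist()))
        sub = set(zip(sampled.keys.tolist(), sampled.values.tolist()))
        assert sub <= full
        sizes = np.diff(sampled.pointers)
        skipped = np.arange(index.n_buckets) % s != 0
        assert np.all(sizes[skipped] == 0)

    def test_invalid_factor(self, index):
        with pytest.raises(ValueError):
            apply_sampling(index, 0)


class TestSerialization:
    def test_round_trip_bit_for_bit(self, index, tmp_path):
        save_index(index, tmp_path / "db")
        loaded = load_index(tmp_path / "db")
        assert loaded.k == index.k and loaded.bucket_bits == index.bucket_bits
        assert np.array_equal(loaded.keys, index.keys)
        assert np.array_equal(loaded.values, index.values)
        assert np.array_equal(loaded.pointers, index.pointers)
        assert loaded.target_table.labels == index.target_table.labels

    def test_load_time_sampling_commutes(self, index, tmp_path):
        save_index(index, tmp_path / "db")
        direct = load_index(tmp_path / "db", s=6)
        via_memory = apply_sampling(load_index(tmp_path / "db", s=1), 6)
        assert np.array_equal(direct.keys, via_memory.keys)
        assert np.array_equal(direct.values, via_memory.values)
        assert np.array_equal(direct.pointers, via_memory.pointers)
        assert direct.sampling_factor == 6

    def test_header_tamper_detected(self, index, tmp_path):
        save_index(index, tmp_path / "db")
        header_path = tmp_path / "db" / "header.json"
        header = json.loads(header_path.read_text())
        header["k"] = 99
        header_path.write_text(json.dumps(header))
        with pytest.raises(IndexFormatError):
            load_index(tmp_path / "db")

    def test_truncated_arrays_detected(self, index, tmp_path):
        save_index(index, tmp_path / "db")
        keys_path = tmp_path / "db" / "keys.npy"
        truncated = np.load(keys_path)[:-5]
        np.save(keys_path, truncated)
        with pytest.raises(IndexCorruptionError):
            load_index(tmp_path / "db")
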