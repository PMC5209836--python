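"""Ground-truth communities: synthetic genomes, reads, and accuracy summaries.

Every other module is testable without downloading reference data: this
module draws i.i.d. uniform A/C/G/T genomes (one per target), samples
reads uniformly over targets, positions and strands, perturbs them with
i.i.d. substitution errors and 'N' masking, and records which target each
read came from.

Two knobs give exact control over the properties the classifier depends
on:

* ``shared_fraction`` — a single random block of this fraction of the
  genome length is copied verbatim into the start of *every* genome, so
  every k-mer wholly inside it is shared across all targets and must be
  removed by the discriminativeness filter.
* At ``shared_fraction=0`` and the default genome lengths, cross-target
  k-mer collisions are vanishingly rare (the code space 4^k dwarfs the
  total sequence), so essentially every k-mer is discriminative and an
  error-free read must be recovered perfectly.

Uniform genomes are deliberately unrealistic (no GC bias, no repeats
beyond chance): the generator targets algorithmic correctness, not
biological realism.  Errors are substitution-only; exact k-mer matching
reacts to any perturbation the same way, so indels would add nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from kmerclass.classifier import ReadResult
from kmerclass.database import TargetTable

__all__ = [
    "SyntheticCommunity",
    "AccuracySummary",
    "generate_targets",
    "generate_reads",
    "generate_community",
    "write_community",
    "evaluate_assignments",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class SyntheticCommunity:
    """A generated reference set plus reads with known origins."""

    target_table: TargetTable
    genomes: tuple[str, ...]  # one genome per target, same order as the table
    reads: tuple[tuple[str, str], ...]  # (read_id, bases)
    truth: dict[str, int]  # read_id -> source target_id
    parameters: dict = field(default_factory=dict)


@dataclass(frozen=True)
class AccuracySummary:
    """Overall and per-target classification accuracy.

    precision = correct / classified (None when nothing was classified);
    sensitivity = correct / total reads; per_target maps target id to a
    dict with the same two keys plus the read count.
    """

    n_reads: int
    n_classified: int
    n_correct: int
    precision: float | None
    sensitivity: float
    unclassified_fraction: float
    per_target: dict[int, dict[str, float | int | None]]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def generate_targets(
    n_targets: int,
    genome_length: int,
    shared_fraction: float,
    seed: int,
    label_prefix: str = "target",
) -> tuple[list[str], TargetTable]:
    """Draw one uniform random genome per target, with an optional shared block.

    A block of ``round(shared_fraction * genome_length)`` bases is copied
    verbatim into the start of every genome, guaranteeing shared (hence
    non-discriminative) k-mers for filter testing.  Same seed, same output.
    """
    if n_targets < 2:
        raise ValueError(f"n_targets must be >= 2, got {n_targets}")
    if not 0 <= shared_fraction < 1:
        raise ValueError(f"shared_fraction must be in [0, 1), got {shared_fraction}")
    if genome_length < 1:
        raise ValueError(f"genome_length must be positive, got {genome_length}")
    rng = np.random.default_rng(seed)
    block_len = int(round(shared_fraction * genome_length))
    block = _random_seq(rng, block_len)
    genomes = [
        block + _random_seq(rng, genome_length - block_len) for _ in range(n_targets)
    ]
    labels = tuple(f"{label_prefix}_{i}" for i in range(n_targets))
    table = TargetTable(labels, tuple((f"{lab}.fasta",) for lab in labels))
    return genomes, table


def generate_reads(
    genomes: Sequence[str],
    n_reads: int,
    read_length: int,
    error_rate: float,
    ambiguous_rate: float,
    seed: int,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Sample reads uniformly over targets, positions and strands.

    Substitution errors hit each position i.i.d. at ``error_rate`` (the
    base is replaced by a *different* one); independently, positions are
    masked to 'N' at ``ambiguous_rate``.  Returns the reads and the truth
    mapping read_id -> source target id.
    """
    if not 0 <= error_rate < 1 or not 0 <= ambiguous_rate < 1:
        raise ValueError("error_rate and ambiguous_rate must be in [0, 1)")
    if any(read_length > len(g) for g in genomes):
        raise ValueError("read_length exceeds a genome length")
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    truth: dict[str, int] = {}
    for i in range(n_reads):
        tid = int(rng.integers(0, len(genomes)))
        genome = genomes[tid]
        pos = int(rng.integers(0, len(genome) - read_length + 1))
        bases = genome[pos : pos + read_length]
        if rng.integers(0, 2):
            bases = _revcomp(bases)
        arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8).copy()
        if error_rate > 0:
            err = np.nonzero(rng.random(read_length) < error_rate)[0]
            for p in err:
                current = arr[p : p + 1].tobytes().decode()
                choices = [b for b in "ACGT" if b != current]
                arr[p] = ord(choices[int(rng.integers(0, 3))])
        if ambiguous_rate > 0:
            amb = rng.random(read_length) < ambiguous_rate
            arr[amb] = ord("N")
        read_id = f"read_{i}"
        reads.append((read_id, arr.tobytes().decode("ascii")))
        truth[read_id] = tid
    return reads, truth


def generate_community(
    n_targets: int = 5,
    genome_length: int = 10_000,
    shared_fraction: float = 0.2,
    n_reads: int = 1000,
    read_length: int = 100,
    error_rate: float = 0.01,
    ambiguous_rate: float = 0.0,
    seed: int = 0,
) -> SyntheticCommunity:
    """Generate genomes and reads in one call; fully seed-deterministic.

    Defaults describe the standard test community: 5 targets of 10 kb
    with a 20% shared block, 1000 reads of 100 bp at 1% substitution
    error.
    """
    genomes, table = generate_targets(n_targets, genome_length, shared_fraction, seed)
    reads, truth = generate_reads(
        genomes, n_reads, read_length, error_rate, ambiguous_rate, seed=seed + 1
    )
    return SyntheticCommunity(
        target_table=table,
        genomes=tuple(genomes),
        reads=tuple(reads),
        truth=truth,
        parameters={
            "n_targets": n_targets,
            "genome_length": genome_length,
            "shared_fraction": shared_fraction,
            "n_reads": n_reads,
            "read_length": read_length,
            "error_rate": error_rate,
            "ambiguous_rate": ambiguous_rate,
            "seed": seed,
        },
    )


def write_community(community: SyntheticCommunity, directory: str | Path) -> dict[str, Path]:
    """Materialize a community on disk in the package's external formats.

    Writes one FASTA per genome, a targets-definition file, the reads as
    FASTQ (constant quality), and a two-column truth TSV.  Returns the
    paths keyed by role (``targets``, ``reads``, ``truth``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table = community.target_table
    targets_path = directory / "targets.txt"
    with open(targets_path, "wt") as tf:
        for tid, (label, genome) in enumerate(zip(table.labels, community.genomes)):
            fasta = directory / f"{label}.fasta"
            with open(fasta, "wt") as fh:
                fh.write(f">{label}\n")
                for i in range(0, len(genome), 70):
                    fh.write(genome[i : i + 70] + "\n")
            tf.write(f"{fasta.name} {label}\n")
    reads_path = directory / "reads.fastq"
    with open(reads_path, "wt") as fh:
        for read_id, bases in community.reads:
            fh.write(f"@{read_id}\n{bases}\n+\n{'I' * len(bases)}\n")
    truth_path = directory / "truth.tsv"
    with open(truth_path, "wt") as fh:
        for read_id, tid in community.truth.items():
            fh.write(f"{read_id}\t{table.label(tid)}\n")
    return {"targets": targets_path, "reads": reads_path, "truth": truth_path}


def evaluate_assignments(
    results: Sequence[ReadResult], truth: Mapping[str, int]
) -> AccuracySummary:
    """Score assignments against the ground truth.

    Requires results and truth to cover exactly the same read ids.
    """
    result_ids = {r.read_id for r in results}
    if result_ids != set(truth):
        missing = set(truth) - result_ids
        extra = result_ids - set(truth)
        raise ValueError(
            f"results and truth disagree on read ids "
            f"({len(missing)} missing, {len(extra)} unexpected)"
        )
    n_reads = len(results)
    per_counts: dict[int, dict[str, int]] = {}
    n_classified = n_correct = 0
    for r in results:
        tid = truth[r.read_id]
        c = per_counts.setdefault(tid, {"total": 0, "classified": 0, "correct": 0})
        c["total"] += 1
        if r.best_target is not None:
            n_classified += 1
            c["classified"] += 1
            if r.best_target == tid:
                n_correct += 1
                c["correct"] += 1
    per_target = {
        tid: {
            "n_reads": c["total"],
            "precision": c["correct"] / c["classified"] if c["classified"] else None,
            "sensitivity": c["correct"] / c["total"],
        }
        for tid, c in sorted(per_counts.items())
    }
    return AccuracySummary(
        n_reads=n_reads,
        n_classified=n_classified,
        n_correct=n_correct,
        precision=n_correct / n_classified if n_classified else None,
        sensitivity=n_correct / n_reads if n_reads else 0.0,
        unclassified_fraction=(n_reads - n_classified) / n_reads if n_reads else 0.0,
        per_target=per_target,
    )
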