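"""Sequence input, targets-definition parsing, and CLARK-style CSV output.

Input reads may be FASTA or FASTQ, optionally gzip-compressed; the format
is auto-detected from the first character of the (decompressed) stream
('>' = FASTA, '@' = FASTQ).  FASTQ quality strings are validated by the
parser but discarded — the method uses exact k-mer matches only.

The per-read results file follows the column layout of CLARK's full-mode
CSV so downstream post-processing scripts that consume that format keep
working: ``Object_ID,Length,Gamma,1st_assignment,score1,2nd_assignment,
score2,confidence``, one row per input read, ``NA`` for unclassified
fields, gamma and confidence printed with 6 decimals.  The extended output
additionally reports the complete per-target hit vector (zeros included)
for every read.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator, Sequence

from Bio import SeqIO

from kmerclass.classifier import ReadResult
from kmerclass.database import TargetTable

__all__ = [
    "ReadRecord",
    "ParseError",
    "read_sequences",
    "read_targets_definition",
    "write_results_csv",
    "write_extended_results",
    "RESULTS_HEADER",
]

RESULTS_HEADER = (
    "Object_ID,Length,Gamma,1st_assignment,score1,2nd_assignment,score2,confidence"
)


class ParseError(ValueError):
    """Malformed sequence or targets-definition input."""


@dataclass(frozen=True)
class ReadRecord:
    """One query read: id (first header token), bases, and source format."""

    read_id: str
    bases: str
    source_format: str  # "fasta" or "fastq"


def _open_text(path: str | Path) -> IO[str]:
    """Open a possibly gzip-compressed file as text (magic-byte sniffing)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sequences(path: str | Path) -> Iterator[ReadRecord]:
    """Stream reads from a FASTA or FASTQ file (gzip transparent).

    Records are yielded in file order; the read id is the header token
    before the first whitespace.  Duplicate ids are allowed but warned
    about.  Malformed records (FASTQ length mismatch, empty sequence)
    raise :class:`ParseError`.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"input file not found: {path}")
    handle = _open_text(path)
    try:
        first = handle.read(1)
        handle.seek(0)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        else:
            raise ParseError(
                f"{path}: cannot detect format from first character {first!r} "
                "(expected '>' for FASTA or '@' for FASTQ)"
            )
        seen: set[str] = set()
        try:
            for record in SeqIO.parse(handle, fmt):
                bases = str(record.seq)
                if not bases:
                    raise ParseError(f"{path}: record {record.id!r} has an empty sequence")
                if record.id in seen:
                    warnings.warn(f"duplicate read id {record.id!r} in {path}")
                seen.add(record.id)
                yield ReadRecord(read_id=record.id, bases=bases, source_format=fmt)
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    finally:
        handle.close()


def read_targets_definition(path: str | Path) -> TargetTable:
    """Parse the targets-definition file into a :class:`TargetTable`.

    Plain text, one genome per line: ``<fasta_path> <target_label>``,
    whitespace-separated; ``#`` lines are comments; several lines may
    share a label (multi-genome target).  Ids follow first appearance.
    Relative genome paths are resolved against the file's directory.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"targets-definition file not found: {path}")
    pairs: list[tuple[str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected '<fasta_path> <target_label>', got {line!r}"
            )
        genome_path = Path(fields[0])
        if not genome_path.is_absolute():
            genome_path = path.parent / genome_path
        if not genome_path.exists():
            raise IOError(f"{path}:{lineno}: genome file not found: {fields[0]}")
        pairs.append((str(genome_path), fields[1]))
    if not pairs:
        raise ValueError(f"{path}: no target definitions found")
    return TargetTable.from_pairs(pairs)


def _fmt6(x: float | None) -> str:
    return "NA" if x is None else f"{x:.6f}"


def write_results_csv(
    results: Sequence[ReadResult], target_table: TargetTable, path: str | Path
) -> None:
    """Write the per-read assignment CSV (one row per input read)."""
    path = Path(path)
    with open(path, "wt") as out:
        out.write(RESULTS_HEADER + "\n")
        for r in results:
            if r.best_target is None:
                out.write(f"{r.read_id},{r.length},NA,NA,NA,NA,NA,NA\n")
                continue
            second = (
                target_table.label(r.second_target) if r.second_target is not None else "NA"
            )
            second_score = r.second_score if r.second_target is not None else "NA"
            out.write(
                f"{r.read_id},{r.length},{_fmt6(r.gamma)},"
                f"{target_table.label(r.best_target)},{r.best_score},"
                f"{second},{second_score},{_fmt6(r.confidence)}\n"
            )


def write_extended_results(
    results: Sequence[ReadResult], target_table: TargetTable, path: str | Path
) -> None:
    """Write the all-scores table: one hit column per target, zeros included.

    Requires results produced with retained score lists
    (``classify(..., keep_scores=True)``).
    """
    path = Path(path)
    n = target_table.n_targets
    with open(path, "wt") as out:
        out.write("Object_ID," + ",".join(target_table.labels) + "\n")
        for r in results:
            if r.scores is None:
                raise ValueError(
                    f"read {r.read_id!r} has no retained score list; "
                    "run classification with keep_scores=True"
                )
            row = [0] * n
            for tid, h in r.scores.pairs:
                row[tid] = h
            out.write(r.read_id + "," + ",".join(map(str, row)) + "\n")
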