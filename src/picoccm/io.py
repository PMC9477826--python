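"""Readers and writers for the plain-text formats the pipeline exchanges.

Sequence IO is delegated to Biopython; matrices travel as tab-delimited UTF-8
TSV with row and column labels ('.' decimal). Parse failures raise
:class:`ParseError` carrying the best available location information.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ParseError",
    "InputError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_sequences",
    "read_matrix",
    "write_matrix",
]


class InputError(ValueError):
    """A precondition on user input was violated."""


class ParseError(InputError):
    """A file could not be parsed; message names the offending location."""


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(record_id, uppercase sequence), ...]``."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}")
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"empty or non-FASTA file: {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTQ into ``[(read_id, uppercase sequence, quality), ...]``.

    Truncated or malformed records raise :class:`ParseError` naming the
    approximate line (FASTQ records are 4 lines each).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}")
    records: list[tuple[str, str, str]] = []
    try:
        with open(path) as fh:
            for title, seq, qual in FastqGeneralIterator(fh):
                records.append((title.split()[0], seq.upper(), qual))
    except ValueError as exc:
        line = len(records) * 4 + 1
        raise ParseError(f"{path}: malformed FASTQ record near line {line}: {exc}") from exc
    if not records:
        raise InputError(f"empty or non-FASTQ file: {path}")
    return records


def write_fastq(path: str | Path, records: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    """Write reads as FASTQ with a constant quality character."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_sequences(path: str | Path, format: str = "fasta") -> list[tuple[str, str]]:
    """Read sequence records, preserving order and identifiers.

    FASTQ qualities are parsed for validation but dropped (downstream stages
    are quality-agnostic).
    """
    if format == "fasta":
        return read_fasta(path)
    if format == "fastq":
        return [(rid, seq) for rid, seq, _ in read_fastq(path)]
    raise InputError(f"unknown sequence format: {format!r}")


def _iter_reads(path: str | Path) -> Iterator[tuple[str, str]]:
    path = Path(path)
    fmt = "fastq" if path.suffix in {".fastq", ".fq"} else "fasta"
    return iter(read_sequences(path, fmt))


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labeled rectangular TSV matrix with numeric cells.

    Raises :class:`ParseError` on ragged rows, duplicate labels or
    non-numeric cells, naming the offending label or cell.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: ragged or malformed TSV: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate row label {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"{path}: duplicate column label {dup!r}")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ParseError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        df[col] = converted
    if df.isna().any().any():
        raise ParseError(f"{path}: missing cells")
    return df


def write_matrix(path: str | Path, df: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")
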