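"""Plain-text sequence and table I/O shared across the pipeline.

FASTA/FASTQ handling is deliberately thin wrappers over Biopython so the
formats stay standard; tables are pandas round-trips with a ``#``-prefixed
schema header line.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FastqRecord = tuple[str, str, str]  # (id, sequence, quality string)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path | io.TextIOBase) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, path, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def fasta_bytes(records: Iterable[tuple[str, str]]) -> bytes:
    buf = io.StringIO()
    write_fasta(records, buf)
    return buf.getvalue().encode()


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[FastqRecord]:
    """Parse FASTQ; malformed records raise with the 1-based record number."""
    out: list[FastqRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise ValueError(
            f"malformed FASTQ {path}: truncated record {len(lines) // 4 + 1}"
        )
    for i in range(0, len(lines), 4):
        recno = i // 4 + 1
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@") or not plus.startswith("+"):
            raise ValueError(f"malformed FASTQ {path}: record {recno}")
        if len(seq) != len(qual):
            raise ValueError(
                f"malformed FASTQ {path}: record {recno} sequence/quality length mismatch"
            )
        out.append((head[1:].split()[0], seq.upper(), qual))
    return out


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[tuple[FastqRecord, FastqRecord]]:
    r1, r2 = read_fastq(path1), read_fastq(path2)
    if len(r1) != len(r2):
        raise ValueError(f"paired FASTQ record counts differ: {len(r1)} vs {len(r2)}")
    return list(zip(r1, r2))


def phred_to_scores(qual: str, offset: int = 33) -> list[int]:
    return [ord(c) - offset for c in qual]


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None, index: bool = False) -> None:
    """TSV writer with a leading ``#`` schema comment declaring the columns."""
    with open(path, "w") as fh:
        cols = list(df.index.names) * index + list(df.columns) if index else list(df.columns)
        fh.write("# columns: " + "\t".join(str(c) for c in cols) + "\n")
        if schema:
            fh.write(f"# {schema}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def iter_windows(seq: str, size: int) -> Iterator[str]:
    for i in range(len(seq) - size + 1):
        yield seq[i : i + size]
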