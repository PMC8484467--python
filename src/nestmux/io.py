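"""Thin FASTQ I/O helpers (Phred+33, gzip-transparent)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

FastqRecord = tuple[str, str, str]  # (id line without '@', sequence, quality)


def _open(path: str | Path, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Yield (title, sequence, quality) from a FASTQ file, .gz transparent."""
    with _open(path, "r") as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> int:
    """Write records to FASTQ; returns the number written."""
    n = 0
    with _open(path, "w") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper()
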