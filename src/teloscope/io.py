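"""Small format helpers shared across the pipeline.

FASTA/FASTQ go through Biopython; everything here is gzip-transparent
(paths ending in ``.gz`` are opened through :mod:`gzip`).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "open_text",
    "read_fasta",
    "write_fasta",
    "iter_fastq",
    "write_fastq",
    "iter_reads",
]


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ordered ``{id: sequence}`` mapping."""
    with open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = (SeqRecord(Seq(s), id=name, description="") for name, s in items)
    with open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(id, sequence)`` pairs from a FASTQ file."""
    with open_text(path) as fh:
        for title, seq, _qual in SeqIO.QualityIO.FastqGeneralIterator(fh):
            yield title.split()[0], seq.upper()


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I") -> int:
    """Write ``(id, sequence)`` pairs as 4-line FASTQ with constant qualities.

    Returns the number of records written.
    """
    n = 0
    with open_text(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")
            n += 1
    return n


def iter_reads(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(id, sequence)`` from FASTA or FASTQ, sniffing the format."""
    with open_text(path) as fh:
        first = fh.read(1)
    if first == ">":
        with open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                yield rec.id, str(rec.seq).upper()
    else:
        yield from iter_fastq(path)
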