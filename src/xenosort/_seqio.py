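"""Light wrappers around FASTA/FASTQ reading and writing.

FASTA parsing goes through Biopython; FASTQ records are plain 4-line blocks
(constant qualities, ``/1``/``/2`` mate suffixes) so reading and writing stay
symmetric with what the simulator emits. Gzipped inputs are accepted anywhere
a path is taken.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

FASTA_WRAP = 60


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Return ``[(record_id, uppercase_sequence), ...]`` from a FASTA file."""
    with _open_text(path) as handle:
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]
    if not records:
        raise ValueError(f"empty FASTA: {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with _open_text(path, "wt") as out:
        for name, seq in records:
            out.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WRAP):
                out.write(seq[i : i + FASTA_WRAP] + "\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(title, sequence, quality)`` tuples; gzip transparent."""
    with _open_text(path) as handle:
        yield from FastqGeneralIterator(handle)


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with _open_text(path, "wt") as out:
        for title, seq, qual in records:
            out.write(f"@{title}\n{seq}\n+\n{qual}\n")


def strip_mate_suffix(title: str) -> str:
    """Pair id of a read title: first whitespace token, minus a ``/1``/``/2`` tail."""
    token = title.split()[0]
    if token.endswith("/1") or token.endswith("/2"):
        return token[:-2]
    return token
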