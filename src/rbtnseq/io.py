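"""Shared format helpers: FASTQ/FASTA/GFF3 reading and writing, gzip handling."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

__all__ = [
    "open_maybe_gzip",
    "parse_fastq",
    "reverse_complement",
    "write_fasta",
    "write_gff3",
    "FastqWriter",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def parse_fastq(handle: IO[str]) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) triples; sequences upper-cased."""
    for title, seq, qual in FastqGeneralIterator(handle):
        yield title, seq.upper(), qual


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def write_gff3(
    genes: Iterable, path: str | Path, feature_type: str = "gene"
) -> None:
    """Write Gene records as a minimal GFF3 (ID and locus_tag both set)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.id};locus_tag={g.id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.replicon}\trbtnseq\t{feature_type}\t{g.start}\t{g.end}"
                f"\t.\t{g.strand}\t.\t{attrs}\n"
            )


class FastqWriter:
    """Minimal FASTQ writer (constant quality); supports .gz paths."""

    def __init__(self, path: str | Path, quality_char: str = "I"):
        self._fh = open_maybe_gzip(path, "wt")
        self._q = quality_char
        self._n = 0

    def write(self, name: str, seq: str) -> None:
        self._fh.write(f"@{name}\n{seq}\n+\n{self._q * len(seq)}\n")
        self._n += 1

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "FastqWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
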