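"""Reference genome I/O and coordinate utilities.

All internal coordinates are 0-based, half-open. VCF positions (1-based)
are converted at the I/O boundary, and the report writers emit 1-based
inclusive spans to match the convention of published variant tables.
Assembly gaps (N) are preserved verbatim; they are never imputed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterator

from Bio import SeqIO

__all__ = [
    "Genome",
    "GenomicInterval",
    "load_fasta",
    "write_fasta",
    "fetch",
    "reverse_complement",
    "FastaNotFoundError",
    "EmptyFastaError",
    "DuplicateSequenceNameError",
    "IllegalBaseError",
    "UnknownChromosomeError",
    "IntervalOutOfBoundsError",
]

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaNotFoundError(FileNotFoundError):
    """The FASTA path does not exist."""


class EmptyFastaError(ValueError):
    """The FASTA file contains no sequence records."""


class DuplicateSequenceNameError(ValueError):
    """Two FASTA records share the same name."""


class IllegalBaseError(ValueError):
    """A sequence contains a character outside {A, C, G, T, N}."""


class UnknownChromosomeError(KeyError):
    """An interval references a chromosome absent from the genome."""


class IntervalOutOfBoundsError(ValueError):
    """An interval does not satisfy 0 <= start < end <= chromosome length."""


def reverse_complement(s: str) -> str:
    """Watson-Crick reverse complement; N maps to N.

    Raises :class:`IllegalBaseError` on characters outside {A,C,G,T,N}.
    """
    if not VALID_BASES.issuperset(s):
        bad = sorted(set(s) - VALID_BASES)
        raise IllegalBaseError(f"illegal nucleotide characters: {bad}")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic span, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise IntervalOutOfBoundsError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def padded(self, pad: int) -> "GenomicInterval":
        """Return the interval widened by ``pad`` on each side (clipped at 0)."""
        return GenomicInterval(self.chrom, max(0, self.start - pad), self.end + pad, self.strand)


@dataclass
class Genome:
    """An in-memory reference genome: chromosome name -> uppercase sequence."""

    sequences: Dict[str, str] = field(default_factory=dict)

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)


def load_fasta(path: str | os.PathLike) -> Genome:
    """Read a (plain or bgzipped) FASTA file into a :class:`Genome`.

    Lowercase bases are uppercased. Characters outside {A,C,G,T,N} raise
    :class:`IllegalBaseError`; duplicate record names raise
    :class:`DuplicateSequenceNameError`; a missing or record-less file raises
    :class:`FastaNotFoundError` / :class:`EmptyFastaError`.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FastaNotFoundError(path)
    if str(path).endswith(".gz"):
        import gzip

        handle = gzip.open(path, "rt")
    else:
        handle = open(path)
    sequences: Dict[str, str] = {}
    with handle:
        for record in SeqIO.parse(handle, "fasta"):
            if not record.id:
                raise DuplicateSequenceNameError("empty record name")
            if record.id in sequences:
                raise DuplicateSequenceNameError(f"duplicate record name: {record.id}")
            seq = str(record.seq).upper()
            if not VALID_BASES.issuperset(seq):
                bad = sorted(set(seq) - VALID_BASES)
                raise IllegalBaseError(f"record {record.id}: illegal characters {bad}")
            sequences[record.id] = seq
    if not sequences:
        raise EmptyFastaError(f"no FASTA records in {path}")
    return Genome(sequences)


def write_fasta(genome: Genome, path: str | os.PathLike, width: int = 70) -> None:
    """Write a Genome to a plain FASTA file (fixed line width, stable order)."""
    with open(path, "w") as out:
        for name, seq in genome.sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def fetch(genome: Genome, iv: GenomicInterval) -> str:
    """Return the sequence of ``iv``; minus-strand intervals are reverse-complemented."""
    if iv.chrom not in genome:
        raise UnknownChromosomeError(iv.chrom)
    seq = genome.sequences[iv.chrom]
    if iv.end > len(seq):
        raise IntervalOutOfBoundsError(
            f"interval [{iv.start}, {iv.end}) exceeds {iv.chrom} length {len(seq)}"
        )
    sub = seq[iv.start : iv.end]
    return reverse_complement(sub) if iv.strand == "-" else sub
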