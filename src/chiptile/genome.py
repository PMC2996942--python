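"""Circular genome sequences and coordinate arithmetic.

The analysis substrate is a circular bacterial chromosome. All internal
coordinates are 0-based; file outputs use 1-based inclusive positions except
BED/bedGraph, which follow their 0-based half-open standards.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = frozenset("ACGT")

_RC = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase ACGT string."""
    return seq.translate(_RC)[::-1]


def circular_distance(a, b, length: int):
    """Shortest distance between positions on a circle of the given length.

    Accepts scalars or numpy arrays; broadcasting follows numpy rules.
    """
    d = np.abs(np.asarray(a) - np.asarray(b)) % length
    return np.minimum(d, length - d)


@dataclass
class GenomeSequence:
    """A (usually circular) nucleotide sequence with duplication annotations.

    Parameters
    ----------
    name
        Sequence label, used as the chromosome name in all outputs.
    sequence
        Uppercase string over ``{A, C, G, T}``.
    circular
        Whether coordinates wrap at the origin. Bacterial chromosomes are
        circular; the default reflects that.
    duplications
        ``(source_start, dest_start, length)`` triples marking segments that
        occur verbatim at two loci. Probes falling inside such segments
        hybridize material from every copy ("non-unique" probes).
    """

    name: str
    sequence: str
    circular: bool = True
    duplications: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("genome sequence must be non-empty")
        if not _VALID_BASES.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - _VALID_BASES)
            raise ValueError(f"genome contains characters outside ACGT: {bad}")
        n = len(self.sequence)
        for src, dst, ln in self.duplications:
            if ln <= 0:
                raise ValueError("duplication length must be positive")
            if not (0 <= src < n and 0 <= dst < n):
                raise ValueError("duplication start outside genome")
            if self.fetch(src, ln) != self.fetch(dst, ln):
                raise ValueError(
                    f"duplication ({src}, {dst}, {ln}) is not an exact copy"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, length: int) -> str:
        """Substring of the given length starting at ``start``, wrapping at
        the origin when the genome is circular."""
        n = len(self.sequence)
        if length > n:
            raise ValueError("requested substring longer than genome")
        start %= n
        end = start + length
        if end <= n:
            return self.sequence[start:end]
        if not self.circular:
            raise ValueError("substring runs off the end of a linear genome")
        return self.sequence[start:] + self.sequence[: end - n]

    # -- FASTA round trip ---------------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        """Write the genome as FASTA; circularity and duplication triples are
        encoded in the record description so a round trip preserves them."""
        parts = ["circular" if self.circular else "linear"]
        if self.duplications:
            dups = ",".join(f"{s}:{d}:{l}" for s, d, l in self.duplications)
            parts.append(f"duplications={dups}")
        record = SeqRecord(Seq(self.sequence), id=self.name, description=" ".join(parts))
        SeqIO.write([record], str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        record = next(SeqIO.parse(str(path), "fasta"))
        desc = record.description.split()
        circular = "linear" not in desc
        duplications: list[tuple[int, int, int]] = []
        for token in desc:
            if token.startswith("duplications="):
                for triple in token.split("=", 1)[1].split(","):
                    s, d, l = (int(x) for x in triple.split(":"))
                    duplications.append((s, d, l))
        return cls(
            name=record.id,
            sequence=str(record.seq).upper(),
            circular=circular,
            duplications=duplications,
        )
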