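"""Shared domain records for piRNA cluster analysis.

Coordinates are 0-based half-open throughout the package; BED files on disk
use the same convention, SAM input is converted on read.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentRecord:
    """Strand-aware genomic interval of one mapped read."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval for {self.read_id}: [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.sequence is not None and len(self.sequence) != self.end - self.start:
            raise ValueError(f"sequence length mismatch for {self.read_id}")

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the read's 5' end."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class PiRNACluster:
    cluster_id: str
    chrom: str
    start: int
    end: int
    klass: str  # "genic" or "intergenic"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty cluster {self.cluster_id}")
        if self.klass not in ("genic", "intergenic"):
            raise ValueError(f"bad cluster class {self.klass!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """Gene with its transcript span and all annotated TSS positions."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    tss_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.tss_positions:
            raise ValueError(f"gene {self.gene_id} has no TSS")


@dataclass(frozen=True)
class RepeatElement:
    chrom: str
    start: int
    end: int
    strand: str
    family: str  # SINE / LINE / LTR / other
    consensus_length: int
    name: str = ""

    @property
    def element_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TargetSignatureSite:
    """Genomic locus supported by a seed-perfect antisense guide and at least
    one overlapping exact-match sense read on the opposite strand."""

    chrom: str
    start: int
    end: int
    guide_id: str
    guide_strand: str
    sense_ids: tuple[str, ...]
    mismatch_positions: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.sense_ids:
            raise ValueError("signature site requires >=1 supporting sense read")


def intervals_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """>=1 base of shared footprint between two half-open intervals."""
    return a_start < b_end and b_start < a_end
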