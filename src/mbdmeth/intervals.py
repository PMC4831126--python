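"""Genomic interval primitives.

All coordinates in this package are 0-based, half-open ``[start, end)``,
matching BED conventions on disk.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A contiguous stretch of one contig: ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different contigs)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_len(other) > 0

    def union_span(self, other: "GenomicInterval") -> "GenomicInterval":
        """Smallest interval covering both (contigs must agree)."""
        if self.chrom != other.chrom:
            raise ValueError("cannot span intervals on different contigs")
        return GenomicInterval(
            self.chrom, min(self.start, other.start), max(self.end, other.end)
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end
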