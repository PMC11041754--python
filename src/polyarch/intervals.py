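"""Genomic interval primitives.

All coordinates in this package are 0-based, half-open ``[start, end)``;
conversions to 1-based conventions (GFF3) happen only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional


@dataclass(frozen=True)
class GenomicInterval:
    """A span on a named chromosome, 0-based half-open.

    ``name``, ``score`` and ``strand`` are optional BED-style annotations;
    ``score`` is free-form (dosage class, hit density, ...).
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        """Overlapping span, or None if disjoint; annotations are dropped."""
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    def with_name(self, name: str) -> "GenomicInterval":
        return replace(self, name=name)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def sort_key(iv: GenomicInterval) -> tuple:
    return (iv.chrom, iv.start, iv.end)


def sorted_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(ivs, key=sort_key)


def is_sorted(ivs: Iterable[GenomicInterval]) -> bool:
    prev = None
    for iv in ivs:
        if prev is not None and sort_key(iv) < sort_key(prev):
            return False
        prev = iv
    return True


def total_length(ivs: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in ivs)


def tile(chrom: str, length: int, window: int) -> list[GenomicInterval]:
    """Non-overlapping tiling windows; the last window may be short."""
    if window <= 0:
        raise ValueError("window size must be positive")
    return [
        GenomicInterval(chrom, s, min(s + window, length))
        for s in range(0, length, window)
    ]
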