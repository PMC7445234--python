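"""Genomic interval primitives.

All coordinates in this package are 0-based half-open (BED convention).
Promoter annotations arriving as 1-based TSS positions are converted on
read, so no other module ever sees a 1-based coordinate.

Overlap throughout the pipeline means ``overlap_length >= 1`` base and is
strand-blind: histone, accessibility and TF ChIP peaks are unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(
                f"negative start coordinate {self.start} on {self.chrom}"
            )
        if self.end <= self.start:
            raise ValueError(
                f"zero- or negative-width interval "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def intersect(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        """Intersection with ``other``, or None when disjoint.

        The result is unstranded: intersections are only used for
        peak-truncation and site logic, which is strand-blind.
        """
        if self.chrom != other.chrom:
            return None
        start = max(self.start, other.start)
        end = min(self.end, other.end)
        if end <= start:
            return None
        return GenomicInterval(self.chrom, start, end)


@dataclass(frozen=True, order=True)
class Peak:
    """A called peak: an interval plus an optional name and signal.

    For TF ChIP-seq peaks ``name`` carries the TF symbol; for histone /
    accessibility peaks it is free-form. ``signal`` (narrowPeak
    signalValue) is preserved but unused by the algorithm.
    """

    interval: GenomicInterval
    name: str = ""
    signal: Optional[float] = field(default=None, compare=False)

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases between two intervals; 0 across chromosomes.

    Half-open abutment ([100,200) vs [200,300)) counts as zero overlap.
    Strand is ignored.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Symmetric overlap stringency: min over both intervals of the
    fraction of its bases shared with the other.

    Equals ``overlap_length(a, b) / max(width(a), width(b))`` rewritten as
    the min of the two per-interval fractions; 1.0 only for identical
    intervals, 0.0 when disjoint.
    """
    ov = overlap_length(a, b)
    if ov == 0:
        return 0.0
    return min(ov / a.width, ov / b.width)


def overlaps_any(iv: GenomicInterval, peaks) -> bool:
    """True when ``iv`` shares >=1 base with at least one peak."""
    return any(overlap_length(iv, p.interval) >= 1 for p in peaks)
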