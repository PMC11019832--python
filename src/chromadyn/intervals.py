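"""Genomic interval primitives and interval algebra.

All coordinates are 0-based, half-open (BED convention). Formats that use
1-based inclusive coordinates (GTF) are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

VALID_STRANDS = ("+", "-", ".")


class IntervalError(ValueError):
    """Raised when an interval violates the coordinate invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name; must be non-empty.
    start, end : int
        0-based half-open coordinates with ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    name : str, optional
        Free-form label (e.g. a peak or region id).
    score : float, optional
        Numeric score carried through BED/narrowPeak round trips.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntervalError(f"empty chromosome name in {self!r}")
        if self.start < 0:
            raise IntervalError(
                f"negative start coordinate in {self.chrom}:{self.start}-{self.end}"
            )
        if self.start >= self.end:
            raise IntervalError(
                f"start >= end in {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise IntervalError(
                f"strand {self.strand!r} not in {VALID_STRANDS} "
                f"({self.chrom}:{self.start}-{self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Floor of the interval midpoint."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two half-open intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_position(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort by (chrom, start, end); a stable total order for writers."""
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose inter-interval distance is <= ``gap``.

    Two intervals on the same chromosome merge when ``start2 - end1 <= gap``
    under the half-open convention, i.e. touching or overlapping intervals
    always merge and a non-negative gap additionally bridges small
    separations. Merging is transitive. Strand is ignored; merged regions
    are emitted unstranded and unnamed.

    Parameters
    ----------
    intervals : iterable of GenomicInterval
    gap : int
        Maximum inter-interval distance (in bases) that still merges;
        must be >= 0.

    Returns
    -------
    list of GenomicInterval, sorted, pairwise separated by more than
    ``gap`` bases. Idempotent: merging the output again is a no-op.
    """
    if gap < 0:
        raise ValueError(f"gap must be non-negative, got {gap}")
    ivs = sort_intervals(intervals)
    if not ivs:
        return []
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = ivs[0].chrom, ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        if iv.chrom == cur_chrom and iv.start - cur_end <= gap:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return merged
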