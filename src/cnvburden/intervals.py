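"""Genomic interval primitives.

Every coordinate in this package is 0-based, half-open (``[start, end)``),
the BED convention.  Formats that use other conventions (the CNVnator text
dialect is 1-based fully closed) are converted exactly once, at parse time.
Chromosome names are opaque tokens: ``"chr1"`` and ``"1"`` are different
chromosomes, and intervals on different chromosomes never overlap.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored half-open span ``[start, end)`` in base pairs."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Number of shared base pairs; 0 on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_len(other) > 0

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Reciprocal overlap fraction: ``min(ov/len(a), ov/len(b))`` in [0, 1].

    The standard criterion for calling two structural-variant calls "the
    same event": both intervals must share the given fraction of their own
    length, so a small call never merges into an unrelated giant one.
    Returns 0.0 for disjoint intervals or different chromosomes.
    """
    ov = a.overlap_len(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of possibly-overlapping intervals, sorted, per chromosome.

    Touching intervals (``a.end == b.start``) are coalesced.
    """
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


class IntervalUnion:
    """A pre-merged interval track supporting covered-length queries.

    Used for repeat-track coverage accounting: the input track may contain
    mutually overlapping intervals; they are unioned on construction so each
    base pair counts once.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for iv in merge_intervals(intervals):
            starts, ends = self._by_chrom.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)

    def covered_length(self, query: GenomicInterval) -> int:
        """Base pairs of ``query`` covered by the union of the track."""
        if query.chrom not in self._by_chrom:
            return 0
        starts, ends = self._by_chrom[query.chrom]
        lo = bisect_right(ends, query.start)
        hi = bisect_left(starts, query.end)
        covered = 0
        for i in range(lo, hi):
            covered += max(0, min(ends[i], query.end) - max(starts[i], query.start))
        return covered

    def intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom in sorted(self._by_chrom):
            starts, ends = self._by_chrom[chrom]
            out.extend(GenomicInterval(chrom, s, e) for s, e in zip(starts, ends))
        return out


def intervals_overlap_any(
    query: GenomicInterval, others: Sequence[GenomicInterval]
) -> bool:
    """True if ``query`` shares >= 1 bp with any interval in ``others``."""
    return any(query.overlaps(o) for o in others)
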