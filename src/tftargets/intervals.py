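"""Genomic primitives: intervals, peaks, gene models, and interval arithmetic.

All coordinates are 0-based, half-open (BED convention). Two intervals
overlap iff they share at least one base, so abutting intervals such as
[0, 10) and [10, 20) do *not* overlap but are merged by
:func:`merge_intervals`.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic region ``chrom:[start, end)``.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Peak:
    """A called binding-site peak, labelled with its sample of origin.

    ``summit`` is an absolute base position inside the peak (not an offset)
    when available, e.g. from narrowPeak column 10.
    """

    interval: GenomicInterval
    cell_line: Optional[str] = None
    replicate: Optional[str] = None
    summit: Optional[int] = None
    score: Optional[float] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"{self.interval.chrom}:[{self.interval.start},{self.interval.end})"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    def reference_point(self) -> int:
        """Summit when called, otherwise the interval midpoint."""
        return self.summit if self.summit is not None else self.interval.midpoint


@dataclass
class GeneModel:
    """A gene with a strand-aware transcription start site (TSS).

    The TSS is ``start`` for a +strand gene and ``end - 1`` (the last
    covered base) for a -strand gene.
    """

    gene_id: str
    interval: GenomicInterval
    symbol: Optional[str] = None

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def tss(self) -> int:
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping *and abutting* intervals into a sorted disjoint set.

    Strand information is dropped (merged regions are unstranded); the base
    union of the output equals the base union of the input.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


class IntervalSet:
    """Merged, per-chromosome indexed interval collection for overlap queries.

    Construct once, query many times; used for blacklist filtering and
    enhancer overlap where thousands of lookups hit the same region set.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for iv in merge_intervals(intervals):
            starts, ends = self._by_chrom.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)

    def overlaps(self, query: GenomicInterval) -> bool:
        entry = self._by_chrom.get(query.chrom)
        if entry is None:
            return False
        starts, ends = entry
        # candidate: last merged interval starting before query.end
        i = bisect_right(starts, query.end - 1) - 1
        return i >= 0 and ends[i] > query.start

    def __len__(self) -> int:
        return sum(len(starts) for starts, _ in self._by_chrom.values())


def overlaps_any(query: GenomicInterval, regions: Iterable[GenomicInterval]) -> bool:
    """True iff ``query`` shares at least one base with at least one region.

    ``regions`` may be unmerged. For repeated queries against the same set,
    build an :class:`IntervalSet` once instead.
    """
    return IntervalSet(regions).overlaps(query)


def remove_blacklisted(
    peaks: Sequence[Peak], blacklist: Iterable[GenomicInterval]
) -> list[Peak]:
    """Drop every peak sharing >=1 base with a blacklist region, keeping order."""
    index = IntervalSet(blacklist)
    return [p for p in peaks if not index.overlaps(p.interval)]
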