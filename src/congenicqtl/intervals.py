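"""Interval algebra on donor regions.

Congenic donor fragments are contiguous runs of heterozygous (129/B6)
markers on one chromosome. All coordinates are 1-based inclusive base
pairs (GRCm38 convention), so the interval [5, 5] has length 1 bp and
[1, 10] and [11, 20] are adjacent (their union is [1, 20]).

The algebra here (union, intersection, symmetric difference, lengths,
atomic bins) is the substrate for the minimum-spanning-tree distance
between strains and for the multi-QTL consistency search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence


@dataclass(frozen=True)
class Interval:
    """A 1-based inclusive genomic interval on a single chromosome."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"interval end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        """Inclusive length in bp ([5, 5] has length 1)."""
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def __str__(self) -> str:
        return f"[{self.start}, {self.end}]"


class IntervalSet:
    """A canonical set of disjoint, sorted, 1-based inclusive intervals.

    Construction normalizes the input: overlapping or bookended
    (adjacent) intervals are merged, so two IntervalSets covering the
    same base pairs compare equal.
    """

    __slots__ = ("_intervals",)

    def __init__(self, intervals: Iterable[tuple[int, int] | Interval] = ()) -> None:
        pairs = []
        for iv in intervals:
            if isinstance(iv, Interval):
                pairs.append((iv.start, iv.end))
            else:
                start, end = iv
                pairs.append((int(start), int(end)))
        merged: list[list[int]] = []
        for start, end in sorted(pairs):
            if start < 1:
                raise ValueError(f"interval start must be >= 1, got {start}")
            if end < start:
                raise ValueError(f"interval end {end} < start {start}")
            if merged and start <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        self._intervals = tuple(Interval(s, e) for s, e in merged)

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls()

    @property
    def intervals(self) -> tuple[Interval, ...]:
        return self._intervals

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self._intervals)

    def __bool__(self) -> bool:
        return bool(self._intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __hash__(self) -> int:
        return hash(self._intervals)

    def __repr__(self) -> str:
        body = ", ".join(str(iv) for iv in self._intervals)
        return f"IntervalSet({{{body}}})"

    @property
    def total_length(self) -> int:
        """Total inclusive bp covered."""
        return sum(iv.length for iv in self._intervals)

    @property
    def span(self) -> Interval | None:
        """Smallest single interval covering the set (None when empty)."""
        if not self._intervals:
            return None
        return Interval(self._intervals[0].start, self._intervals[-1].end)

    def contains(self, pos: int) -> bool:
        return any(iv.contains(pos) for iv in self._intervals)

    # -- boundary-sweep machinery ------------------------------------
    # Each set is encoded as +1/-1 events at (start) and (end + 1);
    # a linear sweep then evaluates any boolean combination exactly on
    # inclusive integer coordinates without enumerating base pairs.

    def _events(self, tag: int) -> list[tuple[int, int, int]]:
        ev = []
        for iv in self._intervals:
            ev.append((iv.start, tag, +1))
            ev.append((iv.end + 1, tag, -1))
        return ev

    @staticmethod
    def _sweep(a: "IntervalSet", b: "IntervalSet", keep) -> "IntervalSet":
        events = sorted(a._events(0) + b._events(1))
        depth = [0, 0]
        out: list[tuple[int, int]] = []
        open_start: int | None = None
        i = 0
        while i < len(events):
            pos = events[i][0]
            while i < len(events) and events[i][0] == pos:
                _, tag, delta = events[i]
                depth[tag] += delta
                i += 1
            inside = keep(depth[0] > 0, depth[1] > 0)
            if inside and open_start is None:
                open_start = pos
            elif not inside and open_start is not None:
                out.append((open_start, pos - 1))
                open_start = None
        return IntervalSet(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return self._sweep(self, other, lambda x, y: x or y)

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        return self._sweep(self, other, lambda x, y: x and y)

    def difference(self, other: "IntervalSet") -> "IntervalSet":
        return self._sweep(self, other, lambda x, y: x and not y)

    def symmetric_difference(self, other: "IntervalSet") -> "IntervalSet":
        return self._sweep(self, other, lambda x, y: x != y)

    __or__ = union
    __and__ = intersection
    __sub__ = difference
    __xor__ = symmetric_difference


def union(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.union(b)


def intersection(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.intersection(b)


def symmetric_difference(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.symmetric_difference(b)


def total_length(a: IntervalSet) -> int:
    return a.total_length


def gap_bp(left_end: int, right_start: int) -> int:
    """Coordinate gap between two loci, ``right_start - left_end``.

    This is the conventional "distance between interval boundaries"
    (e.g., between the distal end of one QTL and the proximal end of
    the next); it exceeds the count of strictly-between base pairs
    by one.
    """
    if right_start < left_end:
        raise ValueError("right_start must be >= left_end")
    return right_start - left_end


def atomic_bins(regions: Sequence[IntervalSet]) -> list[Interval]:
    """Partition the union of ``regions`` into atomic intervals.

    The returned bins are the finest partition such that every input
    region is an exact union of bins: bin boundaries are the distinct
    interval endpoints across all regions. Bins are the resolution
    limit of any breakpoint-based QTL inference — no comparison of
    donor regions can localize an effect below the bin level.
    """
    cuts: set[int] = set()
    covered = IntervalSet()
    for region in regions:
        covered = covered.union(region)
        for iv in region:
            cuts.add(iv.start)
            cuts.add(iv.end + 1)
    bins: list[Interval] = []
    for cov in covered:
        inner = sorted(c for c in cuts if cov.start < c <= cov.end)
        lo = cov.start
        for c in inner:
            bins.append(Interval(lo, c - 1))
            lo = c
        bins.append(Interval(lo, cov.end))
    return bins
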