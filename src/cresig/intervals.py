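"""Genomic interval primitives and interval-set algebra.

All coordinates are 0-based, half-open ``[start, end)`` — the BED
convention.  Two intervals that merely share a boundary (``[0,10)`` and
``[10,20)``) therefore do not overlap, but :func:`merge` coalesces such
book-ended spans into one, matching the usual ``bedtools merge``
behaviour.

The algebra here is deliberately simple — sorted span lists per
chromosome and linear sweeps — because every downstream stage (CRE
calling, specificity filtering, domain assignment, Monte-Carlo nulls)
reduces to these four primitives and their semantics must be exact:

* :func:`merge` — coalesce overlapping/book-ended spans,
* :func:`intersect_regions` — basepair-level intersection,
* :func:`overlaps_any` — whole query intervals sharing at least
  ``min_overlap_bp`` with some single reference interval,
* :func:`subtract_any` — the zero-overlap complement of the above.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Iterator


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor midpoint, used for TSS-distance reporting."""
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared basepairs (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalSet:
    """An immutable, sorted collection of :class:`GenomicInterval`.

    Intervals are stored per chromosome as sorted ``(start, end)`` span
    lists.  ``merged`` is True only for sets produced by :meth:`merge`
    (pairwise disjoint, non-book-ended, sorted).
    """

    __slots__ = ("_by_chrom", "merged")

    def __init__(self, intervals: Iterable[GenomicInterval] = (), *, _merged: bool = False):
        by: dict[str, set[tuple[int, int]]] = {}
        for iv in intervals:
            by.setdefault(iv.chrom, set()).add((iv.start, iv.end))
        # set semantics: duplicate spans collapse; spans kept sorted
        self._by_chrom = {chrom: sorted(spans) for chrom, spans in sorted(by.items())}
        self.merged = _merged

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __bool__(self) -> bool:
        return bool(self._by_chrom)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom, spans in self._by_chrom.items():
            for s, e in spans:
                yield GenomicInterval(chrom, s, e)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._by_chrom == other._by_chrom

    def __hash__(self) -> int:  # frozen-ish; spans never mutate after init
        return hash(tuple((c, tuple(s)) for c, s in self._by_chrom.items()))

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals on {len(self._by_chrom)} chromosomes)"

    # -- accessors ----------------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def spans(self, chrom: str) -> list[tuple[int, int]]:
        return list(self._by_chrom.get(chrom, []))

    def total_bp(self) -> int:
        """Covered basepairs; double-counts overlaps unless merged."""
        return sum(e - s for spans in self._by_chrom.values() for s, e in spans)

    # -- algebra ------------------------------------------------------------

    def merge(self) -> "IntervalSet":
        """Coalesce overlapping and book-ended spans.

        Returns the minimal sorted set covering exactly the same
        basepairs. Idempotent.
        """
        out = IntervalSet.__new__(IntervalSet)
        merged: dict[str, list[tuple[int, int]]] = {}
        for chrom, spans in self._by_chrom.items():
            acc: list[tuple[int, int]] = []
            cur_s, cur_e = spans[0]
            for s, e in spans[1:]:
                if s <= cur_e:  # overlap or book-ended
                    cur_e = max(cur_e, e)
                else:
                    acc.append((cur_s, cur_e))
                    cur_s, cur_e = s, e
            acc.append((cur_s, cur_e))
            merged[chrom] = acc
        out._by_chrom = merged
        out.merged = True
        return out

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Exact basepair intersection, returned merged."""
        a, b = self.merge(), other.merge()
        out = IntervalSet.__new__(IntervalSet)
        result: dict[str, list[tuple[int, int]]] = {}
        for chrom in a._by_chrom:
            if chrom not in b._by_chrom:
                continue
            sa, sb = a._by_chrom[chrom], b._by_chrom[chrom]
            i = j = 0
            acc: list[tuple[int, int]] = []
            while i < len(sa) and j < len(sb):
                s = max(sa[i][0], sb[j][0])
                e = min(sa[i][1], sb[j][1])
                if s < e:
                    acc.append((s, e))
                if sa[i][1] < sb[j][1]:
                    i += 1
                else:
                    j += 1
            if acc:
                result[chrom] = acc
        out._by_chrom = dict(sorted(result.items()))
        out.merged = True
        return out

    def overlaps_any(self, reference: "IntervalSet", min_overlap_bp: int = 1) -> "IntervalSet":
        """Whole query intervals sharing >= ``min_overlap_bp`` with any
        single reference interval.

        The threshold applies per reference interval (not to summed
        overlap), so the reference is deliberately not merged first.
        """
        if min_overlap_bp < 1:
            raise ValueError("min_overlap_bp must be >= 1")
        kept: list[GenomicInterval] = []
        for chrom, spans in self._by_chrom.items():
            ref = reference._by_chrom.get(chrom)
            if not ref:
                continue
            ref_starts = [r[0] for r in ref]
            ref_maxlen = max(r[1] - r[0] for r in ref)
            for s, e in spans:
                # first reference whose start could still overlap [s, e)
                j = bisect_left(ref_starts, s - ref_maxlen)
                hit = False
                for rs, re in ref[max(0, j):]:
                    if rs >= e:
                        break
                    if min(e, re) - max(s, rs) >= min_overlap_bp:
                        hit = True
                        break
                if hit:
                    kept.append(GenomicInterval(chrom, s, e))
        return IntervalSet(kept)

    def subtract_any(self, reference: "IntervalSet", min_overlap_bp: int = 1) -> "IntervalSet":
        """Whole query intervals with overlap below the threshold against
        every reference interval.  Partition property:
        ``overlaps_any | subtract_any == query`` disjointly.
        """
        hits = {(iv.chrom, iv.start, iv.end) for iv in self.overlaps_any(reference, min_overlap_bp)}
        return IntervalSet(iv for iv in self if (iv.chrom, iv.start, iv.end) not in hits)


# -- module-level functional aliases (operation names used by the CLI) ------


def merge(intervals: IntervalSet | Iterable[GenomicInterval]) -> IntervalSet:
    if not isinstance(intervals, IntervalSet):
        intervals = IntervalSet(intervals)
    return intervals.merge()


def intersect_regions(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.intersect(b)


def overlaps_any(query: IntervalSet, reference: IntervalSet, min_overlap_bp: int = 1) -> IntervalSet:
    return query.overlaps_any(reference, min_overlap_bp)


def subtract_any(query: IntervalSet, reference: IntervalSet, min_overlap_bp: int = 1) -> IntervalSet:
    return query.subtract_any(reference, min_overlap_bp)
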