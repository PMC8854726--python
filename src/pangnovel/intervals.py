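"""Genomic interval algebra on 0-based half-open coordinates.

Implements the merge / subtract / overlap operations the pipeline needs
(the behaviour of ``bedtools merge``, ``bedtools subtract -A -f`` and
``bedtools intersect``) on plain Python structures, with numpy-backed
indexes for bulk overlap queries.  All coordinates are 0-based half-open
throughout the package; 1-based inputs (VCF) are converted at the I/O
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Coalesce overlapping *and adjacent* intervals into a sorted union.

    Adjacent means end == next start; ``bedtools merge`` with default
    distance 0 behaves the same way.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if s > e:
            raise ValueError(f"invalid interval ({s}, {e}): start > end")
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def subtract_intervals(intervals: Iterable[Interval], removals: Iterable[Interval]) -> list[Interval]:
    """Per-base set difference ``intervals - removals`` (both merged first)."""
    keep = merge_intervals(intervals)
    cut = merge_intervals(removals)
    out: list[Interval] = []
    j = 0
    for s, e in keep:
        cur = s
        while j < len(cut) and cut[j][1] <= cur:
            j += 1
        k = j
        while k < len(cut) and cut[k][0] < e:
            rs, re = cut[k]
            if rs > cur:
                out.append((cur, rs))
            cur = max(cur, re)
            if re >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def overlap_length(interval: Interval, merged: Sequence[Interval]) -> int:
    """Total bp of ``interval`` covered by the union of ``merged``.

    ``merged`` must be sorted and non-overlapping (merge_intervals output).
    """
    s, e = interval
    total = 0
    for ms, me in merged:
        if me <= s:
            continue
        if ms >= e:
            break
        total += min(e, me) - max(s, ms)
    return total


def intervals_overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


@dataclass
class IntervalSet:
    """Per-chromosome, optionally typed, collection of genomic intervals.

    Intervals are stored as (chrom, start, end, type) tuples; ``type`` is
    None for untyped sets.  ``merged()`` returns the coalesced union per
    (chrom, type) key.  Overlap queries run against sorted numpy arrays of
    merged intervals, built lazily and cached.
    """

    records: list[tuple[str, int, int, str | None]] = field(default_factory=list)
    _index: dict | None = field(default=None, repr=False, compare=False)

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple], typed: bool = False
    ) -> "IntervalSet":
        recs = []
        for iv in intervals:
            if typed:
                chrom, s, e, t = iv[:4]
                recs.append((str(chrom), int(s), int(e), str(t)))
            else:
                chrom, s, e = iv[:3]
                recs.append((str(chrom), int(s), int(e), None))
        return cls(recs)

    def add(self, chrom: str, start: int, end: int, svtype: str | None = None) -> None:
        self.records.append((chrom, int(start), int(end), svtype))
        self._index = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, int, int, str | None]]:
        return iter(self.records)

    def chroms(self) -> set[str]:
        return {r[0] for r in self.records}

    def merged(self) -> "IntervalSet":
        """Union per (chrom, type), overlapping/adjacent intervals coalesced."""
        by_key: dict[tuple[str, str | None], list[Interval]] = {}
        for chrom, s, e, t in self.records:
            by_key.setdefault((chrom, t), []).append((s, e))
        out = IntervalSet()
        for (chrom, t) in sorted(by_key, key=lambda k: (k[0], k[1] or "")):
            for s, e in merge_intervals(by_key[(chrom, t)]):
                out.records.append((chrom, s, e, t))
        return out

    def restrict(self, keep_chroms: Iterable[str]) -> "IntervalSet":
        keep = set(keep_chroms)
        return IntervalSet([r for r in self.records if r[0] in keep])

    def untyped(self) -> "IntervalSet":
        """Drop type labels (pooled region set)."""
        return IntervalSet([(c, s, e, None) for c, s, e, _ in self.records])

    def _build_index(self) -> dict:
        if self._index is None:
            idx: dict[tuple[str, str | None], tuple[np.ndarray, np.ndarray]] = {}
            by_key: dict[tuple[str, str | None], list[Interval]] = {}
            for chrom, s, e, t in self.records:
                by_key.setdefault((chrom, t), []).append((s, e))
            for key, ivs in by_key.items():
                m = merge_intervals(ivs)
                idx[key] = (
                    np.array([s for s, _ in m], dtype=np.int64),
                    np.array([e for _, e in m], dtype=np.int64),
                )
            self._index = idx
        return self._index

    def overlaps(self, chrom: str, start: int, end: int, svtype: str | None = None) -> bool:
        """True iff [start, end) overlaps ≥1 bp of an interval with this type.

        With ``svtype=None`` on a typed set, any type matches (untyped
        any-overlap mode).
        """
        idx = self._build_index()
        if svtype is None:
            keys = [k for k in idx if k[0] == chrom]
        else:
            keys = [(chrom, svtype)]
        for key in keys:
            if key not in idx:
                continue
            starts, ends = idx[key]
            i = int(np.searchsorted(ends, start, side="right"))
            if i < len(starts) and starts[i] < end:
                return True
        return False

    def overlaps_many(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray, svtype: str | None = None
    ) -> np.ndarray:
        """Vectorised ``overlaps`` for arrays of intervals on one chromosome."""
        idx = self._build_index()
        keys = [k for k in idx if k[0] == chrom and (svtype is None or k[1] == svtype)]
        hit = np.zeros(len(starts), dtype=bool)
        for key in keys:
            t_starts, t_ends = idx[key]
            if len(t_starts) == 0:
                continue
            i = np.searchsorted(t_ends, starts, side="right")
            ok = i < len(t_starts)
            hit |= ok & (t_starts[np.minimum(i, len(t_starts) - 1)] < ends)
        return hit

    def total_bp(self) -> int:
        return sum(e - s for _, s, e, _ in self.merged().records)
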