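"""Genomic interval primitives and set operations.

All intervals are 0-based, half-open (BED convention).  Per-CpG positions
elsewhere in the package are 1-based; :func:`point_to_interval` and
:func:`interval_contains_point` centralize the conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A labeled genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def point_to_interval(chrom: str, pos: int) -> GenomicInterval:
    """Convert a 1-based base position to its 1-bp half-open interval."""
    return GenomicInterval(chrom, pos - 1, pos)


def interval_contains_point(iv: GenomicInterval, chrom: str, pos: int) -> bool:
    """Whether a 1-based position falls inside a half-open interval."""
    return iv.chrom == chrom and iv.start <= pos - 1 < iv.end


def _as_arrays(intervals: Iterable[GenomicInterval]):
    """Group intervals per chromosome into (starts, ends) sorted by start."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        arr = np.asarray(pairs, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


class IntervalIndex:
    """Overlap queries against a static interval set.

    Counting uses the identity #overlapping = #(start < qend) - #(end <= qstart),
    valid for arbitrary (possibly overlapping) interval collections.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._starts_sorted: dict[str, np.ndarray] = {}
        self._ends_sorted: dict[str, np.ndarray] = {}
        for chrom, (starts, ends) in _as_arrays(intervals).items():
            self._starts_sorted[chrom] = np.sort(starts)
            self._ends_sorted[chrom] = np.sort(ends)

    def count_overlaps(self, chrom: str, start, end):
        """Number of stored intervals overlapping [start, end) by >= 1 bp.

        ``start``/``end`` may be scalars or equal-length arrays.
        """
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        if chrom not in self._starts_sorted:
            return np.zeros(start.shape, dtype=np.int64) if start.ndim else 0
        n_started = np.searchsorted(self._starts_sorted[chrom], end, side="left")
        n_ended = np.searchsorted(self._ends_sorted[chrom], start, side="right")
        out = n_started - n_ended
        return out if start.ndim else int(out)

    def overlaps_any(self, chrom: str, start, end):
        c = self.count_overlaps(chrom, start, end)
        return c > 0 if isinstance(c, np.ndarray) else c > 0

    def contains_point(self, chrom: str, pos: int) -> bool:
        """Whether the 1-based position ``pos`` lies inside any interval."""
        return bool(self.overlaps_any(chrom, pos - 1, pos))


def merge_intervals(
    intervals: Sequence[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge overlapping (or within ``gap`` bp) intervals per chromosome."""
    merged: list[GenomicInterval] = []
    for chrom in sorted({iv.chrom for iv in intervals}):
        pairs = sorted((iv.start, iv.end) for iv in intervals if iv.chrom == chrom)
        cur_s, cur_e = pairs[0]
        for s, e in pairs[1:]:
            if s - cur_e <= gap:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def subtract_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Set difference a \\ b, returned merged and sorted."""
    a_merged = merge_intervals(a) if a else []
    b_merged = merge_intervals(b) if b else []
    b_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b_merged:
        b_by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for iv in a_merged:
        cursor = iv.start
        for cut in b_by_chrom.get(iv.chrom, []):
            if cut.end <= cursor or cut.start >= iv.end:
                continue
            if cut.start > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, cut.start))
            cursor = max(cursor, cut.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end))
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)


def clip_to_genome(
    intervals: Iterable[GenomicInterval], genome: dict[str, int]
) -> list[GenomicInterval]:
    """Truncate intervals to chromosome bounds, dropping any that vanish."""
    out = []
    for iv in intervals:
        limit = genome[iv.chrom]
        s, e = max(0, iv.start), min(limit, iv.end)
        if e > s:
            out.append(GenomicInterval(iv.chrom, s, e, iv.strand, iv.label))
    return out


class NearestIntervalFinder:
    """Nearest-distance queries against merged intervals.

    Distance is 0 for any overlap, otherwise the 1-based gap in bases
    (adjacent intervals are 1 bp apart).
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for iv in merge_intervals(intervals) if intervals else []:
            self._starts.setdefault(iv.chrom, [])
            self._ends.setdefault(iv.chrom, [])
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in merge_intervals(intervals) if intervals else []:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, pairs in by_chrom.items():
            arr = np.asarray(sorted(pairs), dtype=np.int64)
            self._starts[chrom] = arr[:, 0]
            self._ends[chrom] = arr[:, 1]

    def distance(self, chrom: str, start, end):
        """Distance from [start, end) to the nearest stored interval.

        Vectorized over arrays; returns -1 where the chromosome holds no
        intervals.
        """
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        scalar = start.ndim == 0
        start = np.atleast_1d(start)
        end = np.atleast_1d(end)
        if chrom not in self._starts or len(self._starts[chrom]) == 0:
            out = np.full(start.shape, -1, dtype=np.int64)
            return int(out[0]) if scalar else out
        starts = self._starts[chrom]
        ends = self._ends[chrom]
        # candidate to the right: first interval with start >= end of query
        idx_r = np.searchsorted(starts, end, side="left")
        # candidate to the left: last interval with start < end of query
        idx_l = idx_r - 1
        big = np.int64(np.iinfo(np.int64).max // 4)
        d_right = np.where(
            idx_r < len(starts), starts[np.minimum(idx_r, len(starts) - 1)] - end + 1, big
        )
        left_end = ends[np.maximum(idx_l, 0)]
        d_left = np.where(idx_l >= 0, start - left_end + 1, big)
        # overlap: interval to the left extends past query start
        overlap = (idx_l >= 0) & (left_end > start)
        dist = np.minimum(np.maximum(d_right, 0), np.maximum(d_left, 0))
        dist = np.where(overlap, 0, dist)
        return int(dist[0]) if scalar else dist
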