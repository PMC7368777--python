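"""Genomic interval algebra shared by every pipeline stage.

Coordinates are 0-based half-open (BED convention) throughout the package.
Browser-style spans ("chr1:100-200", 1-based inclusive) must be converted on
input; :func:`from_browser` does this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.length


def from_browser(span: str) -> GenomicInterval:
    """Convert a 1-based inclusive browser span like ``chr1:101-200``."""
    chrom, rng = span.split(":")
    lo, hi = rng.replace(",", "").split("-")
    return GenomicInterval(chrom, int(lo) - 1, int(hi))


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of overlapping bases; 0 for different chromosomes or abutting
    half-open intervals."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval, fraction: float) -> bool:
    """True iff the overlap covers at least ``fraction`` of *both* intervals."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    ov = overlap_bp(a, b)
    return ov >= fraction * a.length and ov >= fraction * b.length


@dataclass(frozen=True)
class NearestHit:
    """Result of a nearest-feature query.

    ``distance`` is 0 for an overlapping target, the edge-to-edge gap
    otherwise, and ``inf`` when no target exists on the query chromosome
    (``index`` is then -1).
    """

    distance: float
    index: int

    @property
    def reachable(self) -> bool:
        return self.index >= 0


UNREACHABLE = NearestHit(float("inf"), -1)


class _ChromIndex:
    """Per-chromosome sorted-array index: starts ascending, with a prefix
    maximum of ends for overlap pruning and a separately sorted end array for
    nearest-left queries."""

    def __init__(self, starts: np.ndarray, ends: np.ndarray, orig: np.ndarray):
        order = np.lexsort((ends, starts))
        self.starts = starts[order]
        self.ends = ends[order]
        self.orig = orig[order]
        self.cummax_end = np.maximum.accumulate(self.ends)
        eorder = np.argsort(self.ends, kind="stable")
        self.ends_sorted = self.ends[eorder]
        self.ends_sorted_pos = eorder  # position in start-sorted arrays

    def overlapping(self, start: int, end: int) -> np.ndarray:
        """Positions (in start-sorted order) of intervals overlapping
        [start, end)."""
        hi = int(np.searchsorted(self.starts, end, side="left"))
        hits = []
        i = hi - 1
        while i >= 0 and self.cummax_end[i] > start:
            if self.ends[i] > start:
                hits.append(i)
            i -= 1
        return np.array(sorted(hits), dtype=int)


class IntervalCollection:
    """An ordered, queryable collection of genomic intervals.

    Intervals are stored sorted by (chrom, start); overlap and nearest
    queries run in O(log n + hits) via per-chromosome sorted indexes.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], names: Sequence[str] | None = None):
        ivs = list(intervals)
        order = sorted(range(len(ivs)), key=lambda i: (ivs[i].chrom, ivs[i].start, ivs[i].end))
        self.intervals: list[GenomicInterval] = [ivs[i] for i in order]
        self.names: list[str] | None = None
        if names is not None:
            names = list(names)
            if len(names) != len(ivs):
                raise ValueError("names length mismatch")
            self.names = [names[i] for i in order]
        self._index: dict[str, _ChromIndex] = {}
        bychrom: dict[str, list[int]] = {}
        for i, iv in enumerate(self.intervals):
            bychrom.setdefault(iv.chrom, []).append(i)
        for chrom, idxs in bychrom.items():
            starts = np.array([self.intervals[i].start for i in idxs])
            ends = np.array([self.intervals[i].end for i in idxs])
            self._index[chrom] = _ChromIndex(starts, ends, np.array(idxs))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, name_col: str | None = None) -> "IntervalCollection":
        ivs = [
            GenomicInterval(str(r.chrom), int(r.start), int(r.end),
                            str(getattr(r, "strand", ".")) if hasattr(r, "strand") else ".")
            for r in df.itertuples()
        ]
        names = df[name_col].astype(str).tolist() if name_col else None
        return cls(ivs, names)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
            }
        )
        if self.names is not None:
            df.insert(3, "name", self.names)
        return df

    def overlapping(self, query: GenomicInterval) -> list[int]:
        """Indices (into this collection) of intervals overlapping the query
        by >= 1 bp."""
        idx = self._index.get(query.chrom)
        if idx is None:
            return []
        pos = idx.overlapping(query.start, query.end)
        return sorted(int(idx.orig[p]) for p in pos)

    def count_overlapping(self, query: GenomicInterval) -> int:
        return len(self.overlapping(query))

    def any_overlap(self, query: GenomicInterval) -> bool:
        return bool(self.overlapping(query))

    def nearest(self, query: GenomicInterval) -> NearestHit:
        """Nearest interval to the query on the same chromosome.

        Distance 0 when overlapping; otherwise the gap between closest edges.
        Ties (including multiple overlapping targets) are broken by leftmost
        target start, then collection order.
        """
        idx = self._index.get(query.chrom)
        if idx is None:
            return UNREACHABLE
        hits = idx.overlapping(query.start, query.end)
        if len(hits):
            best = min(hits, key=lambda p: (idx.starts[p], idx.orig[p]))
            return NearestHit(0.0, int(idx.orig[best]))
        candidates: list[tuple[float, int, int]] = []  # (distance, start, orig)
        # nearest left neighbor: largest end <= query.start
        e = int(np.searchsorted(idx.ends_sorted, query.start, side="right")) - 1
        if e >= 0:
            best_end = idx.ends_sorted[e]
            lo = int(np.searchsorted(idx.ends_sorted, best_end, side="left"))
            for k in range(lo, e + 1):
                p = idx.ends_sorted_pos[k]
                candidates.append((float(query.start - best_end), int(idx.starts[p]), int(idx.orig[p])))
        # nearest right neighbor: smallest start >= query.end
        s = int(np.searchsorted(idx.starts, query.end, side="left"))
        if s < len(idx.starts):
            best_start = idx.starts[s]
            hi = int(np.searchsorted(idx.starts, best_start, side="right"))
            for k in range(s, hi):
                candidates.append((float(best_start - query.end), int(idx.starts[k]), int(idx.orig[k])))
        if not candidates:
            return UNREACHABLE
        d, _, orig = min(candidates)
        return NearestHit(d, orig)


def nearest_distance(query: GenomicInterval, targets: IntervalCollection) -> NearestHit:
    """Signed-less nearest distance from ``query`` to ``targets``.

    Returns the :data:`UNREACHABLE` sentinel (never raises) when no target
    shares the query's chromosome.
    """
    return targets.nearest(query)


# ---------------------------------------------------------------------------
# BED I/O (BED3/BED6, tab-separated, 0-based half-open)

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED6_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)
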