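"""Genomic interval arithmetic on 0-based half-open coordinates.

All peak/TE/block coordinates in this package follow the BED convention:
0-based, half-open ``[start, end)``. Helpers here wrap ``intervaltree`` for
overlap queries and provide plain-numpy set operations used by the
conservation, enrichment and annotation stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = ["GenomicInterval", "IntervalIndex", "merge_intervals", "union_length"]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_intervals(ivs: list[tuple[int, int]], min_gap: int = 1) -> list[tuple[int, int]]:
    """Merge a list of (start, end) pairs; gaps < ``min_gap`` are bridged.

    ``min_gap=1`` merges touching intervals (gap 0) but keeps truly disjoint
    ones apart.
    """
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s - out[-1][1] < min_gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(v) for v in out]


def union_length(ivs: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(ivs))


class IntervalIndex:
    """Chromosome-keyed interval index over a BED-like DataFrame.

    Expects columns ``chrom``, ``start``, ``end``; any extra columns are kept
    and retrievable per hit via the stored row index.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"interval frame needs columns {sorted(required)}")
        self.df = df.reset_index(drop=True)
        self._tree_cache: dict[str, IntervalTree] | None = None
        # sorted-start + prefix-max-end arrays for O(log n) existence queries
        self._flat: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            order = np.argsort(starts, kind="stable")
            self._flat[chrom] = (starts[order], np.maximum.accumulate(ends[order]))

    @property
    def _trees(self) -> dict[str, IntervalTree]:
        if self._tree_cache is None:
            self._tree_cache = {}
            for chrom, sub in self.df.groupby("chrom", sort=False):
                tree = IntervalTree()
                for idx, s, e in zip(sub.index, sub["start"], sub["end"]):
                    if e > s:
                        tree.addi(int(s), int(e), int(idx))
                self._tree_cache[chrom] = tree
        return self._tree_cache

    def overlapping(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Rows with >= 1 bp overlap with [start, end) on chrom."""
        tree = self._trees.get(chrom)
        if tree is None:
            return self.df.iloc[0:0]
        idx = sorted(iv.data for iv in tree.overlap(start, end))
        return self.df.loc[idx]

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        flat = self._flat.get(chrom)
        if flat is None:
            return False
        starts, maxends = flat
        i = int(np.searchsorted(starts, end, side="left"))
        return i > 0 and int(maxends[i - 1]) > start

    def coverage_fraction(self, chrom: str, start: int, end: int) -> float:
        """Fraction of [start, end) covered by the union of indexed intervals."""
        hits = self.overlapping(chrom, start, end)
        if hits.empty:
            return 0.0
        clipped = [(max(int(s), start), min(int(e), end))
                   for s, e in zip(hits["start"], hits["end"])]
        clipped = [(s, e) for s, e in clipped if e > s]
        return union_length(clipped) / (end - start)

    def flags_for(self, intervals: pd.DataFrame) -> np.ndarray:
        """Boolean per row of ``intervals``: >= 1 bp overlap with the index."""
        out = np.zeros(len(intervals), dtype=bool)
        pos = np.arange(len(intervals))
        chroms = intervals["chrom"].to_numpy()
        qs = intervals["start"].to_numpy(dtype=np.int64)
        qe = intervals["end"].to_numpy(dtype=np.int64)
        for chrom in pd.unique(chroms):
            flat = self._flat.get(chrom)
            if flat is None:
                continue
            starts, maxends = flat
            m = chroms == chrom
            idx = np.searchsorted(starts, qe[m], side="left")
            hit = (idx > 0) & (maxends[np.maximum(idx - 1, 0)] > qs[m])
            out[pos[m]] = hit
        return out
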