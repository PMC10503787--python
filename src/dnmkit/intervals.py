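"""Genomic interval sets and piecewise-constant depth tracks.

All coordinates are 0-based half-open. An :class:`IntervalSet` is a
per-chromosome collection of disjoint sorted intervals; a
:class:`DepthTrack` additionally carries one value per interval (the
bedGraph model) and is the input to callable-genome computation, which is
pure interval arithmetic — no per-base loops.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np


class IntervalSet:
    """Disjoint sorted intervals per chromosome."""

    def __init__(self, data: Mapping[str, np.ndarray] | None = None) -> None:
        # chrom -> (n, 2) int64 array of [start, end)
        self.data: dict[str, np.ndarray] = {}
        if data:
            for chrom, arr in data.items():
                self.data[chrom] = self._normalize(np.asarray(arr, dtype=np.int64))

    @staticmethod
    def _normalize(arr: np.ndarray) -> np.ndarray:
        if arr.size == 0:
            return np.empty((0, 2), dtype=np.int64)
        arr = arr.reshape(-1, 2)
        if np.any(arr[:, 1] <= arr[:, 0]):
            raise ValueError("intervals must have end > start")
        arr = arr[np.argsort(arr[:, 0])]
        merged = [list(arr[0])]
        for s, e in arr[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return np.array(merged, dtype=np.int64)

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in tuples:
            by_chrom.setdefault(chrom, []).append((s, e))
        return cls({c: np.array(v) for c, v in by_chrom.items()})

    def to_tuples(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self.data):
            for s, e in self.data[chrom]:
                out.append((chrom, int(s), int(e)))
        return out

    def total_length(self) -> int:
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self.data.values())
        )

    def contains(self, chrom: str, pos: np.ndarray | int) -> np.ndarray | bool:
        """Membership test for positions (vectorized)."""
        scalar = np.isscalar(pos)
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        arr = self.data.get(chrom)
        if arr is None or arr.size == 0:
            res = np.zeros(len(pos), dtype=bool)
        else:
            idx = np.searchsorted(arr[:, 0], pos, side="right") - 1
            res = (idx >= 0) & (pos < arr[np.clip(idx, 0, None), 1])
        return bool(res[0]) if scalar else res

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: dict[str, np.ndarray] = {}
        for chrom in self.data:
            if chrom not in other.data:
                continue
            a, b = self.data[chrom], other.data[chrom]
            pieces = []
            for s, e in a:
                lo = np.searchsorted(b[:, 1], s, side="right")
                hi = np.searchsorted(b[:, 0], e, side="left")
                for bs, be in b[lo:hi]:
                    pieces.append((max(s, bs), min(e, be)))
            pieces = [(s, e) for s, e in pieces if e > s]
            if pieces:
                out[chrom] = np.array(pieces)
        return IntervalSet(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        keys = {c for c, a in self.data.items() if len(a)}
        if keys != {c for c, a in other.data.items() if len(a)}:
            return False
        return all(np.array_equal(self.data[c], other.data[c]) for c in keys)


class DepthTrack:
    """Per-sample mean read depth over half-open intervals (bedGraph model).

    Intervals must be sorted and non-overlapping per chromosome; gaps are
    allowed and mean "no depth information" (treated as non-callable).
    """

    def __init__(self, data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # chrom -> (starts, ends, values)
        self.data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError("starts/ends/values length mismatch")
            if np.any(ends <= starts):
                raise ValueError("intervals must have end > start")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping or unsorted intervals on {chrom}")
            self.data[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    def value_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Depth at positions; NaN where the track has a gap."""
        pos = np.asarray(pos, dtype=np.int64)
        out = np.full(len(pos), np.nan)
        if chrom not in self.data:
            return out
        starts, ends, values = self.data[chrom]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        out[ok] = values[idx[ok]]
        return out

    def segment_values(
        self, chrom: str, breaks: np.ndarray
    ) -> np.ndarray:
        """Depth of each segment [breaks[i], breaks[i+1]); NaN in gaps.

        Segments must not straddle interval boundaries of this track, which
        holds when ``breaks`` includes this track's own boundaries.
        """
        return self.value_at(chrom, breaks[:-1])

    def breakpoints(self, chrom: str) -> np.ndarray:
        if chrom not in self.data:
            return np.empty(0, dtype=np.int64)
        starts, ends, _ = self.data[chrom]
        return np.union1d(starts, ends)


def combined_breakpoints(tracks: Iterable[DepthTrack], chrom: str) -> np.ndarray:
    """Union of interval boundaries across tracks for one chromosome."""
    parts = [t.breakpoints(chrom) for t in tracks]
    parts = [p for p in parts if len(p)]
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(parts))
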