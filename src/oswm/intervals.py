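"""Ordered sets of half-open time intervals.

All restriction and masking in the package goes through :class:`IntervalSet`.
Intervals are half-open ``[start, end)`` so that binning and restriction never
double-count a boundary sample or spike.
"""

from __future__ import annotations

import numpy as np

__all__ = ["IntervalSet"]


class IntervalSet:
    """An ordered list of disjoint half-open intervals ``[start, end)``.

    Parameters
    ----------
    intervals : array-like, shape (n, 2)
        Interval bounds in seconds. Must satisfy ``start < end`` per row,
        be sorted by start, and be pairwise disjoint. Use
        :meth:`from_unsorted` to normalise arbitrary input.
    """

    __slots__ = ("_arr",)

    def __init__(self, intervals=None):
        if intervals is None or len(intervals) == 0:
            self._arr = np.empty((0, 2), dtype=float)
            return
        arr = np.asarray(intervals, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(arr)):
            raise ValueError("interval bounds must be finite")
        if np.any(arr[:, 0] >= arr[:, 1]):
            bad = np.nonzero(arr[:, 0] >= arr[:, 1])[0]
            raise ValueError(f"empty or inverted interval at rows {bad.tolist()}")
        if np.any(np.diff(arr[:, 0]) < 0):
            raise ValueError("intervals must be sorted by start time")
        if np.any(arr[1:, 0] < arr[:-1, 1]):
            raise ValueError("intervals must be pairwise disjoint")
        self._arr = arr

    # -- construction -------------------------------------------------

    @classmethod
    def from_unsorted(cls, intervals) -> "IntervalSet":
        """Build an IntervalSet from arbitrary intervals, merging overlaps."""
        arr = np.asarray(intervals, dtype=float).reshape(-1, 2)
        if arr.size == 0:
            return cls()
        if np.any(arr[:, 0] >= arr[:, 1]):
            raise ValueError("empty or inverted interval")
        arr = arr[np.argsort(arr[:, 0], kind="stable")]
        merged = [list(arr[0])]
        for s, e in arr[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return cls(np.asarray(merged))

    # -- basic accessors ----------------------------------------------

    @property
    def arr(self) -> np.ndarray:
        return self._arr

    @property
    def starts(self) -> np.ndarray:
        return self._arr[:, 0]

    @property
    def ends(self) -> np.ndarray:
        return self._arr[:, 1]

    def __len__(self) -> int:
        return self._arr.shape[0]

    def __iter__(self):
        return iter(map(tuple, self._arr))

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._arr.shape == other._arr.shape and np.array_equal(
            self._arr, other._arr
        )

    def __repr__(self) -> str:
        return f"IntervalSet({self._arr.tolist()!r})"

    def total_duration(self) -> float:
        """Summed length of all intervals, in seconds."""
        return float(np.sum(self._arr[:, 1] - self._arr[:, 0]))

    # -- set algebra ---------------------------------------------------

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Pointwise intersection with another IntervalSet."""
        out = []
        a, b = self._arr, other._arr
        i = j = 0
        while i < len(a) and j < len(b):
            s = max(a[i, 0], b[j, 0])
            e = min(a[i, 1], b[j, 1])
            if s < e:
                out.append((s, e))
            if a[i, 1] <= b[j, 1]:
                i += 1
            else:
                j += 1
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Remove every point covered by ``other``."""
        if len(other) == 0 or len(self) == 0:
            return IntervalSet(self._arr.copy())
        out = []
        for s, e in self._arr:
            cur = s
            for os, oe in other._arr:
                if oe <= cur:
                    continue
                if os >= e:
                    break
                if os > cur:
                    out.append((cur, min(os, e)))
                cur = max(cur, oe)
                if cur >= e:
                    break
            if cur < e:
                out.append((cur, e))
        return IntervalSet(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        both = np.vstack([self._arr, other._arr])
        return IntervalSet.from_unsorted(both) if len(both) else IntervalSet()

    # -- queries -------------------------------------------------------

    def contains(self, times) -> np.ndarray:
        """Boolean mask: which of ``times`` fall in some interval (half-open)."""
        t = np.asarray(times, dtype=float)
        if len(self) == 0:
            return np.zeros(t.shape, dtype=bool)
        idx = np.searchsorted(self._arr[:, 0], t, side="right") - 1
        valid = idx >= 0
        inside = np.zeros(t.shape, dtype=bool)
        inside[valid] = t[valid] < self._arr[idx[valid], 1]
        return inside

    def count(self, times) -> int:
        """Number of ``times`` falling inside the set."""
        return int(np.count_nonzero(self.contains(times)))

    def overlaps(self, start: float, end: float) -> bool:
        """True if [start, end) intersects any interval."""
        if len(self) == 0:
            return False
        return bool(np.any((self._arr[:, 0] < end) & (self._arr[:, 1] > start)))
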