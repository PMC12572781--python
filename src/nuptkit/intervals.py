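"""Sorted half-open integer interval arithmetic.

Intervals are ``(start, end)`` pairs with ``start < end``, 0-based, half-open.
Per-chromosome sets are plain ``dict[str, np.ndarray]`` with shape ``(n, 2)``.
These helpers are deliberately minimal: they are the inner loop of the
permutation tests and are oracle-tested against a per-bp bitmap.
"""
from __future__ import annotations

import numpy as np


def as_array(intervals) -> np.ndarray:
    """Coerce a sequence of (start, end) pairs to an (n, 2) int array."""
    arr = np.asarray(intervals, dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of intervals")
    return arr


def merge(intervals) -> np.ndarray:
    """Union of possibly-overlapping intervals as a sorted disjoint set.

    Abutting intervals ([0,5) and [5,9)) are coalesced.
    """
    arr = as_array(intervals)
    if len(arr) == 0:
        return arr
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def total_length(intervals) -> int:
    arr = as_array(intervals)
    if len(arr) == 0:
        return 0
    return int((arr[:, 1] - arr[:, 0]).sum())


def intersect(a, b) -> np.ndarray:
    """Intersection of two merged interval sets (merged output)."""
    a, b = merge(a), merge(b)
    out = []
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
    return as_array(out)


def intersection_length(a, b) -> int:
    return total_length(intersect(a, b))


def union_length(a, b) -> int:
    a, b = as_array(a), as_array(b)
    return total_length(merge(np.concatenate([a, b], axis=0)))


def jaccard(a, b) -> float:
    """Intersection bp over union bp; 0.0 when the union is empty."""
    u = union_length(a, b)
    if u == 0:
        return 0.0
    return intersection_length(a, b) / u


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/len(a), overlap/len(b)) for two single intervals."""
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))
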