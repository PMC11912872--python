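"""Interval arithmetic on 0-based, half-open genomic intervals.

All functions operate on (start, end) pairs with start < end, represented
as ``(N, 2)`` integer/float numpy arrays. These primitives back BED masks,
recombination-map windows, and TMRCA tracks throughout the package.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_array",
    "normalize",
    "merge",
    "intersect",
    "complement",
    "total_length",
]


def as_array(intervals) -> np.ndarray:
    """Coerce an iterable of (start, end) pairs to an (N, 2) float array."""
    arr = np.asarray(list(intervals), dtype=float)
    if arr.size == 0:
        return np.empty((0, 2), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("intervals must be (start, end) pairs")
    return arr


def normalize(intervals) -> np.ndarray:
    """Sort and merge overlapping/adjacent intervals."""
    arr = as_array(intervals)
    if len(arr) == 0:
        return arr
    if np.any(arr[:, 0] >= arr[:, 1]):
        raise ValueError("interval with start >= end")
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    arr = arr[order]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=float)


def merge(a, b) -> np.ndarray:
    """Union of two interval sets, normalized."""
    a = as_array(a)
    b = as_array(b)
    if len(a) == 0:
        return normalize(b) if len(b) else b
    if len(b) == 0:
        return normalize(a)
    return normalize(np.vstack([a, b]))


def intersect(a, b) -> np.ndarray:
    """Intersection of two normalized interval sets."""
    a = normalize(a)
    b = normalize(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return as_array(out)


def complement(intervals, span_start: float, span_end: float) -> np.ndarray:
    """Complement of an interval set within [span_start, span_end)."""
    arr = normalize(intervals)
    out = []
    cursor = span_start
    for s, e in arr:
        s = max(s, span_start)
        e = min(e, span_end)
        if s >= e:
            continue
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < span_end:
        out.append((cursor, span_end))
    return as_array(out)


def total_length(intervals) -> float:
    arr = as_array(intervals)
    if len(arr) == 0:
        return 0.0
    return float(np.sum(arr[:, 1] - arr[:, 0]))
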