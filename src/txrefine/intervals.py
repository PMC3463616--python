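"""Plain half-open interval algebra on ``(start, end)`` tuples.

All genomic arithmetic in this package goes through these helpers so that
the 0-based half-open convention is enforced in exactly one place.
Intervals are plain ``(int, int)`` tuples with ``start < end``; lists of
intervals handed to the set operations need not be sorted or disjoint
unless stated otherwise.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def length(iv: Interval) -> int:
    return iv[1] - iv[0]


def total_length(ivs: Iterable[Interval]) -> int:
    return sum(e - s for s, e in ivs)


def overlap_len(a: Interval, b: Interval) -> int:
    """Length of the intersection of two intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def touches(a: Interval, b: Interval) -> bool:
    """Closed-interval overlap: shared boundary points count as contact."""
    return a[0] <= b[1] and b[0] <= a[1]


def contains(outer: Interval, inner: Interval) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def strictly_contains(outer: Interval, inner: Interval) -> bool:
    return outer[0] < inner[0] and inner[1] < outer[1]


def merge(ivs: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as a sorted, disjoint list (touching runs fuse)."""
    ivs = sorted(ivs)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection of two interval sets; result sorted and disjoint."""
    a, b = merge(a), merge(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Set difference a \\ b; result sorted and disjoint."""
    a, b = merge(a), merge(b)
    out: list[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect_length(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    return total_length(intersect(a, b))


def gaps(ivs: Sequence[Interval]) -> list[Interval]:
    """Gaps between consecutive intervals of a sorted disjoint list."""
    out = []
    for prev, nxt in zip(ivs, ivs[1:]):
        if prev[1] < nxt[0]:
            out.append((prev[1], nxt[0]))
    return out
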