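"""Half-open integer interval arithmetic on sorted lists of (start, end)."""

from __future__ import annotations

Interval = tuple[int, int]


def merge(intervals: list[Interval]) -> list[Interval]:
    """Union of intervals as a sorted, non-overlapping list."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def total_length(intervals: list[Interval]) -> int:
    """Length of the union of intervals."""
    return sum(e - s for s, e in merge(intervals))


def subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Set difference a \\ b, both unioned first."""
    a = merge(a)
    b = merge(b)
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


def intersect_length(a: list[Interval], b: list[Interval]) -> int:
    """Total overlap length between the unions of a and b."""
    a = merge(a)
    b = merge(b)
    i = j = 0
    tot = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            tot += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return tot


def overlaps(a: list[Interval], b: list[Interval]) -> bool:
    return intersect_length(a, b) > 0


def gaps(intervals: list[Interval]) -> list[Interval]:
    """Complement between consecutive merged intervals (introns of an exon chain)."""
    m = merge(intervals)
    return [(m[i][1], m[i + 1][0]) for i in range(len(m) - 1) if m[i][1] < m[i + 1][0]]


def contains(outer: list[Interval], inner: list[Interval]) -> bool:
    """True if the union of `inner` lies entirely inside the union of `outer`."""
    return intersect_length(outer, inner) == total_length(inner)
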