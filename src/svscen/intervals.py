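"""Small interval arithmetic helpers on 1-based closed intervals.

Used for region-set construction (flank merging, gene masking) and by the
simulator's placement bookkeeping. Intervals are ``(start, end)`` tuples with
``start <= end``; lists are kept sorted.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Merge overlapping or bookended (adjacent) closed intervals."""
    ivs = sorted((s, e) for s, e in intervals if e >= s)
    if not ivs:
        return []
    out = [ivs[0]]
    for s, e in ivs[1:]:
        ps, pe = out[-1]
        if s <= pe + 1:  # adjacent closed intervals merge
            out[-1] = (ps, max(pe, e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(base: Iterable[Interval], remove: Iterable[Interval]) -> List[Interval]:
    """Return ``base`` minus ``remove``, both treated as closed intervals."""
    base_m = merge_intervals(base)
    rem_m = merge_intervals(remove)
    out: List[Interval] = []
    j = 0
    for s, e in base_m:
        cur = s
        while j < len(rem_m) and rem_m[j][1] < cur:
            j += 1
        k = j
        while k < len(rem_m) and rem_m[k][0] <= e:
            rs, re = rem_m[k]
            if rs > cur:
                out.append((cur, rs - 1))
            cur = max(cur, re + 1)
            if re >= e:
                break
            k += 1
        if cur <= e:
            out.append((cur, e))
    return out


def clip_interval(start: int, end: int, lo: int, hi: int) -> Interval | None:
    """Clip a closed interval to ``[lo, hi]``; None if nothing remains."""
    s, e = max(start, lo), min(end, hi)
    return (s, e) if s <= e else None


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s + 1 for s, e in intervals)


def overlap_length(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
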