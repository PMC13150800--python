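"""Coordinate transfer between the two reference genomes via alignment blocks.

Blocks come from a whole-genome aligner's coordinate output (show-coords
style). Within a block the mapping is linear interpolation by offset; blocks
carry no per-base alignment, so this is exact for equal-length blocks and
approximate otherwise — a documented precision limit.

An SV whose span has been deleted from the target genome has no mapped
interior; its endpoints are snapped outward to the nearest flanking block so
the record collapses onto its anchor point in the target coordinates. This
keeps reference-carried SVs (those detected only against the other genome)
classifiable instead of silently dropping them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

from intervaltree import IntervalTree

from .io import AlignmentBlock, SVRecord

__all__ = [
    "AlignmentBlockMap",
    "LiftResult",
    "lift_point",
    "lift_sv",
    "A_TO_B",
    "B_TO_A",
]

A_TO_B = "a2b"
B_TO_A = "b2a"

# failure reason codes
ENDPOINT_UNMAPPED = "endpoint_unmapped"
CONTIG_SPLIT = "contig_split"
STRAND_CONFLICT = "strand_conflict"
LENGTH_DISTORTED = "length_distorted"


def _norm_direction(direction: str) -> str:
    d = direction.lower().replace("->", "2").replace("_to_", "2")
    if d in ("a2b", "ab"):
        return A_TO_B
    if d in ("b2a", "ba"):
        return B_TO_A
    raise ValueError(f"direction must be 'a2b' or 'b2a', got {direction!r}")


class AlignmentBlockMap:
    """Ordered co-linear blocks linking the two genomes, interval-indexed."""

    def __init__(self, blocks: List[AlignmentBlock]):
        self.blocks = sorted(
            blocks, key=lambda b: (b.contig_a, b.start_a, b.end_a, b.contig_b, b.start_b)
        )
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        for b in self.blocks:
            self._trees.setdefault((A_TO_B, b.contig_a), IntervalTree()).addi(
                b.start_a, b.end_a + 1, b
            )
            self._trees.setdefault((B_TO_A, b.contig_b), IntervalTree()).addi(
                b.start_b, b.end_b + 1, b
            )

    def __len__(self) -> int:
        return len(self.blocks)

    def blocks_at(self, contig: str, pos: int, direction: str) -> List[AlignmentBlock]:
        tree = self._trees.get((_norm_direction(direction), contig))
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.at(pos)),
            key=lambda b: (b.contig_a, b.start_a, b.contig_b, b.start_b),
        )

    def blocks_overlapping(
        self, contig: str, start: int, end: int, direction: str
    ) -> List[AlignmentBlock]:
        tree = self._trees.get((_norm_direction(direction), contig))
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.overlap(start, end + 1)),
            key=lambda b: (b.contig_a, b.start_a, b.contig_b, b.start_b),
        )

    def nearest_flank(
        self, contig: str, pos: int, direction: str, side: str
    ) -> Optional[AlignmentBlock]:
        """Nearest block strictly left (side='left') or right of ``pos``."""
        direction = _norm_direction(direction)
        best = None
        best_key = None
        for b in self.blocks:
            c, s, e = (b.contig_a, b.start_a, b.end_a) if direction == A_TO_B else (
                b.contig_b, b.start_b, b.end_b)
            if c != contig:
                continue
            if side == "left" and e < pos:
                key = (pos - e, -b.identity)
            elif side == "right" and s > pos:
                key = (s - pos, -b.identity)
            else:
                continue
            if best_key is None or key < best_key:
                best, best_key = b, key
        return best


def _interp(b: AlignmentBlock, pos: int, direction: str) -> Tuple[str, int, str]:
    if direction == A_TO_B:
        src = (b.start_a, b.end_a)
        tgt_contig, tgt = b.contig_b, (b.start_b, b.end_b)
    else:
        src = (b.start_b, b.end_b)
        tgt_contig, tgt = b.contig_a, (b.start_a, b.end_a)
    off = pos - src[0]
    src_len = src[1] - src[0]
    tgt_len = tgt[1] - tgt[0]
    if src_len > 0 and tgt_len != src_len:
        off = round(off * tgt_len / src_len)
    if b.strand == "+":
        return tgt_contig, tgt[0] + off, "+"
    return tgt_contig, tgt[1] - off, "-"


def lift_point(
    contig: str, pos: int, block_map: AlignmentBlockMap, direction: str
) -> Optional[Tuple[str, int, str]]:
    """Map one position; returns ``(contig', pos', strand)`` or None.

    With several overlapping candidate blocks the highest-identity block
    wins; ties go to the longest, then the leftmost.
    """
    direction = _norm_direction(direction)
    candidates = block_map.blocks_at(contig, pos, direction)
    if not candidates:
        return None
    if len(candidates) > 1:
        def rank(b: AlignmentBlock):
            length = b.len_a if direction == A_TO_B else b.len_b
            start = b.start_a if direction == A_TO_B else b.start_b
            return (-b.identity, -length, start, b.contig_a, b.contig_b)
        candidates.sort(key=rank)
    return _interp(candidates[0], pos, direction)


@dataclass
class LiftResult:
    """Outcome of lifting one SV; ``record`` is None on failure."""

    record: Optional[SVRecord]
    reason: Optional[str] = None
    snapped: bool = False

    @property
    def ok(self) -> bool:
        return self.record is not None


def _src_interval(b: AlignmentBlock, direction: str):
    return (b.start_a, b.end_a) if direction == A_TO_B else (b.start_b, b.end_b)


def _collapse_into_gap(
    contig: str, start: int, end: int, block_map: AlignmentBlockMap,
    direction: str, max_snap: int,
):
    """Canonical lift of a span that is (mostly) absent from the target.

    The span's midpoint sits in an alignment gap; the lifted record is the
    junction between the two flanking blocks, i.e. the interval collapses to
    its anchor point in the target. Returns (start', end', contig') or a
    failure reason string.
    """
    mid = (start + end) // 2
    left = block_map.nearest_flank(contig, mid, direction, "left")
    right = block_map.nearest_flank(contig, mid, direction, "right")
    if left is None or right is None:
        return ENDPOINT_UNMAPPED
    l_edge = _src_interval(left, direction)[1]
    r_edge = _src_interval(right, direction)[0]
    if mid - l_edge > max_snap or r_edge - mid > max_snap:
        return ENDPOINT_UNMAPPED
    c1, p1, _ = _interp(left, l_edge, direction)
    c2, p2, _ = _interp(right, r_edge, direction)
    if c1 != c2:
        return CONTIG_SPLIT
    return (min(p1, p2), max(p1, p2), c1)


def lift_sv(
    sv: SVRecord,
    block_map: AlignmentBlockMap,
    direction: str,
    length_tolerance: float = 2.0,
    allow_gap_snap: bool = True,
) -> LiftResult:
    """Lift one SV record between genomes.

    INS lifts its single anchor point and TRA each breakend independently.
    Interval types (DEL/DUP/INV) take one of three routes:

    1. both endpoints map to the same contig and strand with the lifted span
       within ``length_tolerance`` of the original — plain projection;
    2. the span straddles block boundaries but is mostly aligned — both
       endpoints are projected through the single best-covering block
       (clamped at its edges), which resolves strand conflicts at inversion
       boundaries;
    3. most of the span is unaligned in the target (deleted there) — the
       record collapses onto the junction of the flanking blocks.

    Routes 2-3 mark the result ``snapped`` and are exempt from the lower
    length bound (a collapse is expected); the upper bound
    (``length_tolerance`` x span) always applies, guarding against lifts
    through misjoined blocks. ``svlen`` keeps the biological event length.
    """
    direction = _norm_direction(direction)

    if sv.svtype == "INS":
        hit = lift_point(sv.contig, sv.start, block_map, direction)
        if hit is None:
            return LiftResult(None, ENDPOINT_UNMAPPED)
        c, p, _ = hit
        return LiftResult(replace(sv, contig=c, start=p, end=p))

    if sv.svtype == "TRA":
        assert sv.mate is not None
        hit1 = lift_point(sv.contig, sv.start, block_map, direction)
        hit2 = lift_point(sv.mate[0], sv.mate[1], block_map, direction)
        if hit1 is None or hit2 is None:
            return LiftResult(None, ENDPOINT_UNMAPPED)
        from .io import canonical_breakends

        c, p, mate = canonical_breakends(hit1[0], hit1[1], (hit2[0], hit2[1]))
        return LiftResult(replace(sv, contig=c, start=p, end=p, mate=mate))

    # DEL / DUP / INV
    hit_s = lift_point(sv.contig, sv.start, block_map, direction)
    hit_e = lift_point(sv.contig, sv.end, block_map, direction)
    endpointwise = None
    if (hit_s is not None and hit_e is not None
            and hit_s[0] == hit_e[0] and hit_s[2] == hit_e[2]):
        ps, pe = hit_s[1], hit_e[1]
        endpointwise = (hit_s[0], min(ps, pe), max(ps, pe))

    if not allow_gap_snap:
        if hit_s is None or hit_e is None:
            return LiftResult(None, ENDPOINT_UNMAPPED)
        if hit_s[0] != hit_e[0]:
            return LiftResult(None, CONTIG_SPLIT)
        if hit_s[2] != hit_e[2]:
            return LiftResult(None, STRAND_CONFLICT)
        contig, start, end = endpointwise  # type: ignore[misc]
        span = end - start + 1
        if span > length_tolerance * sv.span or span * length_tolerance < sv.span:
            return LiftResult(None, LENGTH_DISTORTED)
        return LiftResult(replace(sv, contig=contig, start=start, end=end))

    candidates = block_map.blocks_overlapping(sv.contig, sv.start, sv.end, direction)

    def src_overlap(b: AlignmentBlock) -> int:
        s, e = _src_interval(b, direction)
        return max(0, min(e, sv.end) - max(s, sv.start) + 1)

    best = None
    if candidates:
        best = max(candidates, key=lambda b: (
            src_overlap(b), b.identity,
            _src_interval(b, direction)[1] - _src_interval(b, direction)[0],
            -_src_interval(b, direction)[0],
        ))

    max_snap = int(length_tolerance * sv.span) + 1000
    if best is None or src_overlap(best) < 0.5 * sv.span:
        # span mostly deleted from the target genome: canonical collapse
        got = _collapse_into_gap(sv.contig, sv.start, sv.end, block_map,
                                 direction, max_snap)
        if isinstance(got, str):
            if got == ENDPOINT_UNMAPPED and endpointwise is not None:
                got = LENGTH_DISTORTED  # mapped flanks but nothing sensible between
            return LiftResult(None, got)
        start, end, contig = got
        return LiftResult(replace(sv, contig=contig, start=start, end=end), snapped=True)

    # mostly aligned: project through the best-covering block (clamped at its
    # edges), and prefer the endpoint-wise projection only when its span is
    # closer to the original — this keeps a tandem-duplication span on the
    # single corresponding copy instead of stretching across both.
    bs, be = _src_interval(best, direction)
    c1, p1, _ = _interp(best, max(sv.start, bs), direction)
    c2, p2, _ = _interp(best, min(sv.end, be), direction)
    clamped = (c1, min(p1, p2), max(p1, p2))
    clamped_was_exact = bs <= sv.start and sv.end <= be

    def ratio_error(option) -> float:
        span = option[2] - option[1] + 1
        return abs(math.log(span / sv.span))

    options = [(ratio_error(clamped), 1, clamped, not clamped_was_exact)]
    if endpointwise is not None:
        options.append((ratio_error(endpointwise), 0, endpointwise, False))
    options.sort(key=lambda t: (t[0], t[1]))
    _err, _tag, (contig, start, end), snapped = options[0]
    span = end - start + 1
    if span > length_tolerance * sv.span:
        return LiftResult(None, LENGTH_DISTORTED)
    if not snapped and span * length_tolerance < sv.span:
        return LiftResult(None, LENGTH_DISTORTED)
    return LiftResult(replace(sv, contig=contig, start=start, end=end), snapped=snapped)
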