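"""Consensus merging of SV calls across callers and samples.

Equivalent calls are clustered by single linkage under a breakpoint-distance
plus reciprocal-overlap criterion (the usual multi-caller merge semantics),
then filtered by two call-level rules: an SV must be confirmed
by at least ``min_callers`` distinct callers within a sample, and its read
support must exceed ``min_support`` (strictly). A population-level merge
across samples records which samples carry each SV so the fixation filter
(present in 100% of a cohort) can be applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set

from .io import SVRecord

__all__ = [
    "MergeParams",
    "PopulationSV",
    "reciprocal_overlap",
    "sv_equivalent",
    "cluster_calls",
    "consensus_filter",
    "population_merge",
    "fixation_filter",
]


@dataclass(frozen=True)
class MergeParams:
    """Tolerances of the SV-equivalence relation and the call-level filters."""

    max_breakpoint_dist: int = 500
    min_reciprocal_overlap: float = 0.5
    min_ins_len_ratio: float = 0.5
    min_callers: int = 2
    min_support: int = 5  # strict: kept only if support > min_support

    def __post_init__(self) -> None:
        if self.max_breakpoint_dist < 0:
            raise ValueError("max_breakpoint_dist must be >= 0")
        for name in ("min_reciprocal_overlap", "min_ins_len_ratio"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.min_callers < 1:
            raise ValueError("min_callers must be >= 1")
        if self.min_support < 0:
            raise ValueError("min_support must be >= 0")


@dataclass
class PopulationSV:
    """A cluster of equivalent SV calls with its consensus representative."""

    representative: SVRecord
    members: List[SVRecord] = field(default_factory=list)
    samples_present: Set[str] = field(default_factory=set)

    @property
    def category(self) -> str:
        return self.representative.mapping_category

    @property
    def callers_present(self) -> Set[str]:
        return {m.caller for m in self.members if m.caller}

    @property
    def max_support(self) -> int:
        return max((m.support for m in self.members), default=self.representative.support)


def reciprocal_overlap(a: SVRecord, b: SVRecord) -> float:
    """Shared closed-interval span divided by the longer span."""
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov <= 0:
        return 0.0
    return ov / max(a.span, b.span)


def sv_equivalent(a: SVRecord, b: SVRecord, params: MergeParams) -> bool:
    """True iff two calls describe the same SV under ``params``.

    Same type and contig, both breakpoints within ``max_breakpoint_dist``;
    additionally reciprocal overlap for interval types (DEL/DUP/INV),
    length-ratio agreement for INS, and mate-breakend proximity for TRA.
    """
    if a.svtype != b.svtype or a.contig != b.contig:
        return False
    d = params.max_breakpoint_dist
    if abs(a.start - b.start) > d or abs(a.end - b.end) > d:
        return False
    if a.svtype in ("DEL", "DUP", "INV"):
        return reciprocal_overlap(a, b) >= params.min_reciprocal_overlap
    if a.svtype == "INS":
        la, lb = a.svlen, b.svlen
        if la == 0 and lb == 0:
            return True
        if la == 0 or lb == 0:
            return False
        return min(la, lb) / max(la, lb) >= params.min_ins_len_ratio
    # TRA: both breakends must match on the same contig pair
    assert a.mate is not None and b.mate is not None
    return a.mate[0] == b.mate[0] and abs(a.mate[1] - b.mate[1]) <= d


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _median_low(values: Sequence[int]) -> int:
    """Lower-middle median (deterministic for even counts)."""
    vs = sorted(values)
    return vs[(len(vs) - 1) // 2]


def _build_population_sv(members: List[SVRecord]) -> PopulationSV:
    members = sorted(members, key=SVRecord.sort_key)
    first = members[0]
    start = _median_low([m.start for m in members])
    end = _median_low([m.end for m in members])
    if end < start:
        start, end = end, start
    mate = None
    if first.svtype == "TRA":
        mate_contig = first.mate[0]  # type: ignore[index]
        mate = (mate_contig, _median_low([m.mate[1] for m in members]))  # type: ignore[index]
    rep = SVRecord(
        contig=first.contig,
        start=start,
        end=end,
        svtype=first.svtype,
        svlen=_median_low([m.svlen for m in members]),
        support=max(m.support for m in members),
        genotype=first.genotype,
        sample=first.sample,
        caller=first.caller,
        mapping_category=first.mapping_category,
        mate=mate,
    )
    return PopulationSV(
        representative=rep,
        members=members,
        samples_present={m.sample for m in members if m.sample},
    )


def cluster_calls(records: Sequence[SVRecord], params: MergeParams) -> List[PopulationSV]:
    """Single-linkage connected components under :func:`sv_equivalent`.

    A position-sorted sweep compares each record only against earlier records
    whose start lies within ``max_breakpoint_dist`` — sufficient because
    equivalence bounds the start difference — and therefore equals the
    brute-force all-pairs components on any input. Output is sorted by
    representative position; ties are broken on the full record key so the
    result is deterministic.
    """
    if not records:
        return []
    order = sorted(range(len(records)), key=lambda i: records[i].sort_key())
    uf = _UnionFind(len(records))
    for oi, i in enumerate(order):
        ri = records[i]
        for oj in range(oi - 1, -1, -1):
            j = order[oj]
            rj = records[j]
            if rj.contig != ri.contig or ri.start - rj.start > params.max_breakpoint_dist:
                break
            if sv_equivalent(ri, rj, params):
                uf.union(i, j)
    groups: Dict[int, List[SVRecord]] = {}
    for i in range(len(records)):
        groups.setdefault(uf.find(i), []).append(records[i])
    clusters = [_build_population_sv(ms) for ms in groups.values()]
    clusters.sort(key=lambda c: c.representative.sort_key())
    return clusters


def consensus_filter(clusters: Iterable[PopulationSV], params: MergeParams) -> List[PopulationSV]:
    """Keep clusters confirmed by >= ``min_callers`` distinct callers with
    max member support strictly greater than ``min_support``."""
    return [
        c for c in clusters
        if len(c.callers_present) >= params.min_callers and c.max_support > params.min_support
    ]


def population_merge(
    per_sample_consensus: Sequence[Sequence[PopulationSV]], params: MergeParams
) -> List[PopulationSV]:
    """Merge per-sample consensus sets into population SVs.

    Single linkage runs over every member call (not just the per-sample
    representatives), so two samples share an SV whenever *any* pair of
    their calls is equivalent — the tolerant semantics of multi-callset
    merging tools. Member calls of one per-sample cluster always stay
    together; ``samples_present`` is collected from the merged members.
    """
    sources = [psv for sample_set in per_sample_consensus for psv in sample_set]
    if not sources:
        return []
    members: List[SVRecord] = []
    source_of: Dict[int, int] = {}
    for si, psv in enumerate(sources):
        for m in psv.members:
            members.append(m)
            source_of[id(m)] = si
    clusters = cluster_calls(members, params)
    uf = _UnionFind(len(clusters))
    first_cluster_of_source: Dict[int, int] = {}
    for ci, cluster in enumerate(clusters):
        for m in cluster.members:
            si = source_of[id(m)]
            if si in first_cluster_of_source:
                uf.union(ci, first_cluster_of_source[si])
            else:
                first_cluster_of_source[si] = ci
    groups: Dict[int, List[SVRecord]] = {}
    for ci, cluster in enumerate(clusters):
        groups.setdefault(uf.find(ci), []).extend(cluster.members)
    out = [_build_population_sv(ms) for ms in groups.values()]
    out.sort(key=lambda c: c.representative.sort_key())
    return out


def fixation_filter(pop_svs: Iterable[PopulationSV], cohort: Set[str]) -> List[PopulationSV]:
    """Keep only SVs present in 100% of the cohort's samples."""
    cohort = set(cohort)
    if not cohort:
        raise ValueError("fixation_filter requires a non-empty cohort")
    return [p for p in pop_svs if cohort <= p.samples_present]
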