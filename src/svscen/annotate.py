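"""Gene-impact classification and per-callset summary statistics.

The impact classifier works at whole-feature granularity: an SV is
*gene-level* if it engulfs an entire gene (or is a translocation with a
breakend inside a gene), otherwise *exonic* if it touches an exon, otherwise
*intronic* if it touches a gene span, otherwise *intergenic*. Precedence is
gene_level > exonic > intronic, overlap is any-base on closed intervals.
Codon-level consequences are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Union

import pandas as pd
from intervaltree import IntervalTree

from .io import GeneModel, SVRecord

__all__ = [
    "ImpactClass",
    "GeneIndex",
    "impact_class",
    "zygosity_summary",
    "size_summary",
]

IMPACT_VALUES = ("gene_level", "exonic", "intronic", "intergenic")
GENIC_IMPACTS = ("gene_level", "exonic", "intronic")


@dataclass
class ImpactClass:
    value: str
    gene_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.value not in IMPACT_VALUES:
            raise ValueError(f"unknown impact {self.value!r}")
        if (self.value == "intergenic") != (not self.gene_ids):
            raise ValueError("intergenic iff no overlapped genes")


class GeneIndex:
    """Interval index over gene spans for any-base overlap queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._trees: Dict[str, IntervalTree] = {}
        for g in self.genes:
            self._trees.setdefault(g.contig, IntervalTree()).addi(g.start, g.end + 1, g)

    def overlapping(self, contig: str, start: int, end: int) -> List[GeneModel]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        hits = {iv.data.gene_id: iv.data for iv in tree.overlap(start, end + 1)}
        return [hits[k] for k in sorted(hits)]


def _as_index(genes: Union[GeneIndex, Sequence[GeneModel]]) -> GeneIndex:
    return genes if isinstance(genes, GeneIndex) else GeneIndex(genes)


def impact_class(sv: SVRecord, genes: Union[GeneIndex, Sequence[GeneModel]]) -> ImpactClass:
    """Classify one SV's gene impact (see module docstring for the rules)."""
    index = _as_index(genes)

    if sv.svtype == "TRA":
        assert sv.mate is not None
        hits = index.overlapping(sv.contig, sv.start, sv.start)
        hits += [g for g in index.overlapping(sv.mate[0], sv.mate[1], sv.mate[1])
                 if g.gene_id not in {h.gene_id for h in hits}]
        if hits:
            return ImpactClass("gene_level", sorted(g.gene_id for g in hits))
        return ImpactClass("intergenic")

    hits = index.overlapping(sv.contig, sv.start, sv.end)
    if not hits:
        return ImpactClass("intergenic")
    ids = sorted(g.gene_id for g in hits)
    if any(sv.start <= g.start and g.end <= sv.end for g in hits):
        return ImpactClass("gene_level", ids)
    for g in hits:
        for es, ee in g.exons:
            if es <= sv.end and sv.start <= ee:
                return ImpactClass("exonic", ids)
    return ImpactClass("intronic", ids)


def zygosity_summary(records: Iterable[SVRecord]) -> pd.DataFrame:
    """Fraction of homozygous calls per (mapping category, SV type).

    Missing genotypes are excluded from the denominator; groups with no
    genotyped calls report NaN.
    """
    rows = []
    for r in records:
        rows.append((r.mapping_category, r.svtype, r.genotype))
    df = pd.DataFrame(rows, columns=["category", "svtype", "genotype"])
    if df.empty:
        return pd.DataFrame(columns=["category", "svtype", "n_total", "n_genotyped",
                                     "n_hom", "frac_hom"])
    out = []
    for (cat, svtype), grp in df.groupby(["category", "svtype"], sort=True):
        genotyped = grp[grp.genotype != "missing"]
        n_hom = int((genotyped.genotype == "hom").sum())
        frac = n_hom / len(genotyped) if len(genotyped) else float("nan")
        out.append((cat, svtype, len(grp), len(genotyped), n_hom, frac))
    return pd.DataFrame(out, columns=["category", "svtype", "n_total", "n_genotyped",
                                      "n_hom", "frac_hom"])


def _median_low(values: List[int]) -> int:
    vs = sorted(values)
    return vs[(len(vs) - 1) // 2]


def size_summary(records: Iterable[SVRecord]) -> pd.DataFrame:
    """Per-type call count and median SV length (lower-middle median).

    TRA calls are counted but carry no length, so their median is NaN.
    """
    by_type: Dict[str, List[int]] = {}
    counts: Dict[str, int] = {}
    for r in records:
        counts[r.svtype] = counts.get(r.svtype, 0) + 1
        if r.svtype != "TRA":
            by_type.setdefault(r.svtype, []).append(r.svlen)
    rows = []
    for svtype in sorted(counts):
        lens = by_type.get(svtype)
        med = float(_median_low(lens)) if lens else float("nan")
        rows.append((svtype, counts[svtype], med))
    return pd.DataFrame(rows, columns=["svtype", "n", "median_svlen"])
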