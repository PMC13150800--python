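"""Enhancer-motif scanning, region-set construction and density comparison.

Motifs are given as IUPAC consensus strings and matched exactly on both
strands (a deterministic stand-in for score-thresholded PWM scanning, which
keeps the density statistic well defined). Three genic-masked region sets
are compared: intergenic space, 50 kb flanks of any SV, and 50 kb flanks of
the fixed species-specific SVs. Motif density is hits per kbp per region;
groups of per-region densities are compared with a one-way ANOVA whose
p-value comes from the regularized incomplete beta function.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd
from scipy.special import betainc

from .intervals import clip_interval, merge_intervals, subtract_intervals, total_length
from .io import GeneModel, SVRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RegionSet",
    "scan_motifs",
    "build_region_sets",
    "density",
    "one_way_anova",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

MotifHit = Tuple[str, int, int, str]  # contig, start, end (1-based closed), strand

DEFAULT_FLANK = 50_000  # bp up- and downstream of an SV

REGION_LABELS = ("intergenic", "sv_flank", "fixed_sv_flank")


@dataclass
class RegionSet:
    """A labelled set of genic-masked regions (1-based closed intervals)."""

    label: str
    regions: List[Tuple[str, int, int]]

    @property
    def total_bp(self) -> int:
        return sum(e - s + 1 for _, s, e in self.regions)


def _iupac_regex(consensus: str) -> str:
    parts = []
    for ch in consensus.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} in consensus")
        code = IUPAC[ch]
        parts.append(code if len(code) == 1 else f"[{code}]")
    return "".join(parts)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def scan_motifs(genome: Mapping[str, str], consensus: str) -> List[MotifHit]:
    """All exact IUPAC matches of ``consensus`` on both strands.

    Overlapping hits are all reported (lookahead matching); reverse-strand
    hits are found by matching the reverse complement of the consensus on
    the forward sequence and reported with strand '-'.
    """
    if not consensus:
        raise ValueError("empty consensus")
    fwd = re.compile(f"(?=({_iupac_regex(consensus)}))")
    rev = re.compile(f"(?=({_iupac_regex(reverse_complement(consensus))}))")
    m = len(consensus)
    hits: List[MotifHit] = []
    for contig in sorted(genome):
        seq = genome[contig].upper()
        for match in fwd.finditer(seq):
            s = match.start() + 1
            hits.append((contig, s, s + m - 1, "+"))
        for match in rev.finditer(seq):
            s = match.start() + 1
            hits.append((contig, s, s + m - 1, "-"))
    hits.sort(key=lambda h: (h[0], h[1], h[3]))
    return hits


def _sv_interval(sv) -> Tuple[str, int, int]:
    if isinstance(sv, SVRecord):
        return (sv.contig, sv.start, sv.end)
    contig, s, e = sv  # plain (contig, start, end) triple
    return (str(contig), int(s), int(e))


def build_region_sets(
    genes: Sequence[GeneModel],
    all_svs: Sequence[SVRecord],
    fixed_svs: Sequence[SVRecord],
    contig_lengths: Mapping[str, int],
    flank: int = DEFAULT_FLANK,
) -> Dict[str, RegionSet]:
    """Build the three genic-masked region sets of the density comparison.

    ``intergenic`` is the genome minus gene spans; the two flank sets take
    ``flank`` bp up- and downstream of each SV (clipped at contig ends,
    merged within the set) minus gene spans.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    genes_by_contig: Dict[str, List[Tuple[int, int]]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.contig, []).append((g.start, g.end))

    def masked(label: str, raw_by_contig: Dict[str, List[Tuple[int, int]]]) -> RegionSet:
        regions = []
        for contig in sorted(raw_by_contig):
            kept = subtract_intervals(
                merge_intervals(raw_by_contig[contig]),
                genes_by_contig.get(contig, []),
            )
            regions.extend((contig, s, e) for s, e in kept)
        return RegionSet(label, regions)

    whole = {c: [(1, length)] for c, length in contig_lengths.items()}

    def flanks(svs: Sequence[SVRecord]) -> Dict[str, List[Tuple[int, int]]]:
        out: Dict[str, List[Tuple[int, int]]] = {}
        for sv in svs:
            contig, s, e = _sv_interval(sv)
            if contig not in contig_lengths:
                continue
            clipped = clip_interval(s - flank, e + flank, 1, contig_lengths[contig])
            if clipped:
                out.setdefault(contig, []).append(clipped)
        return out

    return {
        "intergenic": masked("intergenic", whole),
        "sv_flank": masked("sv_flank", flanks(all_svs)),
        "fixed_sv_flank": masked("fixed_sv_flank", flanks(fixed_svs)),
    }


def density(hits: Sequence[MotifHit], region_set: RegionSet) -> pd.DataFrame:
    """Per-region motif density (hits per kbp).

    A hit belongs to a region iff its start coordinate lies inside it, so a
    hit straddling a region boundary is never double counted.
    """
    starts_by_contig: Dict[str, List[int]] = {}
    for contig, s, _e, _strand in hits:
        starts_by_contig.setdefault(contig, []).append(s)
    for v in starts_by_contig.values():
        v.sort()
    import bisect

    rows = []
    for contig, s, e in region_set.regions:
        if e < s:
            logger.warning("skipping empty region %s:%d-%d", contig, s, e)
            continue
        starts = starts_by_contig.get(contig, [])
        n = bisect.bisect_right(starts, e) - bisect.bisect_left(starts, s)
        kbp = (e - s + 1) / 1000.0
        rows.append((region_set.label, contig, s, e, n, kbp, n / kbp))
    return pd.DataFrame(
        rows, columns=["label", "contig", "start", "end", "n_motifs", "kbp", "density"]
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """One-way fixed-effects ANOVA.

    F = [sum_g n_g (xbar_g - xbar)^2 / (k-1)] / [sum_gi (x_gi - xbar_g)^2 / (N-k)],
    with the p-value from the upper tail of F(k-1, N-k) via the regularized
    incomplete beta function. Degenerate inputs: zero within-group variance
    with non-zero between-group variance gives (inf, 0); all values
    identical gives (0, 1).
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    groups = [[float(x) for x in g] for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two values")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = sum(sum(g) for g in groups) / n_total
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0.0:
        return (float("inf"), 0.0) if ss_between > 0.0 else (0.0, 1.0)
    f = (ss_between / df1) / (ss_within / df2)
    # upper tail of F(df1, df2): I_{df2/(df2 + df1 F)}(df2/2, df1/2)
    p = float(betainc(df2 / 2.0, df1 / 2.0, df2 / (df2 + df1 * f)))
    return f, p


def group_densities(tables: Iterable[pd.DataFrame]) -> List[List[float]]:
    """Extract per-region density lists from :func:`density` tables."""
    return [list(t["density"].values) for t in tables]
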