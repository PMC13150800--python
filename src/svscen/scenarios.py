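"""Reciprocal-mapping scenario classification of population SVs.

Every fixed SV gets a 4-bit presence pattern over the mapping categories
(A2A, A2B, B2A, B2B): species A reads on reference A, species A reads on
reference B, and so on. The pattern determines the scenario:

=========  ====  ====  ====  ====  ================  =======
scenario   A2A   A2B   B2A   B2B   species-specific  species
=========  ====  ====  ====  ====  ================  =======
1           1     1     0     0    yes               A
2           0     0     1     1    yes               B
3           1     0     0     0    no (artefact)     -
4           0     1     0     0    yes               A
5           0     0     1     0    yes               B
6           0     0     0     1    no (artefact)     -
=========  ====  ====  ====  ====  ================  =======

Scenarios 3 and 6 (conspecific mapping only) indicate assembly artefacts or
singletons; an all-ones pattern is a shared SV; any other non-zero pattern
is conservatively "other" and never species-specific. Pattern bits are
computed from fixation-filtered sets, so bit 1 means "fixed in that
cohort-category". Everything is compared in genome-A coordinates: calls
made against reference B are lifted B->A first.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .annotate import GENIC_IMPACTS, GeneIndex, impact_class
from .io import MAPPING_CATEGORIES, SVRecord
from .liftover import AlignmentBlockMap, B_TO_A, LiftResult, lift_sv
from .merge import MergeParams, PopulationSV, cluster_calls, sv_equivalent

__all__ = [
    "ScenarioCall",
    "classify_pattern",
    "build_patterns",
    "species_specific_sets",
    "scenario_summary",
    "platform_overlap",
]

Scenario = Union[int, str]

_PATTERN_TABLE: Dict[Tuple[int, int, int, int], Tuple[Scenario, bool, str]] = {
    (1, 1, 0, 0): (1, True, "A"),
    (0, 0, 1, 1): (2, True, "B"),
    (1, 0, 0, 0): (3, False, "none"),
    (0, 1, 0, 0): (4, True, "A"),
    (0, 0, 1, 0): (5, True, "B"),
    (0, 0, 0, 1): (6, False, "none"),
    (1, 1, 1, 1): ("shared", False, "none"),
}

#: Scenarios whose SVs are considered species-specific.
SPECIES_SPECIFIC_SCENARIOS = (1, 2, 4, 5)
#: Conspecific-mapping-only scenarios (assembly artefacts / singletons).
ARTEFACT_SCENARIOS = (3, 6)


@dataclass
class ScenarioCall:
    """A population SV (genome-A coordinates) with its pattern and scenario."""

    sv: PopulationSV
    pattern: Tuple[bool, bool, bool, bool]
    scenario: Scenario
    species_specific: bool
    species: str  # {A, B, none}


def classify_pattern(pattern: Sequence) -> Tuple[Scenario, bool, str]:
    """Map a 4-bit (A2A, A2B, B2A, B2B) pattern to (scenario, specific, species).

    Total on the 15 non-zero patterns; the all-zero pattern is a precondition
    violation (an SV detected nowhere cannot exist).
    """
    if len(pattern) != 4:
        raise ValueError("pattern must have exactly 4 bits")
    key = tuple(int(bool(b)) for b in pattern)
    if key == (0, 0, 0, 0):
        raise ValueError("all-zero pattern: SV detected in no mapping category")
    return _PATTERN_TABLE.get(key, ("other", False, "none"))


def build_patterns(
    fixed_sets: Mapping[str, Sequence[PopulationSV]],
    block_map: AlignmentBlockMap,
    params: MergeParams,
) -> Tuple[List[ScenarioCall], Dict[str, List[Tuple[PopulationSV, str]]]]:
    """Cluster the four categories' fixed SV sets in genome-A coordinates.

    ``fixed_sets`` must hold all four mapping categories, each already passed
    through consensus and fixation filtering. A2B and B2B calls (reference-B
    coordinates) are lifted B->A; lift failures are returned per category and
    excluded from patterns. The pooled records are clustered with the merge
    equivalence; each cluster's pattern bit is 1 iff it contains a member
    from that category.
    """
    missing = [c for c in MAPPING_CATEGORIES if c not in fixed_sets]
    if missing:
        raise KeyError(f"missing mapping categories: {', '.join(missing)}")

    pooled: List[SVRecord] = []
    origin: Dict[int, Tuple[str, PopulationSV]] = {}
    failures: Dict[str, List[Tuple[PopulationSV, str]]] = {c: [] for c in MAPPING_CATEGORIES}

    for category in MAPPING_CATEGORIES:
        needs_lift = category in ("A2B", "B2B")
        for psv in fixed_sets[category]:
            rec = psv.representative
            if needs_lift:
                result: LiftResult = lift_sv(rec, block_map, B_TO_A)
                if not result.ok:
                    failures[category].append((psv, result.reason or "unmapped"))
                    continue
                rec = result.record
            rec = replace(rec, mapping_category=category)
            pooled.append(rec)
            origin[id(rec)] = (category, psv)

    calls: List[ScenarioCall] = []
    for cluster in cluster_calls(pooled, params):
        cats = set()
        members: List[SVRecord] = []
        samples = set()
        for rec in cluster.members:
            category, psv = origin[id(rec)]
            cats.add(category)
            members.extend(psv.members)
            samples |= psv.samples_present
        pattern = tuple(c in cats for c in MAPPING_CATEGORIES)
        scenario, specific, species = classify_pattern(pattern)
        merged = PopulationSV(
            representative=cluster.representative,
            members=sorted(members, key=SVRecord.sort_key),
            samples_present=samples,
        )
        calls.append(ScenarioCall(merged, pattern, scenario, specific, species))
    calls.sort(key=lambda c: c.sv.representative.sort_key())
    return calls, failures


def species_specific_sets(
    calls: Sequence[ScenarioCall],
    genes: Optional[Union[GeneIndex, Sequence]] = None,
) -> Dict[str, object]:
    """Split classified calls into per-species sets plus a scenario summary.

    Scenarios 3 and 6 (and shared/other patterns) are excluded from the
    species sets; the summary table mirrors the per-scenario tally layout
    (#SVs, per-type counts, #genes, exonic/intronic/gene-level impacts).
    """
    sets: Dict[str, List[ScenarioCall]] = {"A": [], "B": []}
    for call in calls:
        if call.species_specific:
            sets[call.species].append(call)
    summary = scenario_summary(
        [c for c in calls if c.scenario in SPECIES_SPECIFIC_SCENARIOS], genes
    )
    return {"A": sets["A"], "B": sets["B"], "summary": summary}


def scenario_summary(
    calls: Sequence[ScenarioCall],
    genes: Optional[Union[GeneIndex, Sequence]] = None,
) -> pd.DataFrame:
    """Per-scenario tallies: counts by type, overlapped genes, impact triple."""
    index = None
    if genes is not None:
        index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    scenarios = sorted({c.scenario for c in calls}, key=str)
    rows = []
    for scenario in scenarios:
        sub = [c for c in calls if c.scenario == scenario]
        type_counts = {t: 0 for t in ("DEL", "DUP", "INS", "INV", "TRA")}
        gene_ids = set()
        impacts = {"exonic": 0, "intronic": 0, "gene_level": 0}
        for c in sub:
            rep = c.sv.representative
            type_counts[rep.svtype] += 1
            if index is not None:
                imp = impact_class(rep, index)
                gene_ids.update(imp.gene_ids)
                if imp.value in impacts:
                    impacts[imp.value] += 1
        rows.append(
            (scenario, len(sub), *[type_counts[t] for t in ("DEL", "DUP", "INS", "INV", "TRA")],
             len(gene_ids), impacts["exonic"], impacts["intronic"], impacts["gene_level"])
        )
    return pd.DataFrame(
        rows,
        columns=["scenario", "n_svs", "DEL", "DUP", "INS", "INV", "TRA",
                 "n_genes", "exonic", "intronic", "gene_level"],
    )


def platform_overlap(
    set_sr: Sequence[ScenarioCall],
    set_lr: Sequence[ScenarioCall],
    params: MergeParams,
    genes: Union[GeneIndex, Sequence],
) -> List[Tuple[ScenarioCall, ScenarioCall]]:
    """Short-read/long-read overlap of species-specific calls per scenario.

    Pairs SR and LR calls of the same scenario whose representatives are
    equivalent under ``params``. Intergenic SVs are excluded: only calls
    whose gene impact is exonic, intronic or gene-level are compared.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)

    def genic(call: ScenarioCall) -> bool:
        return impact_class(call.sv.representative, index).value in GENIC_IMPACTS

    sr_genic = [c for c in set_sr if genic(c)]
    lr_genic = [c for c in set_lr if genic(c)]
    pairs: List[Tuple[ScenarioCall, ScenarioCall]] = []
    used_lr: set = set()
    for sc in sr_genic:
        for j, lc in enumerate(lr_genic):
            if j in used_lr or lc.scenario != sc.scenario:
                continue
            if sv_equivalent(sc.sv.representative, lc.sv.representative, params):
                pairs.append((sc, lc))
                used_lr.add(j)
                break
    return pairs
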