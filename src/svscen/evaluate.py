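"""Recovery metrics of classified calls against the planted truth.

Used by the test suite and the acceptance script: given the scenario calls
a pipeline run produced (genome-A coordinates) and the truth ledger of the
synthetic genomes, compute sensitivity / precision of the species-specific
sets, artefact capture and polymorphic leakage, with matching done under the
same SV-equivalence relation the merge stage uses.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

from .io import SVRecord
from .merge import MergeParams, sv_equivalent
from .scenarios import ARTEFACT_SCENARIOS, ScenarioCall
from .simulate import TruthRecord

__all__ = ["truth_a_record", "match_truth", "recovery_metrics"]


def truth_a_record(tr: TruthRecord) -> Optional[SVRecord]:
    """The planted SV as an SVRecord in genome-A coordinates (None if unanchored)."""
    if tr.a_interval is None:
        return None
    contig, start, end = tr.a_interval
    if tr.svtype == "TRA":
        from .io import canonical_breakends

        if tr.a_mate is None:
            return None
        contig, start, mate = canonical_breakends(contig, start, tr.a_mate)
        return SVRecord(contig=contig, start=start, end=start, svtype="TRA",
                        svlen=0, mate=mate)
    return SVRecord(contig=contig, start=start, end=end, svtype=tr.svtype, svlen=tr.svlen)


def match_truth(
    calls: Sequence[ScenarioCall],
    truth: Sequence[TruthRecord],
    params: MergeParams,
) -> Dict[str, Optional[ScenarioCall]]:
    """Greedy 1:1 matching of truth records to calls under sv_equivalent."""
    used = set()
    out: Dict[str, Optional[ScenarioCall]] = {}
    for tr in truth:
        rec = truth_a_record(tr)
        out[tr.sv_id] = None
        if rec is None:
            continue
        for i, call in enumerate(calls):
            if i in used:
                continue
            if sv_equivalent(rec, call.sv.representative, params):
                out[tr.sv_id] = call
                used.add(i)
                break
    return out


def recovery_metrics(
    calls: Sequence[ScenarioCall],
    truth: Sequence[TruthRecord],
    params: MergeParams,
) -> Dict[str, object]:
    """Sensitivity/precision of the species-specific sets and artefact capture.

    * sensitivity — fraction of planted fixed SVs matched by a
      species-specific call of the correct species;
    * specificity — fraction of species-specific calls matching a planted
      fixed SV of that species (1.0 when there are no calls);
    * scenario_accuracy — among matched fixed SVs, fraction whose scenario
      equals the planted expectation;
    * artefact capture — planted artefacts recovered in scenarios 3/6, and
      whether any non-artefact call landed there;
    * polymorphic_leaks — polymorphic planted SVs that reached a
      species-specific set (must be 0: they can never be fixed).
    """
    fixed = [tr for tr in truth if tr.is_fixed]
    artefacts = [tr for tr in truth if tr.is_artefact]
    poly = [tr for tr in truth if tr.origin == "polymorphic"]

    specific_calls = [c for c in calls if c.species_specific]
    artefact_calls = [c for c in calls if c.scenario in ARTEFACT_SCENARIOS]

    fixed_matches = match_truth(specific_calls, fixed, params)
    n_hit = 0
    n_scenario_ok = 0
    for tr in fixed:
        call = fixed_matches[tr.sv_id]
        if call is not None and call.species == tr.species:
            n_hit += 1
            if call.scenario == tr.expected_scenario:
                n_scenario_ok += 1
    sensitivity = n_hit / len(fixed) if fixed else 1.0
    scenario_accuracy = n_scenario_ok / n_hit if n_hit else 1.0

    # precision: every species-specific call should correspond to a planted fixed SV
    matched_call_ids = {id(c) for c in fixed_matches.values() if c is not None}
    specificity = (
        sum(1 for c in specific_calls if id(c) in matched_call_ids) / len(specific_calls)
        if specific_calls else 1.0
    )

    art_matches = match_truth(artefact_calls, artefacts, params)
    n_art_hit = sum(1 for v in art_matches.values() if v is not None)
    artefact_sensitivity = n_art_hit / len(artefacts) if artefacts else 1.0
    matched_art_ids = {id(c) for c in art_matches.values() if c is not None}
    artefact_exact = all(id(c) in matched_art_ids for c in artefact_calls)

    poly_matches = match_truth(specific_calls, poly, params)
    polymorphic_leaks = sum(1 for v in poly_matches.values() if v is not None)

    return {
        "n_fixed_planted": len(fixed),
        "n_species_specific_called": len(specific_calls),
        "sensitivity": sensitivity,
        "specificity": specificity,
        "scenario_accuracy": scenario_accuracy,
        "artefact_sensitivity": artefact_sensitivity,
        "artefact_calls_all_planted": artefact_exact,
        "polymorphic_leaks": polymorphic_leaks,
    }
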