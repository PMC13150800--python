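"""Detection-pattern scenario classification and species-specific set building."""

import itertools

import pytest

from svscen.io import AlignmentBlock, GeneModel, SVRecord
from svscen.liftover import AlignmentBlockMap
from svscen.merge import MergeParams, cluster_calls
from svscen.scenarios import (
    build_patterns,
    classify_pattern,
    platform_overlap,
    species_specific_sets,
)


class TestClassifyPattern:
    @pytest.mark.parametrize("pattern,expected", [
        ((1, 1, 0, 0), (1, True, "A")),
        ((0, 0, 1, 1), (2, True, "B")),
        ((1, 0, 0, 0), (3, False, "none")),
        ((0, 1, 0, 0), (4, True, "A")),
        ((0, 0, 1, 0), (5, True, "B")),
        ((0, 0, 0, 1), (6, False, "none")),
    ])
    def test_six_table_rows(self, pattern, expected):
        assert classify_pattern(pattern) == expected

    def test_present_everywhere_is_shared_not_specific(self):
        assert classify_pattern((1, 1, 1, 1)) == ("shared", False, "none")

    def test_exhaustive_fifteen_nonzero_patterns_total_and_deterministic(self):
        table_rows = {(1, 1, 0, 0), (0, 0, 1, 1), (1, 0, 0, 0), (0, 1, 0, 0),
                      (0, 0, 1, 0), (0, 0, 0, 1), (1, 1, 1, 1)}
        for pattern in itertools.product((0, 1), repeat=4):
            if pattern == (0, 0, 0, 0):
                continue
            first = classify_pattern(pattern)
            assert first == classify_pattern(pattern)
            if pattern not in table_rows:
                assert first == ("other", False, "none")
            scenario, specific, species = first
            assert specific == (scenario in (1, 2, 4, 5))
            if scenario in (1, 4):
                assert species == "A"
            elif scenario in (2, 5):
                assert species == "B"
            else:
                assert species == "none"

    def test_all_zero_pattern_rejected(self):
        with pytest.raises(ValueError):
            classify_pattern((0, 0, 0, 0))


def _psv(records, params):
    (cluster,) = cluster_calls(records, params)
    return cluster


@pytest.fixture
def identity_map():
    # both genomes co-linear on one contig
    return AlignmentBlockMap([AlignmentBlock("ctg1", 1, 100_000, "ctg1", 1, 100_000, "+")])


class TestBuildPatterns:
    def test_missing_category_is_hard_error(self, identity_map, params):
        with pytest.raises(KeyError, match="B2B"):
            build_patterns({"A2A": [], "A2B": [], "B2A": []}, identity_map, params)

    def test_four_empty_sets_give_empty_output(self, identity_map, params):
        calls, failures = build_patterns(
            {c: [] for c in ("A2A", "A2B", "B2A", "B2B")}, identity_map, params)
        assert calls == [] and all(v == [] for v in failures.values())

    def test_sv_in_a2a_and_lifted_a2b_gets_scenario_one(self, identity_map, params):
        a2a = _psv([SVRecord("ctg1", 5000, 5400, "DEL", 400, sample="a1",
                             mapping_category="A2A")], params)
        a2b = _psv([SVRecord("ctg1", 5010, 5395, "DEL", 385, sample="a1",
                             mapping_category="A2B")], params)
        calls, failures = build_patterns(
            {"A2A": [a2a], "A2B": [a2b], "B2A": [], "B2B": []}, identity_map, params)
        assert len(calls) == 1
        assert calls[0].pattern == (True, True, False, False)
        assert (calls[0].scenario, calls[0].species) == (1, "A")

    def test_lift_failure_reported_and_excluded(self, params):
        bm = AlignmentBlockMap([AlignmentBlock("ctg1", 1, 1000, "ctg1", 1, 1000, "+")])
        far = _psv([SVRecord("ctg1", 50_000, 50_400, "DEL", 400, sample="b1",
                             mapping_category="B2B")], params)
        calls, failures = build_patterns(
            {"A2A": [], "A2B": [], "B2A": [], "B2B": [far]}, bm, params)
        assert calls == []
        assert len(failures["B2B"]) == 1


class TestSpeciesSpecificSets:
    def test_artefact_scenarios_excluded_from_species_files(self, identity_map, params):
        a2a_only = _psv([SVRecord("ctg1", 5000, 5400, "DEL", 400, sample="a1",
                                  mapping_category="A2A")], params)
        a2b_only = _psv([SVRecord("ctg1", 20_000, 20_000, "INS", 200, sample="a1",
                                  mapping_category="A2B")], params)
        calls, _ = build_patterns(
            {"A2A": [a2a_only], "A2B": [a2b_only], "B2A": [], "B2B": []},
            identity_map, params)
        scenarios = {c.scenario for c in calls}
        assert scenarios == {3, 4}
        sets = species_specific_sets(calls)
        assert [c.scenario for c in sets["A"]] == [4]
        assert sets["B"] == []
        assert list(sets["summary"]["scenario"]) == [4]

    def test_empty_input_gives_empty_sets_and_table(self):
        sets = species_specific_sets([])
        assert sets["A"] == [] and sets["B"] == []
        assert len(sets["summary"]) == 0

    def test_summary_layout(self, identity_map, params):
        a2b = _psv([SVRecord("ctg1", 5000, 5400, "DEL", 400, sample="a1",
                             mapping_category="A2B")], params)
        calls, _ = build_patterns(
            {"A2A": [], "A2B": [a2b], "B2A": [], "B2B": []}, identity_map, params)
        genes = [GeneModel("g1", "ctg1", 4000, 6000, exons=[(4000, 4100)])]
        sets = species_specific_sets(calls, genes)
        row = sets["summary"].iloc[0]
        assert list(sets["summary"].columns) == [
            "scenario", "n_svs", "DEL", "DUP", "INS", "INV", "TRA",
            "n_genes", "exonic", "intronic", "gene_level"]
        assert (row["scenario"], row["n_svs"], row["DEL"], row["n_genes"]) == (4, 1, 1, 1)
        assert row["intronic"] == 1  # overlaps the gene body, no exon


class TestPlatformOverlap:
    def _calls(self, start, params, identity_map, category="A2B"):
        psv = _psv([SVRecord("ctg1", start, start + 400, "DEL", 400, sample="x",
                             mapping_category=category)], params)
        calls, _ = build_patterns(
            {"A2A": [], "A2B": [psv], "B2A": [], "B2B": []}, identity_map, params)
        return calls

    def test_identical_sets_fully_overlap(self, identity_map, params):
        genes = [GeneModel("g1", "ctg1", 4000, 6000, exons=[])]
        sr = self._calls(5000, params, identity_map)
        lr = self._calls(5005, params, identity_map)
        pairs = platform_overlap(sr, lr, params, genes)
        assert len(pairs) == 1

    def test_disjoint_coordinates_no_overlap(self, identity_map, params):
        genes = [GeneModel("g1", "ctg1", 1, 90_000, exons=[])]
        sr = self._calls(5000, params, identity_map)
        lr = self._calls(50_000, params, identity_map)
        assert platform_overlap(sr, lr, params, genes) == []

    def test_intergenic_calls_excluded(self, identity_map, params):
        sr = self._calls(5000, params, identity_map)
        lr = self._calls(5005, params, identity_map)
        assert platform_overlap(sr, lr, params, genes=[]) == []


class TestEndToEndTruth:
    def test_noise_free_patterns_match_planted_truth_everywhere(self, noise_free_run):
        """With zero noise the classifier reproduces every planted scenario."""
        from svscen.evaluate import match_truth

        for pr in noise_free_run.platforms.values():
            truth = [t for t in noise_free_run.planted.truth
                     if t.is_fixed or t.is_artefact]
            matches = match_truth(pr.calls, truth, noise_free_run.params)
            for tr in truth:
                call = matches[tr.sv_id]
                assert call is not None, tr.sv_id
                assert call.scenario == tr.expected_scenario
                assert call.pattern == tr.expected_pattern
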