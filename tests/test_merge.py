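"""Consensus clustering and the support / concordance / fixation filters."""

import numpy as np
import pytest

from conftest import random_records
from svscen.io import SVRecord
from svscen.merge import (
    MergeParams,
    cluster_calls,
    consensus_filter,
    fixation_filter,
    population_merge,
    reciprocal_overlap,
    sv_equivalent,
)


def D(start, end, caller="c1", sample="s1", support=10):
    return SVRecord("ctg1", start, end, "DEL", end - start, support=support,
                    caller=caller, sample=sample, genotype="hom")


def brute_force_components(records, params):
    """Independent oracle: BFS over the all-pairs equivalence graph."""
    n = len(records)
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        comp, stack = [], [i]
        seen[i] = True
        while stack:
            k = stack.pop()
            comp.append(k)
            for j in range(n):
                if not seen[j] and sv_equivalent(records[k], records[j], params):
                    seen[j] = True
                    stack.append(j)
        comps.append(frozenset(comp))
    return set(comps)


def sweep_components(records, params):
    clusters = cluster_calls(records, params)
    index = {id(r): i for i, r in enumerate(records)}
    return {frozenset(index[id(m)] for m in c.members) for c in clusters}


class TestEquivalence:
    def test_nearby_deletions_with_high_overlap_are_equivalent(self, params):
        a, b = D(100, 400), D(150, 420)
        assert reciprocal_overlap(a, b) == pytest.approx(251 / 301)
        assert sv_equivalent(a, b, params)

    def test_type_mismatch_never_equivalent(self, params):
        ins = SVRecord("ctg1", 100, 100, "INS", 300)
        assert not sv_equivalent(D(100, 400), ins, params)

    def test_distant_calls_not_equivalent(self, params):
        assert not sv_equivalent(D(100, 400), D(10_000, 10_300), params)

    def test_insertion_length_ratio(self, params):
        a = SVRecord("ctg1", 100, 100, "INS", 100)
        b = SVRecord("ctg1", 120, 120, "INS", 55)
        c = SVRecord("ctg1", 120, 120, "INS", 45)
        assert sv_equivalent(a, b, params)       # 55/100 >= 0.5
        assert not sv_equivalent(a, c, params)   # 45/100 < 0.5

    def test_tra_requires_both_breakends_close(self, params):
        a = SVRecord("ctg1", 100, 100, "TRA", 0, mate=("ctg2", 5000))
        b = SVRecord("ctg1", 300, 300, "TRA", 0, mate=("ctg2", 5200))
        c = SVRecord("ctg1", 300, 300, "TRA", 0, mate=("ctg2", 9000))
        assert sv_equivalent(a, b, params)
        assert not sv_equivalent(a, c, params)


class TestClustering:
    def test_single_linkage_chains_transitively(self, params):
        # A~B and B~C but A and C are beyond the breakpoint tolerance
        a, b, c = D(1000, 3000), D(1400, 3400), D(1800, 3800)
        assert sv_equivalent(a, b, params) and sv_equivalent(b, c, params)
        assert not sv_equivalent(a, c, params)
        clusters = cluster_calls([a, b, c], params)
        assert len(clusters) == 1 and len(clusters[0].members) == 3

    def test_empty_input(self, params):
        assert cluster_calls([], params) == []

    def test_two_callers_one_cluster(self, params):
        clusters = cluster_calls([D(100, 400, caller="delly"),
                                  D(100, 400, caller="manta")], params)
        assert len(clusters) == 1
        assert clusters[0].callers_present == {"delly", "manta"}

    def test_representative_uses_lower_middle_median(self, params):
        clusters = cluster_calls([D(100, 400), D(120, 420), D(140, 440), D(160, 460)],
                                 params)
        rep = clusters[0].representative
        assert (rep.start, rep.end) == (120, 420)

    @pytest.mark.parametrize("seed", range(8))
    def test_sweep_equals_brute_force_components(self, params, seed):
        rng = np.random.default_rng(seed)
        records = random_records(rng, 120, span_max=30_000)
        assert sweep_components(records, params) == brute_force_components(records, params)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_clustering_is_idempotent_on_representatives(self, params, seed):
        rng = np.random.default_rng(seed)
        records = random_records(rng, 80, span_max=20_000)
        clusters = cluster_calls(records, params)
        again = cluster_calls([c.representative for c in clusters], params)
        assert len(again) == len(clusters)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_larger_tolerance_never_increases_cluster_count(self, seed):
        rng = np.random.default_rng(seed)
        records = random_records(rng, 100, span_max=20_000)
        counts = [
            len(cluster_calls(records, MergeParams(max_breakpoint_dist=d)))
            for d in (100, 500, 2000)
        ]
        assert counts == sorted(counts, reverse=True)


class TestConsensusFilter:
    def _cluster(self, callers, support, params):
        recs = [D(100, 400, caller=c, support=support) for c in callers]
        return cluster_calls(recs, params)

    def test_single_caller_cluster_dropped(self, params):
        assert consensus_filter(self._cluster(["delly"], 20, params), params) == []

    def test_support_exactly_at_threshold_dropped(self, params):
        # the support rule is strict: 5 is not > 5
        clusters = self._cluster(["delly", "manta"], 5, params)
        assert consensus_filter(clusters, params) == []

    def test_support_one_above_threshold_kept(self, params):
        clusters = self._cluster(["delly", "manta"], 6, params)
        assert len(consensus_filter(clusters, params)) == 1


class TestPopulationAndFixation:
    def test_shared_deletion_collects_all_samples(self, params):
        per_sample = [
            cluster_calls([D(100, 400, sample=s, caller="c1"),
                           D(100, 400, sample=s, caller="c2")], params)
            for s in ("s1", "s2", "s3")
        ]
        merged = population_merge(per_sample, params)
        assert len(merged) == 1
        assert merged[0].samples_present == {"s1", "s2", "s3"}

    def test_disjoint_sample_calls_stay_separate(self, params):
        per_sample = [cluster_calls([D(100, 400, sample="s1")], params),
                      cluster_calls([D(50_000, 50_300, sample="s2")], params)]
        merged = population_merge(per_sample, params)
        assert len(merged) == 2

    def test_population_merge_matches_brute_force_on_random_records(self, params):
        rng = np.random.default_rng(42)
        records = random_records(rng, 50, span_max=15_000)
        by_sample = {}
        for r in records:
            by_sample.setdefault(r.sample, []).append(r)
        per_sample = [cluster_calls(v, params) for _k, v in sorted(by_sample.items())]
        merged = population_merge(per_sample, params)
        # all original members survive the two-level merge exactly once
        members = [id(m) for c in merged for m in c.members]
        assert sorted(members) == sorted(id(r) for r in records)
        # without consensus filtering, the two-level merge equals direct
        # single-linkage components over all raw records
        index = {id(r): i for i, r in enumerate(records)}
        got = {frozenset(index[id(m)] for m in c.members) for c in merged}
        assert got == brute_force_components(records, params)

    def test_almost_fixed_sv_dropped(self, params):
        cohort = {f"s{i}" for i in range(22)}
        present = cohort - {"s21"}
        psv = cluster_calls([D(100, 400, sample=s) for s in sorted(present)], params)
        assert fixation_filter(psv, cohort) == []

    def test_fully_fixed_sv_kept(self, params):
        cohort = {f"s{i}" for i in range(4)}
        psv = cluster_calls([D(100, 400, sample=s) for s in sorted(cohort)], params)
        assert len(fixation_filter(psv, cohort)) == 1

    def test_empty_cohort_rejected(self, params):
        with pytest.raises(ValueError):
            fixation_filter([], set())

    def test_consensus_and_fixation_filters_commute(self, params):
        rng = np.random.default_rng(7)
        records = random_records(rng, 100, span_max=10_000)
        clusters = cluster_calls(records, params)
        cohort = {"s1", "s2"}
        a = fixation_filter(consensus_filter(clusters, params), cohort)
        b = consensus_filter(fixation_filter(clusters, cohort), params)
        assert a == b
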