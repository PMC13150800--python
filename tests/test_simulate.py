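"""Synthetic genome generator: planting, noise model, annotation layer."""

from collections import Counter

import numpy as np
import pytest

from conftest import small_config
from svscen.annotate import GeneIndex
from svscen.intervals import subtract_intervals, total_length
from svscen.simulate import (
    PlacementError,
    SimConfig,
    emit_annotation,
    emit_callsets,
    plant_svs,
    simulate_all,
    simulate_ancestral,
)


class TestAncestral:
    def test_zero_gc_forces_at_only(self):
        cfg = small_config(contig_length=10_000, gc_fraction=0.0, n_fixed_sv_per_species=0,
                           n_polymorphic_sv=0, n_artefact_sv=0)
        genome = simulate_ancestral(cfg)
        assert len(genome) == 2
        assert all(set(seq) <= {"A", "T"} for seq in genome.values())

    def test_same_seed_identical_sequences(self):
        cfg = small_config(seed=7)
        assert simulate_ancestral(cfg) == simulate_ancestral(cfg)

    def test_gc_concentrates_at_configured_value(self):
        cfg = small_config(contig_length=1_000_000, gc_fraction=0.5, n_contigs=1)
        (seq,) = simulate_ancestral(cfg).values()
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.48 <= gc <= 0.52

    def test_invalid_config_names_the_field(self):
        with pytest.raises(ValueError, match="gc_fraction"):
            small_config(gc_fraction=1.5)
        with pytest.raises(ValueError, match="sv_type_weights"):
            small_config(sv_type_weights={"DEL": 0.9})
        with pytest.raises(ValueError, match="fn_rate"):
            small_config(fn_rate=-0.1)


class TestPlanting:
    def test_no_svs_means_identical_references_one_block_per_contig(self):
        cfg = small_config(n_fixed_sv_per_species=0, n_polymorphic_sv=0, n_artefact_sv=0)
        genome = simulate_ancestral(cfg)
        planted = plant_svs(genome, cfg)
        assert planted.ref_a == genome and planted.ref_b == genome
        assert len(planted.blocks) == cfg.n_contigs
        for block in planted.blocks:
            assert (block.start_a, block.end_a) == (1, cfg.contig_length)
            assert block.strand == "+"

    def test_truth_scenario_histogram_matches_config(self):
        cfg = small_config()
        planted = plant_svs(simulate_ancestral(cfg), cfg)
        hist = Counter(t.expected_scenario for t in planted.truth)
        assert hist[1] + hist[4] == cfg.n_fixed_sv_per_species          # species A
        assert hist[2] + hist[5] == cfg.n_fixed_sv_per_species          # species B
        assert hist[3] + hist[6] == cfg.n_artefact_sv
        assert hist["other"] == cfg.n_polymorphic_sv

    def test_all_five_types_represented_per_species(self):
        cfg = small_config()
        planted = plant_svs(simulate_ancestral(cfg), cfg)
        for species in "AB":
            types = {t.svtype for t in planted.truth
                     if t.is_fixed and t.species == species}
            assert types == {"DEL", "DUP", "INS", "INV", "TRA"}

    def test_reference_length_conservation(self):
        """len(ref_A) - len(ref_B) per contig equals the signed sum of
        length-changing edits applied to each lineage (oracle from truth)."""
        cfg = small_config(seed=3)
        genome = simulate_ancestral(cfg)
        planted = plant_svs(genome, cfg)
        delta = {c: {"A": 0, "B": 0} for c in genome}
        for t in planted.truth:
            if not t.in_ref:
                continue
            ref = t.species
            if t.is_artefact:
                # reference edit is the inverse of the observed type
                signed = {"DEL": +t.svlen, "INS": -t.svlen}.get(t.svtype, 0)
            else:
                signed = {"DEL": -t.svlen, "INS": +t.svlen, "DUP": +t.svlen}.get(t.svtype, 0)
            delta[t.contig][ref] += signed
        for contig in genome:
            expected = delta[contig]["A"] - delta[contig]["B"]
            assert len(planted.ref_a[contig]) - len(planted.ref_b[contig]) == expected

    def test_polymorphic_carriers_are_strict_subsets(self):
        cfg = small_config()
        planted = plant_svs(simulate_ancestral(cfg), cfg)
        for t in planted.truth:
            if t.origin != "polymorphic":
                continue
            for (species, platform), carriers in t.carriers.items():
                n = cfg.samples_per_species[species][platform]
                assert 0 < len(carriers) < n or (n <= 1 and len(carriers) == 0)

    def test_genome_too_small_raises_placement_error(self):
        cfg = small_config(contig_length=10_000, n_fixed_sv_per_species=40)
        with pytest.raises(PlacementError):
            plant_svs(simulate_ancestral(cfg), cfg)


class TestCallsetEmission:
    def test_noise_free_callsets_are_exact_truth_projection(self):
        cfg = small_config()
        planted = plant_svs(simulate_ancestral(cfg), cfg)
        callsets = emit_callsets(planted.truth, planted.ref_a, planted.ref_b, cfg)
        coords_by_cat = {}
        for t in planted.truth:
            for cat, (contig, s, e, _m) in t.category_coords.items():
                coords_by_cat.setdefault(cat, set()).add((contig, s, e, t.svtype))
        for (platform, sample, _caller, cat), records in callsets.items():
            for r in records:
                key = (r.contig, r.start, r.end if r.svtype != "TRA" else r.start, r.svtype)
                lookup = {(c, s, e if t != "TRA" else s, t)
                          for (c, s, e, t) in coords_by_cat.get(cat, set())}
                # TRA records may be breakend-swapped into canonical order
                if r.svtype == "TRA":
                    ok = any(t == "TRA" and ((c, s) == (r.contig, r.start)
                                             or (c, s) == r.mate)
                             for (c, s, e, t) in coords_by_cat.get(cat, set()))
                    assert ok, r
                else:
                    assert key in lookup, r

    def test_total_fn_rate_empties_every_callset(self):
        cfg = small_config(fn_rate=1.0)
        planted = plant_svs(simulate_ancestral(cfg), cfg)
        callsets = emit_callsets(planted.truth, planted.ref_a, planted.ref_b, cfg)
        assert all(recs == [] for recs in callsets.values())

    def test_breakpoint_jitter_has_half_normal_magnitude(self):
        """jitter_sd = 10 -> mean |called - true| near 10*sqrt(2/pi) ~ 8."""
        cfg = small_config(
            n_fixed_sv_per_species=100, n_polymorphic_sv=0, n_artefact_sv=0,
            sv_type_weights={"DEL": 1.0}, fixed_in_ref_fraction=0.0,
            contig_length=2_000_000, breakpoint_jitter_sd=10.0,
            samples_per_species={"A": {"SR": 1, "LR": 0}, "B": {"SR": 1, "LR": 0}},
        )
        planted = plant_svs(simulate_ancestral(cfg), cfg)
        callsets = emit_callsets(planted.truth, planted.ref_a, planted.ref_b, cfg)
        true_starts = {}
        for t in planted.truth:
            for cat, (contig, s, _e, _m) in t.category_coords.items():
                true_starts.setdefault(cat, []).append((contig, s))
        deviations = []
        for (_p, _s, _c, cat), records in callsets.items():
            for r in records:
                nearest = min(abs(r.start - s) for c, s in true_starts[cat] if c == r.contig)
                deviations.append(nearest)
        assert len(deviations) > 500
        assert 6.0 <= float(np.mean(deviations)) <= 10.0

    def test_deterministic_byte_identical_outputs(self, tmp_path):
        cfg = small_config(contig_length=60_000, n_fixed_sv_per_species=3,
                           n_polymorphic_sv=2, n_artefact_sv=2,
                           fn_rate=0.1, fp_rate_per_mbp=1.0, breakpoint_jitter_sd=5.0)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        simulate_all(cfg, out1)
        simulate_all(cfg, out2)
        files1 = sorted(p.relative_to(out1) for p in out1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(out2) for p in out2.rglob("*") if p.is_file())
        assert files1 == files2 and len(files1) > 10
        for rel in files1:
            assert (out1 / rel).read_bytes() == (out2 / rel).read_bytes(), rel


class TestAnnotationLayer:
    def test_fraction_genic_zero_keeps_all_svs_intergenic(self):
        cfg = small_config(fraction_genic=0.0)
        planted = plant_svs(simulate_ancestral(cfg), cfg)
        ann = emit_annotation(planted.ref_a, planted.ref_b, planted.truth, cfg)
        index = GeneIndex(ann.genes)
        for t in planted.truth:
            if t.a_interval is None:
                continue
            contig, s, e = t.a_interval
            assert index.overlapping(contig, s, e) == [], t.sv_id

    def test_planted_motif_densities_recovered_on_partition(self):
        """Poisson planting at 2.0 / 1.0 / 0.5 per kbp is recovered within
        15% on each exclusive region class at megabase scale."""
        cfg = small_config(
            contig_length=1_500_000, n_fixed_sv_per_species=3, n_polymorphic_sv=2,
            n_artefact_sv=0, n_genes=10, seed=9,
        )
        planted = plant_svs(simulate_ancestral(cfg), cfg)
        ann = emit_annotation(planted.ref_a, planted.ref_b, planted.truth, cfg)
        from svscen.motifs import build_region_sets

        all_iv = [t.a_interval for t in planted.truth if t.a_interval]
        fixed_iv = [t.a_interval for t in planted.truth if t.is_fixed and t.a_interval]
        sets = build_region_sets(ann.genes, all_iv, fixed_iv,
                                 planted.contig_lengths_a, flank=cfg.flank)

        def by_contig(rs):
            d = {}
            for c, s, e in rs.regions:
                d.setdefault(c, []).append((s, e))
            return d

        fixed_r = by_contig(sets["fixed_sv_flank"])
        sv_r = by_contig(sets["sv_flank"])
        inter_r = by_contig(sets["intergenic"])
        partition = {"fixed": [], "sv_only": [], "inter_only": []}
        for c in planted.contig_lengths_a:
            partition["fixed"] += [(c, s, e) for s, e in fixed_r.get(c, [])]
            partition["sv_only"] += [
                (c, s, e) for s, e in subtract_intervals(sv_r.get(c, []), fixed_r.get(c, []))]
            partition["inter_only"] += [
                (c, s, e) for s, e in subtract_intervals(inter_r.get(c, []), sv_r.get(c, []))]
        starts = {}
        for c, s, _e, _n, _st in ann.motif_hits:
            starts.setdefault(c, []).append(s)
        recovered = {}
        for label, regions in partition.items():
            bp = total_length([(s, e) for _c, s, e in regions])
            n = sum(1 for c, s, e in regions for h in starts.get(c, []) if s <= h <= e)
            recovered[label] = (bp, n / (bp / 1000.0))
        assert recovered["fixed"][0] >= 400_000
        assert recovered["inter_only"][0] >= 1_000_000
        assert abs(recovered["fixed"][1] - 0.5) / 0.5 <= 0.15
        assert abs(recovered["inter_only"][1] - 2.0) / 2.0 <= 0.15
        # the intermediate class sits strictly between the two extremes
        assert recovered["fixed"][1] < recovered["sv_only"][1] < recovered["inter_only"][1]

    def test_gene_ledger_relations_match_impact_classifier(self):
        cfg = small_config(fraction_genic=1.0)
        planted = plant_svs(simulate_ancestral(cfg), cfg)
        ann = emit_annotation(planted.ref_a, planted.ref_b, planted.truth, cfg)
        from svscen.annotate import impact_class
        from svscen.evaluate import truth_a_record

        index = GeneIndex(ann.genes)
        truth = {t.sv_id: t for t in planted.truth}
        assert len(ann.gene_ledger) > 0
        for row in ann.gene_ledger.itertuples(index=False):
            rec = truth_a_record(truth[row.sv_id])
            imp = impact_class(rec, index)
            assert imp.value == row.relation, (row.sv_id, imp.value, row.relation)
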