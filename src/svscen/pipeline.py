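"""End-to-end orchestration: simulate -> merge -> lift -> classify -> annotate -> motifs.

``run_synthetic_pipeline`` drives everything in memory from a
:class:`~svscen.simulate.SimConfig`; ``run_pipeline`` additionally writes
each stage's outputs (FASTA/VCF/TSV) plus a JSON manifest with checksums,
so a rerun with the same configuration is bytewise identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import annotate, motifs
from .evaluate import recovery_metrics
from .io import (
    MAPPING_CATEGORIES,
    SVRecord,
    write_alignment_coords,
    write_bed,
    write_fasta,
    write_gff3,
    write_population_vcf,
)
from .merge import (
    MergeParams,
    PopulationSV,
    cluster_calls,
    consensus_filter,
    fixation_filter,
    population_merge,
)
from .scenarios import (
    ScenarioCall,
    build_patterns,
    platform_overlap,
    scenario_summary,
    species_specific_sets,
)
from .simulate import (
    PLATFORMS,
    SPECIES,
    PlantResult,
    SimConfig,
    cohort,
    emit_annotation,
    emit_callsets,
    plant_svs,
    simulate_ancestral,
    write_truth,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ConfigError",
    "PlatformResult",
    "PipelineResult",
    "validate_config",
    "run_synthetic_pipeline",
    "run_pipeline",
]


class ConfigError(ValueError):
    """Raised with the list of problems found while validating a run config."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass
class RunConfig:
    """One document configuring a full synthetic run."""

    sim: SimConfig = field(default_factory=SimConfig)
    merge: MergeParams = field(default_factory=MergeParams)
    platforms: Tuple[str, ...] = PLATFORMS
    motif_consensus: Optional[str] = None  # IUPAC; None -> use planted motif BED
    write_callset_vcfs: bool = False


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run config; all problems are reported at once."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    errors: List[str] = []
    known = {"seed", "simulate", "merge", "platforms", "motif_consensus",
             "write_callset_vcfs"}
    for key in doc:
        if key not in known:
            errors.append(f"unknown config key {key!r}")
    sim_kwargs = dict(doc.get("simulate") or {})
    if "seed" in doc:
        sim_kwargs["seed"] = doc["seed"]
    sim = merge_params = None
    try:
        sim = SimConfig(**sim_kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"simulate: {exc}")
    try:
        merge_params = MergeParams(**(doc.get("merge") or {}))
    except (TypeError, ValueError) as exc:
        errors.append(f"merge: {exc}")
    platforms = tuple(doc.get("platforms", PLATFORMS))
    for p in platforms:
        if p not in PLATFORMS:
            errors.append(f"unknown platform {p!r}")
    if sim is not None:
        for platform in platforms:
            cohorts = [cohort(sim, sp, platform) for sp in SPECIES]
            names = [n for c in cohorts for n in c]
            if len(names) != len(set(names)):
                errors.append(f"cohorts overlap on platform {platform}")
    if errors:
        raise ConfigError(errors)
    return RunConfig(sim=sim, merge=merge_params, platforms=platforms,
                     motif_consensus=doc.get("motif_consensus"),
                     write_callset_vcfs=bool(doc.get("write_callset_vcfs", False)))


@dataclass
class PlatformResult:
    platform: str
    fixed_sets: Dict[str, List[PopulationSV]]
    population: Dict[str, List[PopulationSV]]
    calls: List[ScenarioCall]
    lift_failures: Dict[str, list]
    species_sets: Dict[str, object]
    metrics: Dict[str, object]


@dataclass
class PipelineResult:
    sim: SimConfig
    params: MergeParams
    planted: PlantResult
    annotation: object
    callsets: Dict
    platforms: Dict[str, PlatformResult]
    overlap_pairs: List
    overlap_summary: pd.DataFrame
    zygosity: pd.DataFrame
    sizes: pd.DataFrame
    motif_density: pd.DataFrame
    anova: Tuple[float, float]


def merge_category_callsets(
    callsets: Dict, platform: str, sim: SimConfig, params: MergeParams
) -> Tuple[Dict[str, List[PopulationSV]], Dict[str, List[PopulationSV]]]:
    """Per-category consensus + population merge + fixation for one platform.

    Returns ``(fixed_sets, population)``: the fixation-filtered sets feeding
    the scenario classifier, and the pre-fixation population SVs.
    """
    by_cat: Dict[str, Dict[str, List[SVRecord]]] = {c: {} for c in MAPPING_CATEGORIES}
    for (plat, sample, _caller, category), recs in callsets.items():
        if plat != platform:
            continue
        by_cat[category].setdefault(sample, []).extend(recs)
    fixed_sets: Dict[str, List[PopulationSV]] = {}
    population: Dict[str, List[PopulationSV]] = {}
    for category in MAPPING_CATEGORIES:
        per_sample = [
            consensus_filter(cluster_calls(by_cat[category][sample], params), params)
            for sample in sorted(by_cat[category])
        ]
        pop = population_merge(per_sample, params)
        population[category] = pop
        coh = set(cohort(sim, category[0], platform))
        fixed_sets[category] = fixation_filter(pop, coh) if coh else []
    return fixed_sets, population


def run_synthetic_pipeline(
    sim: SimConfig,
    params: Optional[MergeParams] = None,
    platforms: Sequence[str] = PLATFORMS,
) -> PipelineResult:
    """Full in-memory run against synthetic data with planted truth."""
    params = params or MergeParams()
    genome = simulate_ancestral(sim)
    planted = plant_svs(genome, sim)
    callsets = emit_callsets(planted.truth, planted.ref_a, planted.ref_b, sim)
    annotation = emit_annotation(planted.ref_a, planted.ref_b, planted.truth, sim)
    gene_index = annotate.GeneIndex(annotation.genes)
    block_map = planted.block_map

    platform_results: Dict[str, PlatformResult] = {}
    for platform in platforms:
        if any(not cohort(sim, sp, platform) for sp in SPECIES):
            logger.info("skipping platform %s: empty cohort", platform)
            continue
        fixed_sets, population = merge_category_callsets(callsets, platform, sim, params)
        calls, failures = build_patterns(fixed_sets, block_map, params)
        sets = species_specific_sets(calls, gene_index)
        metrics = recovery_metrics(calls, planted.truth, params)
        platform_results[platform] = PlatformResult(
            platform=platform, fixed_sets=fixed_sets, population=population,
            calls=calls, lift_failures=failures, species_sets=sets, metrics=metrics,
        )

    overlap_pairs: List = []
    overlap_summary = pd.DataFrame()
    if "SR" in platform_results and "LR" in platform_results:
        sr = platform_results["SR"]
        lr = platform_results["LR"]
        sr_specific = sr.species_sets["A"] + sr.species_sets["B"]
        lr_specific = lr.species_sets["A"] + lr.species_sets["B"]
        overlap_pairs = platform_overlap(sr_specific, lr_specific, params, gene_index)
        overlap_summary = scenario_summary([p[0] for p in overlap_pairs], gene_index)

    # conspecific-mapping call-level summaries (zygosity, sizes)
    conspecific: List[SVRecord] = []
    for pr in platform_results.values():
        for category in ("A2A", "B2B"):
            for psv in pr.population[category]:
                conspecific.extend(psv.members)
    zygosity = annotate.zygosity_summary(conspecific)
    sizes = annotate.size_summary(conspecific)

    # motif density over genic-masked region sets, in genome-A coordinates
    all_sv_iv = [tr.a_interval for tr in planted.truth if tr.a_interval is not None]
    fixed_iv = [tr.a_interval for tr in planted.truth
                if tr.is_fixed and tr.a_interval is not None]
    region_sets = motifs.build_region_sets(
        annotation.genes, all_sv_iv, fixed_iv, planted.contig_lengths_a, flank=sim.flank
    )
    hits = [(c, s, e, st) for (c, s, e, _n, st) in annotation.motif_hits]
    tables = {label: motifs.density(hits, rs) for label, rs in region_sets.items()}
    motif_density = pd.concat(tables.values(), ignore_index=True)
    groups = [list(tables[label]["density"]) for label in
              ("intergenic", "sv_flank", "fixed_sv_flank")]
    anova = (float("nan"), float("nan"))
    if all(len(g) >= 2 for g in groups):
        anova = motifs.one_way_anova(groups)

    return PipelineResult(
        sim=sim, params=params, planted=planted, annotation=annotation,
        callsets=callsets, platforms=platform_results,
        overlap_pairs=overlap_pairs, overlap_summary=overlap_summary,
        zygosity=zygosity, sizes=sizes, motif_density=motif_density, anova=anova,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir) -> PipelineResult:
    """Run everything and write stage outputs plus a checksum manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = run_synthetic_pipeline(config.sim, config.merge, config.platforms)
    planted = result.planted

    write_fasta(planted.ref_a, outdir / "ref_A.fasta")
    write_fasta(planted.ref_b, outdir / "ref_B.fasta")
    write_alignment_coords(planted.blocks, outdir / "alignment.coords.tsv")
    write_truth(planted.truth, outdir / "truth.tsv")
    write_gff3(result.annotation.genes, outdir / "genes.gff3")
    write_bed(result.annotation.motif_hits, outdir / "motifs.bed")
    if config.write_callset_vcfs:
        from .io import write_sv_vcf

        vcf_dir = outdir / "callsets"
        vcf_dir.mkdir(exist_ok=True)
        lengths = {"A": planted.contig_lengths_a, "B": planted.contig_lengths_b}
        for (platform, sample, caller, category), records in sorted(result.callsets.items()):
            write_sv_vcf(records, vcf_dir / f"{platform}_{sample}_{caller}_{category}.vcf",
                         reference_name=f"ref_{category[-1]}",
                         contig_lengths=lengths[category[-1]])

    for platform, pr in result.platforms.items():
        for species in SPECIES:
            calls = pr.species_sets[species]
            write_population_vcf(
                [c.sv for c in calls],
                outdir / f"{platform}_species_{species}.vcf",
                reference_name="ref_A", contig_lengths=planted.contig_lengths_a,
            )
        pr.species_sets["summary"].to_csv(
            outdir / f"{platform}_scenario_summary.tsv", sep="\t", index=False)
    if len(result.overlap_summary):
        result.overlap_summary.to_csv(outdir / "sr_lr_overlap_summary.tsv",
                                      sep="\t", index=False)
    result.zygosity.to_csv(outdir / "zygosity_summary.tsv", sep="\t", index=False)
    result.sizes.to_csv(outdir / "size_summary.tsv", sep="\t", index=False)
    result.motif_density.to_csv(outdir / "motif_density.tsv", sep="\t", index=False)

    manifest = {
        "config": {
            "simulate": dataclasses.asdict(config.sim),
            "merge": dataclasses.asdict(config.merge),
            "platforms": list(config.platforms),
        },
        "anova": {"F": result.anova[0], "p": result.anova[1]},
        "files": {
            p.name: {"sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in sorted(outdir.glob("*")) if p.is_file() and p.name != "manifest.json"
        },
        "metrics": {plat: pr.metrics for plat, pr in result.platforms.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return result
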