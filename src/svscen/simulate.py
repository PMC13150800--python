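"""Synthetic two-genome benchmark with planted, labelled structural variants.

An ancestral genome is simulated, then derived alleles are planted on the
two species lineages. Each planted SV carries its expected detection pattern
over the four mapping categories (A2A, A2B, B2A, B2B) and hence its expected
scenario, so every downstream stage can be verified against truth:

* ``fixed_A`` / ``fixed_B`` — fixed in all samples of one species. A fixed
  SV is either carried by that species' reference too (detected only against
  the other genome: scenarios 4/5) or absent from both references (detected
  against both genomes: scenarios 1/2, the "SV real, reference misassembled"
  case).
* ``polymorphic`` — carried by a strict subset of one species' samples, so
  it can never pass the 100%-of-cohort fixation filter (negative control).
* ``artefact_A`` / ``artefact_B`` — an edit present in one reference
  assembly but in no sample's genome; every conspecific sample then calls
  the inverse difference against its own reference and nothing else
  (scenarios 3/6). Artefact observed types are restricted to DEL/INS/INV,
  whose inverses are again simple edits.

Both references are produced as segment decompositions of the ancestral
sequence; the co-linear alignment blocks between them (what a whole-genome
aligner would report) fall out of the decomposition exactly. Caller noise is
modelled per (sample, caller, mapping category): Bernoulli missed calls,
Poisson false positives, Gaussian breakpoint jitter, truncated-Poisson read
support. Every byte of output is a deterministic function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import (
    AlignmentBlock,
    MAPPING_CATEGORIES,
    SVRecord,
    write_alignment_coords,
    write_bed,
    write_fasta,
    write_gff3,
    write_sv_vcf,
)
from .io import BedFeature, GeneModel
from .liftover import AlignmentBlockMap, B_TO_A, lift_sv
from .motifs import build_region_sets

__all__ = [
    "SimConfig",
    "TruthRecord",
    "PlantResult",
    "AnnotationResult",
    "simulate_ancestral",
    "plant_svs",
    "emit_callsets",
    "emit_annotation",
    "simulate_all",
    "write_truth",
    "read_truth",
]

SPECIES = ("A", "B")
PLATFORMS = ("SR", "LR")

_PAD = 1_500  # bp kept clear around every planted SV (> merge breakpoint tolerance)

# default size medians per SV type (bp) -> lognormal log-means
_DEFAULT_LOG_MEAN = {
    "DEL": math.log(206.0),
    "DUP": math.log(1817.0),
    "INS": math.log(84.0),
    "INV": math.log(1294.0),
    "TRA": math.log(610.0),
}
_ARTEFACT_TYPES = ("DEL", "INS", "INV")


class PlacementError(RuntimeError):
    """Raised when the genome is too small to place the requested SVs."""


def _default_samples() -> Dict[str, Dict[str, int]]:
    # short-read and long-read cohort sizes of the two study species
    return {"A": {"SR": 57, "LR": 4}, "B": {"SR": 22, "LR": 3}}


def _default_weights() -> Dict[str, float]:
    return {"DEL": 0.35, "DUP": 0.10, "INS": 0.30, "INV": 0.15, "TRA": 0.10}


@dataclass
class SimConfig:
    """All tunables of the synthetic benchmark; the seed fixes every byte."""

    n_contigs: int = 2
    contig_length: int = 2_000_000
    gc_fraction: float = 0.42
    n_fixed_sv_per_species: int = 20
    n_polymorphic_sv: int = 10
    n_artefact_sv: int = 4
    sv_type_weights: Dict[str, float] = field(default_factory=_default_weights)
    sv_size_log_mean: Dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_LOG_MEAN))
    sv_size_log_sd: Dict[str, float] = field(
        default_factory=lambda: {t: 0.6 for t in _DEFAULT_LOG_MEAN}
    )
    fixed_in_ref_fraction: float = 0.5  # fraction of fixed SVs carried by the own reference
    samples_per_species: Dict[str, Dict[str, int]] = field(default_factory=_default_samples)
    callers_per_platform: int = 3
    fn_rate: float = 0.05
    fp_rate_per_mbp: float = 0.5
    breakpoint_jitter_sd: float = 20.0
    support_mean: float = 20.0
    # annotation layer
    n_genes: int = 40
    fraction_genic: float = 0.5
    flank: int = 50_000
    motif_length: int = 10
    motif_density_intergenic: float = 2.0  # hits per kbp
    motif_density_sv_flank: float = 1.0
    motif_density_fixed_flank: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if self.contig_length < 10_000:
            raise ValueError("contig_length must be >= 10000")
        for name in ("gc_fraction", "fn_rate", "fixed_in_ref_fraction", "fraction_genic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_fixed_sv_per_species", "n_polymorphic_sv", "n_artefact_sv",
                     "n_genes", "flank", "motif_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fp_rate_per_mbp", "breakpoint_jitter_sd", "support_mean",
                     "motif_density_intergenic", "motif_density_sv_flank",
                     "motif_density_fixed_flank"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.callers_per_platform < 1:
            raise ValueError("callers_per_platform must be >= 1")
        w = self.sv_type_weights
        if any(v < 0 for v in w.values()):
            raise ValueError("sv_type_weights must be non-negative")
        if abs(sum(w.values()) - 1.0) > 1e-6:
            raise ValueError("sv_type_weights must sum to 1")
        for sp, plats in self.samples_per_species.items():
            for plat, n in plats.items():
                if n < 0:
                    raise ValueError(f"samples_per_species[{sp}][{plat}] must be >= 0")

    @property
    def max_sv_size(self) -> int:
        """Planted sizes are capped so the largest SV is << contig length."""
        return self.contig_length // 20


@dataclass
class TruthRecord:
    """One planted SV with everything needed to verify its recovery."""

    sv_id: str
    contig: str           # ancestral coordinates
    start: int
    end: int
    svtype: str
    svlen: int
    origin: str           # fixed_A | fixed_B | polymorphic | artefact_A | artefact_B
    species: str          # which species' lineage/cohort it belongs to
    in_ref: bool          # derived allele present in the own species' reference
    expected_pattern: Tuple[bool, bool, bool, bool]
    expected_scenario: object  # 1..6 or "other"
    mate: Optional[Tuple[str, int]] = None          # ancestral mate breakend (TRA)
    segment_len: int = 0                            # exchanged-segment length (TRA)
    category_coords: Dict[str, tuple] = field(default_factory=dict)
    a_interval: Optional[Tuple[str, int, int]] = None  # anchor in genome-A coordinates
    a_mate: Optional[Tuple[str, int]] = None           # TRA mate anchor in genome A
    carriers: Dict[Tuple[str, str], FrozenSet[int]] = field(default_factory=dict)

    @property
    def is_fixed(self) -> bool:
        return self.origin.startswith("fixed")

    @property
    def is_artefact(self) -> bool:
        return self.origin.startswith("artefact")


# ---------------------------------------------------------------------------
# random sequence
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_RC = str.maketrans("ACGTN", "TGCAN")


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=int(length), p=p)
    return _BASES[idx].tobytes().decode()


def simulate_ancestral(config: SimConfig) -> Dict[str, str]:
    """Simulate the ancestral genome: iid bases at the configured GC."""
    rng = _rng(config.seed, 1)
    return {
        f"ctg{i + 1}": _random_seq(rng, config.contig_length, config.gc_fraction)
        for i in range(config.n_contigs)
    }


# ---------------------------------------------------------------------------
# segment decomposition of a derived reference
# ---------------------------------------------------------------------------


@dataclass
class _Segment:
    origin: Optional[str]      # ancestral contig, or None for novel sequence
    start: int                 # ancestral coords (ignored when novel)
    end: int
    strand: str = "+"
    novel_id: Optional[str] = None
    primary: bool = True       # False for extra DUP copies
    ref_contig: str = ""       # filled once placed
    ref_start: int = 0
    ref_end: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class _Edit:
    kind: str                  # DEL | INS | DUP | INV | SWAP
    contig: str
    start: int                 # for INS: insertion is after this base
    end: int
    novel_id: Optional[str] = None
    novel_len: int = 0
    swap_origin: Optional[Tuple[str, int, int]] = None

    def sort_key(self) -> tuple:
        return (self.start, 1 if self.kind == "INS" else 0)


def _decompose(
    contig_lengths: Mapping[str, int], edits: Sequence[_Edit]
) -> Dict[str, List[_Segment]]:
    by_contig: Dict[str, List[_Edit]] = {c: [] for c in contig_lengths}
    for e in edits:
        by_contig[e.contig].append(e)
    out: Dict[str, List[_Segment]] = {}
    for contig, length in contig_lengths.items():
        segs: List[_Segment] = []

        def passthrough(a: int, b: int) -> None:
            if b >= a:
                segs.append(_Segment(contig, a, b))

        cursor = 1
        for e in sorted(by_contig[contig], key=_Edit.sort_key):
            if e.kind == "INS":
                passthrough(cursor, e.start)
                segs.append(_Segment(None, 1, e.novel_len, novel_id=e.novel_id))
                cursor = e.start + 1
            elif e.kind == "DEL":
                passthrough(cursor, e.start - 1)
                cursor = e.end + 1
            elif e.kind == "DUP":
                passthrough(cursor, e.end)
                segs.append(_Segment(contig, e.start, e.end, primary=False))
                cursor = e.end + 1
            elif e.kind == "INV":
                passthrough(cursor, e.start - 1)
                segs.append(_Segment(contig, e.start, e.end, strand="-"))
                cursor = e.end + 1
            elif e.kind == "SWAP":
                passthrough(cursor, e.start - 1)
                oc, os_, oe = e.swap_origin  # type: ignore[misc]
                segs.append(_Segment(oc, os_, oe))
                cursor = e.end + 1
            else:  # pragma: no cover
                raise AssertionError(e.kind)
        passthrough(cursor, length)
        out[contig] = segs
    return out


def _place_segments(segments: Dict[str, List[_Segment]]) -> None:
    for contig, segs in segments.items():
        pos = 1
        for seg in segs:
            seg.ref_contig = contig
            seg.ref_start = pos
            seg.ref_end = pos + seg.length - 1
            pos = seg.ref_end + 1


def _assemble(
    segments: Dict[str, List[_Segment]],
    ancestral: Mapping[str, str],
    novel: Mapping[str, str],
) -> Dict[str, str]:
    out = {}
    for contig, segs in segments.items():
        parts = []
        for seg in segs:
            if seg.origin is None:
                parts.append(novel[seg.novel_id])
            else:
                piece = ancestral[seg.origin][seg.start - 1:seg.end]
                parts.append(piece.translate(_RC)[::-1] if seg.strand == "-" else piece)
        out[contig] = "".join(parts)
    return out


class _CoordMap:
    """Ancestral -> derived-reference coordinate lookup (primary segments)."""

    def __init__(self, segments: Dict[str, List[_Segment]]):
        self._by_origin: Dict[str, List[_Segment]] = {}
        self.novel: Dict[str, _Segment] = {}
        for segs in segments.values():
            for seg in segs:
                if seg.origin is None:
                    self.novel[seg.novel_id] = seg
                elif seg.primary:
                    self._by_origin.setdefault(seg.origin, []).append(seg)
        for v in self._by_origin.values():
            v.sort(key=lambda s: s.start)

    def map(self, contig: str, pos: int) -> Optional[Tuple[str, int]]:
        segs = self._by_origin.get(contig, [])
        import bisect

        i = bisect.bisect_right([s.start for s in segs], pos) - 1
        if i < 0:
            return None
        seg = segs[i]
        if not (seg.start <= pos <= seg.end):
            return None
        if seg.strand == "+":
            return seg.ref_contig, seg.ref_start + (pos - seg.start)
        return seg.ref_contig, seg.ref_start + (seg.end - pos)


def _blocks_between(
    segs_a: Dict[str, List[_Segment]], segs_b: Dict[str, List[_Segment]]
) -> List[AlignmentBlock]:
    by_origin_b: Dict[str, List[_Segment]] = {}
    for segs in segs_b.values():
        for seg in segs:
            if seg.origin is not None:
                by_origin_b.setdefault(seg.origin, []).append(seg)
    blocks: List[AlignmentBlock] = []
    for segs in segs_a.values():
        for sa in segs:
            if sa.origin is None:
                continue
            for sb in by_origin_b.get(sa.origin, []):
                os_, oe = max(sa.start, sb.start), min(sa.end, sb.end)
                if os_ > oe:
                    continue

                def ref_interval(seg: _Segment) -> Tuple[int, int]:
                    if seg.strand == "+":
                        return (seg.ref_start + (os_ - seg.start),
                                seg.ref_start + (oe - seg.start))
                    return (seg.ref_start + (seg.end - oe),
                            seg.ref_start + (seg.end - os_))

                a_s, a_e = ref_interval(sa)
                b_s, b_e = ref_interval(sb)
                blocks.append(AlignmentBlock(
                    contig_a=sa.ref_contig, start_a=a_s, end_a=a_e,
                    contig_b=sb.ref_contig, start_b=b_s, end_b=b_e,
                    strand="+" if sa.strand == sb.strand else "-",
                    identity=100.0,
                ))
    blocks.sort(key=lambda b: (b.contig_a, b.start_a, b.contig_b, b.start_b))
    return blocks


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------


@dataclass
class PlantResult:
    """Two derived references, the truth ledger and their alignment blocks."""

    ref_a: Dict[str, str]
    ref_b: Dict[str, str]
    truth: List[TruthRecord]
    blocks: List[AlignmentBlock]

    @property
    def block_map(self) -> AlignmentBlockMap:
        return AlignmentBlockMap(self.blocks)

    @property
    def contig_lengths_a(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.ref_a.items()}

    @property
    def contig_lengths_b(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.ref_b.items()}


def _pattern_for(origin: str, species: str, in_ref: bool) -> Tuple[Tuple[bool, ...], object]:
    if origin.startswith("fixed"):
        if species == "A":
            return ((False, True, False, False), 4) if in_ref else ((True, True, False, False), 1)
        return ((False, False, True, False), 5) if in_ref else ((False, False, True, True), 2)
    if origin == "artefact_A":
        return (True, False, False, False), 3
    if origin == "artefact_B":
        return (False, False, False, True), 6
    # polymorphic: detectable where carriers map, but never fixed
    if species == "A":
        return (True, True, False, False), "other"
    return (False, False, True, True), "other"


def _draw_type(rng: np.random.Generator, config: SimConfig, types: Sequence[str]) -> str:
    weights = np.array([config.sv_type_weights.get(t, 0.0) for t in types])
    if weights.sum() <= 0:
        weights = np.ones(len(types))
    return str(types[int(rng.choice(len(types), p=weights / weights.sum()))])


def _draw_size(rng: np.random.Generator, config: SimConfig, svtype: str) -> int:
    raw = rng.lognormal(config.sv_size_log_mean[svtype], config.sv_size_log_sd[svtype])
    return int(min(max(50, round(raw)), config.max_sv_size))


def plant_svs(genome: Mapping[str, str], config: SimConfig) -> PlantResult:
    """Plant the configured SVs on the two lineages and derive both references.

    Planted intervals are mutually non-overlapping after padding; the
    alignment blocks returned describe exactly the co-linear segments implied
    by the applied edits. For each species the first five fixed SVs cycle
    through the five SV types so every type is represented; the remainder is
    drawn from ``sv_type_weights``.
    """
    rng = _rng(config.seed, 2)
    contig_names = sorted(genome, key=lambda c: int(c[3:]) if c[3:].isdigit() else 0)
    contig_lengths = {c: len(genome[c]) for c in contig_names}
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in contig_names}

    spanning_types = list(config.sv_type_weights)
    if config.n_contigs < 2 and "TRA" in spanning_types:
        spanning_types = [t for t in spanning_types if t != "TRA"]

    def place(size: int, exclude_contig: Optional[str] = None) -> Tuple[str, int]:
        for _ in range(400):
            candidates = [c for c in contig_names if c != exclude_contig]
            contig = candidates[int(rng.integers(len(candidates)))]
            hi = contig_lengths[contig] - size - _PAD
            if hi <= _PAD + 1:
                continue
            start = int(rng.integers(_PAD + 1, hi))
            lo, hi2 = start - _PAD, start + size - 1 + _PAD
            if all(e < lo or s > hi2 for s, e in occupied[contig]):
                occupied[contig].append((lo, hi2))
                return contig, start
        raise PlacementError(
            f"cannot place an SV of {size} bp without overlap; genome too small/full"
        )

    # --- draw the truth list ------------------------------------------------
    specs: List[TruthRecord] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"sv{counter:04d}"

    for species in SPECIES:
        for k in range(config.n_fixed_sv_per_species):
            svtype = (spanning_types[k % len(spanning_types)]
                      if k < len(spanning_types)
                      else _draw_type(rng, config, spanning_types))
            in_ref = bool(rng.random() < config.fixed_in_ref_fraction)
            specs.append(_make_truth(new_id(), f"fixed_{species}", species, svtype,
                                     in_ref, rng, config, place))
    for k in range(config.n_polymorphic_sv):
        species = SPECIES[k % 2]
        svtype = _draw_type(rng, config, spanning_types)
        specs.append(_make_truth(new_id(), "polymorphic", species, svtype,
                                 False, rng, config, place))
    for k in range(config.n_artefact_sv):
        species = SPECIES[k % 2]
        svtype = _draw_type(rng, config, _ARTEFACT_TYPES)
        specs.append(_make_truth(new_id(), f"artefact_{species}", species, svtype,
                                 True, rng, config, place))

    # polymorphic carriers: uniform over {1..n-1} per cohort, never the full cohort
    for tr in specs:
        if tr.origin != "polymorphic":
            continue
        for platform in PLATFORMS:
            n = config.samples_per_species.get(tr.species, {}).get(platform, 0)
            if n <= 1:
                tr.carriers[(tr.species, platform)] = frozenset()
                continue
            k = int(rng.integers(1, n))
            tr.carriers[(tr.species, platform)] = frozenset(
                int(x) for x in rng.choice(n, size=k, replace=False)
            )

    # --- translate truth into reference edits -------------------------------
    edits_a: List[_Edit] = []
    edits_b: List[_Edit] = []
    novel_a: Dict[str, str] = {}
    novel_b: Dict[str, str] = {}

    for tr in specs:
        if not tr.in_ref:
            continue
        edits, novel = (edits_a, novel_a) if tr.species == "A" else (edits_b, novel_b)
        nid = f"{tr.sv_id}_novel"
        if tr.is_artefact:
            # the edit is the inverse of the observed sample-vs-reference type
            if tr.svtype == "DEL":     # observed DEL <- reference gained novel sequence
                novel[nid] = _random_seq(rng, tr.svlen, config.gc_fraction)
                edits.append(_Edit("INS", tr.contig, tr.start - 1, tr.start - 1,
                                   novel_id=nid, novel_len=tr.svlen))
            elif tr.svtype == "INS":   # observed INS <- reference lost a segment
                edits.append(_Edit("DEL", tr.contig, tr.start, tr.start + tr.svlen - 1))
            else:                      # INV is self-inverse
                edits.append(_Edit("INV", tr.contig, tr.start, tr.end))
            continue
        if tr.svtype == "DEL":
            edits.append(_Edit("DEL", tr.contig, tr.start, tr.end))
        elif tr.svtype == "INS":
            novel[nid] = _random_seq(rng, tr.svlen, config.gc_fraction)
            edits.append(_Edit("INS", tr.contig, tr.start, tr.start,
                               novel_id=nid, novel_len=tr.svlen))
        elif tr.svtype == "DUP":
            edits.append(_Edit("DUP", tr.contig, tr.start, tr.end))
        elif tr.svtype == "INV":
            edits.append(_Edit("INV", tr.contig, tr.start, tr.end))
        elif tr.svtype == "TRA":
            mc, mp = tr.mate  # type: ignore[misc]
            edits.append(_Edit("SWAP", tr.contig, tr.start, tr.end,
                               swap_origin=(mc, mp, mp + tr.segment_len - 1)))
            edits.append(_Edit("SWAP", mc, mp, mp + tr.segment_len - 1,
                               swap_origin=(tr.contig, tr.start, tr.end)))

    segs_a = _decompose(contig_lengths, edits_a)
    segs_b = _decompose(contig_lengths, edits_b)
    _place_segments(segs_a)
    _place_segments(segs_b)
    ref_a = _assemble(segs_a, genome, novel_a)
    ref_b = _assemble(segs_b, genome, novel_b)
    map_a = _CoordMap(segs_a)
    map_b = _CoordMap(segs_b)
    blocks = _blocks_between(segs_a, segs_b)
    block_map = AlignmentBlockMap(blocks)

    # --- per-category record coordinates and the genome-A anchor ------------
    for tr in specs:
        _fill_category_coords(tr, map_a, map_b)
        _fill_a_interval(tr, block_map)

    return PlantResult(ref_a=ref_a, ref_b=ref_b, truth=specs, blocks=blocks)


def _make_truth(sv_id, origin, species, svtype, in_ref, rng, config, place) -> TruthRecord:
    size = _draw_size(rng, config, svtype)
    pattern, scenario = _pattern_for(origin, species, in_ref)
    if svtype == "TRA":
        contig, start = place(size)
        mate_contig, mate_pos = place(size, exclude_contig=contig)
        tr = TruthRecord(
            sv_id=sv_id, contig=contig, start=start, end=start + size - 1,
            svtype="TRA", svlen=0, origin=origin, species=species, in_ref=in_ref,
            expected_pattern=tuple(pattern), expected_scenario=scenario,
            mate=(mate_contig, mate_pos), segment_len=size,
        )
        return tr
    contig, start = place(size)
    end = start if svtype == "INS" else start + size - 1
    return TruthRecord(
        sv_id=sv_id, contig=contig, start=start, end=end, svtype=svtype,
        svlen=size, origin=origin, species=species, in_ref=in_ref,
        expected_pattern=tuple(pattern), expected_scenario=scenario,
    )


def _fill_category_coords(tr: TruthRecord, map_a: _CoordMap, map_b: _CoordMap) -> None:
    for ci, category in enumerate(MAPPING_CATEGORIES):
        if not tr.expected_pattern[ci]:
            continue
        target = category[-1]
        cmap = map_a if target == "A" else map_b
        if tr.is_artefact:
            if tr.svtype == "DEL":  # spans the novel insert in the conspecific reference
                seg = cmap.novel[f"{tr.sv_id}_novel"]
                tr.category_coords[category] = (seg.ref_contig, seg.ref_start,
                                                seg.ref_end, None)
            elif tr.svtype == "INS":  # anchored just before the segment the reference lost
                c, p = cmap.map(tr.contig, tr.start - 1)
                tr.category_coords[category] = (c, p, p, None)
            else:  # INV occupies the same interval either way
                c1, p1 = cmap.map(tr.contig, tr.start)
                c2, p2 = cmap.map(tr.contig, tr.end)
                tr.category_coords[category] = (c1, min(p1, p2), max(p1, p2), None)
            continue
        if tr.svtype == "TRA":
            c1, p1 = cmap.map(tr.contig, tr.start)
            c2, p2 = cmap.map(tr.mate[0], tr.mate[1])  # type: ignore[index]
            tr.category_coords[category] = (c1, p1, p1, (c2, p2))
        elif tr.svtype == "INS":
            c, p = cmap.map(tr.contig, tr.start)
            tr.category_coords[category] = (c, p, p, None)
        else:
            c1, p1 = cmap.map(tr.contig, tr.start)
            c2, p2 = cmap.map(tr.contig, tr.end)
            tr.category_coords[category] = (c1, min(p1, p2), max(p1, p2), None)


def _record_from_coords(tr: TruthRecord, category: str) -> SVRecord:
    contig, start, end, mate = tr.category_coords[category]
    return SVRecord(
        contig=contig, start=start, end=end, svtype=tr.svtype,
        svlen=tr.svlen, support=1, genotype="hom",
        sample="", caller="", mapping_category=category, mate=mate,
    )


def _fill_a_interval(tr: TruthRecord, block_map: AlignmentBlockMap) -> None:
    for category in ("A2A", "B2A"):
        if category in tr.category_coords:
            contig, start, end, mate = tr.category_coords[category]
            tr.a_interval = (contig, start, end)
            tr.a_mate = mate
            return
    for category in ("A2B", "B2B"):
        if category in tr.category_coords:
            result = lift_sv(_record_from_coords(tr, category), block_map, B_TO_A)
            if result.ok:
                rec = result.record
                tr.a_interval = (rec.contig, rec.start, rec.end)
                tr.a_mate = rec.mate
            return


# ---------------------------------------------------------------------------
# callset emission
# ---------------------------------------------------------------------------

CallsetKey = Tuple[str, str, str, str]  # platform, sample, caller, category


def sample_name(species: str, platform: str, index: int) -> str:
    return f"{species}_{platform}{index + 1:02d}"


def cohort(config: SimConfig, species: str, platform: str) -> List[str]:
    n = config.samples_per_species.get(species, {}).get(platform, 0)
    return [sample_name(species, platform, i) for i in range(n)]


def emit_callsets(
    truth: Sequence[TruthRecord],
    ref_a: Mapping[str, str],
    ref_b: Mapping[str, str],
    config: SimConfig,
) -> Dict[CallsetKey, List[SVRecord]]:
    """Emit noisy per-(sample, caller, mapping category) callsets.

    A planted SV appears in a callset iff its truth pattern marks the
    category detectable, the sample carries it, and a Bernoulli(1 - fn_rate)
    draw succeeds; breakpoints get rounded-Gaussian jitter, support is
    Poisson truncated at 1, and false positives arrive at ``fp_rate_per_mbp``
    with random type and size. Each callset has its own derived RNG stream,
    so the output is independent of iteration order and byte-reproducible.
    """
    lengths = {"A": {c: len(s) for c, s in ref_a.items()},
               "B": {c: len(s) for c, s in ref_b.items()}}
    out: Dict[CallsetKey, List[SVRecord]] = {}
    for sp_i, species in enumerate(SPECIES):
        for pl_i, platform in enumerate(PLATFORMS):
            n = config.samples_per_species.get(species, {}).get(platform, 0)
            for s_i in range(n):
                sample = sample_name(species, platform, s_i)
                for c_i in range(config.callers_per_platform):
                    caller = f"{platform.lower()}c{c_i + 1}"
                    for t_i, target in enumerate(("A", "B")):
                        category = f"{species}2{target}"
                        rng = _rng(config.seed, 3, sp_i, pl_i, s_i, c_i, t_i)
                        records = _emit_one_callset(
                            truth, config, rng, species, platform, s_i,
                            sample, caller, category, lengths[target],
                        )
                        out[(platform, sample, caller, category)] = records
    return out


def _emit_one_callset(
    truth, config, rng, species, platform, s_i, sample, caller, category, contig_lengths
) -> List[SVRecord]:
    ci = MAPPING_CATEGORIES.index(category)
    records: List[SVRecord] = []
    for tr in truth:
        if not tr.expected_pattern[ci]:
            continue
        if tr.origin == "polymorphic" and s_i not in tr.carriers.get((species, platform),
                                                                     frozenset()):
            continue
        if rng.random() < config.fn_rate:
            continue
        contig, start, end, mate = tr.category_coords[category]
        sd = config.breakpoint_jitter_sd
        j1 = int(round(rng.normal(0.0, sd))) if sd > 0 else 0
        j2 = int(round(rng.normal(0.0, sd))) if sd > 0 else 0
        genotype = "het" if tr.origin == "polymorphic" else "hom"
        support = max(1, int(rng.poisson(config.support_mean)))
        if tr.svtype == "INS":
            p = max(1, start + j1)
            records.append(SVRecord(contig=contig, start=p, end=p, svtype="INS",
                                    svlen=tr.svlen, support=support, genotype=genotype,
                                    sample=sample, caller=caller,
                                    mapping_category=category))
        elif tr.svtype == "TRA":
            from .io import canonical_breakends

            c, p, m = canonical_breakends(contig, max(1, start + j1),
                                          (mate[0], max(1, mate[1] + j2)))
            records.append(SVRecord(contig=c, start=p, end=p, svtype="TRA",
                                    svlen=0, support=support, genotype=genotype,
                                    sample=sample, caller=caller,
                                    mapping_category=category, mate=m))
        else:
            s2, e2 = max(1, start + j1), max(1, end + j2)
            if s2 > e2:
                s2, e2 = e2, s2
            records.append(SVRecord(contig=contig, start=s2, end=e2, svtype=tr.svtype,
                                    svlen=e2 - s2 + 1, support=support, genotype=genotype,
                                    sample=sample, caller=caller,
                                    mapping_category=category))
    # false positives, uniform over the target genome
    genome_mbp = sum(contig_lengths.values()) / 1e6
    n_fp = int(rng.poisson(config.fp_rate_per_mbp * genome_mbp))
    contigs = sorted(contig_lengths)
    for k in range(n_fp):
        svtype = str(np.array(["DEL", "DUP", "INS", "INV"])[int(rng.integers(4))])
        size = _draw_size(rng, config, svtype)
        contig = contigs[int(rng.integers(len(contigs)))]
        hi = max(2, contig_lengths[contig] - size)
        pos = int(rng.integers(1, hi))
        end = pos if svtype == "INS" else pos + size - 1
        records.append(SVRecord(
            contig=contig, start=pos, end=end, svtype=svtype, svlen=size,
            support=max(1, int(rng.poisson(config.support_mean))),
            genotype="het" if rng.random() < 0.5 else "hom",
            sample=sample, caller=caller, mapping_category=category,
        ))
    records.sort(key=SVRecord.sort_key)
    return records


# ---------------------------------------------------------------------------
# annotation layer: genes and motif hits
# ---------------------------------------------------------------------------


@dataclass
class AnnotationResult:
    genes: List[GeneModel]
    motif_hits: List[BedFeature]
    gene_ledger: pd.DataFrame  # sv_id, gene_id, relation


def emit_annotation(
    ref_a: Mapping[str, str],
    ref_b: Mapping[str, str],
    truth: Sequence[TruthRecord],
    config: SimConfig,
) -> AnnotationResult:
    """Plant gene models and motif hits in genome-A coordinates.

    A ``fraction_genic`` share of the fixed SVs gets a gene constructed
    around it realising a drawn impact relation (gene_level / exonic /
    intronic; TRA always breakend-in-gene); background genes avoid all
    planted SVs. Motif hits are a Poisson process whose rate decreases from
    exclusive intergenic space through SV flanks to fixed-SV flanks,
    mirroring the density gradient the pipeline is meant to detect.
    """
    rng = _rng(config.seed, 4)
    lengths = {c: len(s) for c, s in ref_a.items()}
    anchors = [(tr, tr.a_interval) for tr in truth if tr.a_interval is not None]
    all_iv = sorted((iv for _t, iv in anchors), key=lambda x: (x[0], x[1]))

    def neighbours(contig: str, s: int, e: int) -> Tuple[int, int]:
        lo, hi = 1, lengths[contig]
        for c2, s2, e2 in all_iv:
            if c2 != contig or (s2 == s and e2 == e):
                continue
            if e2 < s:
                lo = max(lo, e2 + 2)
            elif s2 > e:
                hi = min(hi, s2 - 2)
        return lo, hi

    genes: List[GeneModel] = []
    ledger_rows = []
    gene_spans: Dict[str, List[Tuple[int, int]]] = {c: [] for c in lengths}

    def add_gene(contig: str, start: int, end: int, exons) -> Optional[str]:
        if start < 1 or end > lengths[contig] or start >= end:
            return None
        if any(s <= end and start <= e for s, e in gene_spans[contig]):
            return None
        gid = f"gene{len(genes) + 1:04d}"
        genes.append(GeneModel(gene_id=gid, contig=contig, start=start, end=end,
                               exons=list(exons)))
        gene_spans[contig].append((start, end))
        return gid

    fixed = [tr for tr in truth if tr.is_fixed and tr.a_interval is not None]
    for tr in fixed:
        if rng.random() >= config.fraction_genic:
            continue
        contig, s, e = tr.a_interval
        lo, hi = neighbours(contig, s, e)
        span = e - s + 1
        if tr.svtype == "TRA":
            g_s, g_e = max(lo, s - 1200), min(hi, s + 1200)
            gid = add_gene(contig, g_s, g_e, [(g_s, min(g_s + 150, g_e))])
            relation = "gene_level"  # breakend inside the gene body
        elif span < 60:
            # point-like anchor (collapsed or insertion): put an exon over it
            g_s, g_e = max(lo, s - 1200), min(hi, e + 1200)
            gid = add_gene(contig, g_s, g_e, [(max(g_s, s - 50), min(g_e, e + 50))])
            relation = "exonic"
        else:
            relation = ("gene_level", "exonic", "intronic")[int(rng.integers(3))]
            if relation == "gene_level" and span >= 300:
                inset = span // 10
                g_s, g_e = s + inset, e - inset
                gid = add_gene(contig, g_s, g_e, [(g_s, min(g_s + 100, g_e))])
            elif relation != "intronic":
                relation = "exonic"
                g_s, g_e = max(lo, s - 200), min(hi, e + 200)
                ex_e = min(e, s + 150, g_e)
                gid = add_gene(contig, g_s, g_e, [(max(g_s, s - 20), ex_e)])
            else:
                g_s, g_e = max(lo, s - 800), min(hi, e + 800)
                if g_s > s - 60 or g_e < e + 60:
                    continue  # too tight for flanking exons; leave intergenic
                gid = add_gene(contig, g_s, g_e,
                               [(g_s, min(g_s + 150, s - 1)),
                                (max(e + 1, g_e - 150), g_e)])
        if gid is not None:
            ledger_rows.append((tr.sv_id, gid, relation))

    # background genes keep clear of every planted SV
    for _ in range(config.n_genes):
        for _attempt in range(40):
            contig = sorted(lengths)[int(rng.integers(len(lengths)))]
            glen = int(rng.integers(2_000, 8_000))
            if lengths[contig] <= glen + 2:
                continue
            g_s = int(rng.integers(1, lengths[contig] - glen))
            g_e = g_s + glen - 1
            near_sv = any(c == contig and s - 500 <= g_e and g_s <= e + 500
                          for c, s, e in all_iv)
            if near_sv:
                continue
            third = glen // 3
            exons = [(g_s, g_s + 150), (g_s + third, g_s + third + 150),
                     (g_e - 150, g_e)]
            if add_gene(contig, g_s, g_e, exons) is not None:
                break
    genes.sort(key=lambda g: (g.contig, g.start))

    # motif planting over the exclusive partition of the three region sets
    fixed_iv = [tr.a_interval for tr in fixed]
    region_sets = build_region_sets(genes, [iv for _t, iv in anchors], fixed_iv,
                                    lengths, flank=config.flank)
    from .intervals import subtract_intervals

    def regions_by_contig(rs):
        d: Dict[str, List[Tuple[int, int]]] = {}
        for c, s, e in rs.regions:
            d.setdefault(c, []).append((s, e))
        return d

    fixed_r = regions_by_contig(region_sets["fixed_sv_flank"])
    sv_r = regions_by_contig(region_sets["sv_flank"])
    inter_r = regions_by_contig(region_sets["intergenic"])
    partition = []  # (density, contig, start, end)
    for c in sorted(lengths):
        fx = fixed_r.get(c, [])
        sv_only = subtract_intervals(sv_r.get(c, []), fx)
        inter_only = subtract_intervals(inter_r.get(c, []), sv_r.get(c, []))
        partition += [(config.motif_density_fixed_flank, c, s, e) for s, e in fx]
        partition += [(config.motif_density_sv_flank, c, s, e) for s, e in sv_only]
        partition += [(config.motif_density_intergenic, c, s, e) for s, e in inter_only]
    partition.sort(key=lambda t: (t[1], t[2]))

    hits: List[BedFeature] = []
    m = config.motif_length
    for dens, contig, s, e in partition:
        kbp = (e - s + 1) / 1000.0
        n = int(rng.poisson(dens * kbp))
        if n == 0 or e - s + 1 <= m:
            continue
        starts = np.sort(rng.integers(s, e - m + 2, size=n))
        strands = rng.integers(0, 2, size=n)
        for p, st in zip(starts, strands):
            hits.append((contig, int(p), int(p) + m - 1,
                         f"motif{len(hits) + 1:05d}", "+" if st == 0 else "-"))
    ledger = pd.DataFrame(ledger_rows, columns=["sv_id", "gene_id", "relation"])
    return AnnotationResult(genes=genes, motif_hits=hits, gene_ledger=ledger)


# ---------------------------------------------------------------------------
# truth ledger I/O and the one-call driver
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = ["sv_id", "contig", "start", "end", "svtype", "svlen",
                  "origin", "pattern", "scenario"]


def write_truth(truth: Sequence[TruthRecord], path) -> None:
    rows = [
        (tr.sv_id, tr.contig, tr.start, tr.end, tr.svtype, tr.svlen, tr.origin,
         "".join(str(int(b)) for b in tr.expected_pattern), str(tr.expected_scenario))
        for tr in truth
    ]
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"pattern": str, "scenario": str})


def simulate_all(config: SimConfig, outdir) -> Dict[str, object]:
    """Run the full generator and write every downstream input to ``outdir``.

    Emits the two reference FASTAs, alignment-block TSV, truth ledger,
    GFF3 gene models, motif BED and one VCF per (sample, caller, mapping
    category). Returns the in-memory objects for direct use.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_ancestral(config)
    planted = plant_svs(genome, config)
    callsets = emit_callsets(planted.truth, planted.ref_a, planted.ref_b, config)
    annotation = emit_annotation(planted.ref_a, planted.ref_b, planted.truth, config)

    write_fasta(planted.ref_a, outdir / "ref_A.fasta")
    write_fasta(planted.ref_b, outdir / "ref_B.fasta")
    write_alignment_coords(planted.blocks, outdir / "alignment.coords.tsv")
    write_truth(planted.truth, outdir / "truth.tsv")
    write_gff3(annotation.genes, outdir / "genes.gff3")
    write_bed(annotation.motif_hits, outdir / "motifs.bed")
    vcf_dir = outdir / "callsets"
    vcf_dir.mkdir(exist_ok=True)
    lengths = {"A": planted.contig_lengths_a, "B": planted.contig_lengths_b}
    paths = {}
    for (platform, sample, caller, category), records in sorted(callsets.items()):
        name = f"{platform}_{sample}_{caller}_{category}.vcf"
        write_sv_vcf(records, vcf_dir / name,
                     reference_name=f"ref_{category[-1]}",
                     contig_lengths=lengths[category[-1]])
        paths[(platform, sample, caller, category)] = vcf_dir / name
    return {
        "genome": genome,
        "planted": planted,
        "callsets": callsets,
        "annotation": annotation,
        "callset_paths": paths,
    }
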