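"""Readers/writers for the formats the pipeline touches, and the core records.

Coordinate convention: everything in memory is 1-based, closed intervals.
BED (0-based half-open) and the show-coords dialect (descending intervals on
the reverse strand) are converted at the boundary, in both directions.

VCF handling goes through :mod:`pysam`. The SV dialect accepted is the common
one: a symbolic ALT (``<DEL>`` etc.) or an explicit-sequence indel, an
``SVTYPE`` INFO key, and breakpoints from ``POS``/``END``/``SVLEN``.
Breakend (BND) mate pairs are collapsed into single translocation (TRA)
records on read and expanded back into two BND lines on write.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

SV_TYPES = ("DEL", "DUP", "INS", "INV", "TRA")
MAPPING_CATEGORIES = ("A2A", "A2B", "B2A", "B2B")

#: INFO keys tried, in order, to recover read support; a tuple means the sum
#: of whichever of its members are present (Delly-style SR+PE).
DEFAULT_SUPPORT_KEYS: Tuple = ("SUPP", "SUPPORT", "RE", "DV", ("SR", "PE"))

#: Variants shorter than this are not structural variants and are dropped.
MIN_SV_LEN = 50

_BND_ALT_RE = re.compile(r"[\[\]]([^\[\]:]+):(\d+)[\[\]]")


def canonical_breakends(contig: str, pos: int, mate: Tuple[str, int]):
    """Order a translocation's two breakends canonically (lexicographic).

    Keeping every TRA record in canonical orientation makes breakend pairs
    comparable regardless of which end a caller (or a liftover) reported
    first.
    """
    if (mate[0], mate[1]) < (contig, pos):
        return mate[0], mate[1], (contig, pos)
    return contig, pos, mate


@dataclass
class SVRecord:
    """One structural-variant call.

    ``start``/``end`` are 1-based; for INS ``end == start`` and ``svlen`` is
    the inserted length; for TRA ``svlen`` is 0 and ``mate`` holds the
    partner breakend.
    """

    contig: str
    start: int
    end: int
    svtype: str
    svlen: int
    support: int = 0
    genotype: str = "missing"  # {het, hom, missing}
    sample: str = ""
    caller: str = ""
    mapping_category: str = ""
    mate: Optional[Tuple[str, int]] = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.svlen < 0:
            raise ValueError("svlen must be >= 0")
        if self.svtype == "TRA" and self.mate is None:
            raise ValueError("TRA record requires a mate breakend")
        if self.svtype != "TRA" and self.mate is not None:
            raise ValueError("only TRA records carry a mate breakend")

    @property
    def span(self) -> int:
        """Closed-interval span in bp (1 for point records)."""
        return self.end - self.start + 1

    def sort_key(self) -> tuple:
        return (
            self.contig,
            self.start,
            self.end,
            self.svtype,
            self.svlen,
            self.caller,
            self.sample,
            self.mapping_category,
        )


@dataclass
class GeneModel:
    """A gene span with its exons (1-based closed, exons within span)."""

    gene_id: str
    contig: str
    start: int
    end: int
    exons: List[Tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("gene start > end")
        prev_end = None
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"exon ({s},{e}) outside gene span of {self.gene_id}")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"exons of {self.gene_id} unsorted or overlapping")
            prev_end = e


@dataclass
class AlignmentBlock:
    """One co-linear aligned block between genome A and genome B.

    Intervals are stored ascending on both genomes; ``strand`` records the
    relative orientation.
    """

    contig_a: str
    start_a: int
    end_a: int
    contig_b: str
    start_b: int
    end_b: int
    strand: str = "+"
    identity: float = 100.0

    def __post_init__(self) -> None:
        if self.start_a > self.end_a or self.start_b > self.end_b:
            raise ValueError("alignment block intervals must be ascending")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def len_a(self) -> int:
        return self.end_a - self.start_a + 1

    @property
    def len_b(self) -> int:
        return self.end_b - self.start_b + 1


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _genotype_from_gt(gt) -> str:
    if gt is None:
        return "missing"
    alleles = [a for a in gt if a is not None]
    if not alleles or all(a == 0 for a in alleles):
        return "missing"
    if all(a >= 1 for a in alleles) and len(alleles) >= 2:
        return "hom"
    return "het"


def _extract_support(info, support_keys) -> int:
    for key in support_keys:
        if isinstance(key, tuple):
            vals = [info.get(k) for k in key if k in info]
            if vals:
                total = 0
                for v in vals:
                    total += sum(v) if isinstance(v, (tuple, list)) else int(v)
                return total
        elif key in info:
            v = info[key]
            return int(sum(v) if isinstance(v, (tuple, list)) else v)
    return 0


def _info_scalar(info, key):
    if key not in info:
        return None
    v = info[key]
    if isinstance(v, (tuple, list)):
        v = v[0]
    return v


def read_sv_vcf(
    path,
    sample: str = "",
    caller: str = "",
    mapping_category: str = "",
    support_keys: Sequence = DEFAULT_SUPPORT_KEYS,
    min_len: int = MIN_SV_LEN,
) -> List[SVRecord]:
    """Read an SV VCF into normalized :class:`SVRecord` objects.

    ``sample``/``caller``/``mapping_category`` are defaults used when the
    file does not carry the corresponding ``SAMPLE``/``CALLER``/``MCAT``
    INFO tags. BND mate pairs are collapsed into one TRA record placed at
    the first-seen mate; sub-threshold (< ``min_len``) non-TRA variants are
    dropped.
    """
    out: List[Optional[SVRecord]] = []
    bnd_pending: Dict[tuple, int] = {}  # (contig,pos,mate_contig,mate_pos) -> slot
    bnd_by_id: Dict[str, int] = {}

    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            svtype = _info_scalar(info, "SVTYPE")
            ref = rec.ref or ""
            alts = rec.alts or ()

            if svtype is None:
                # explicit-sequence indel without SVTYPE
                plain = [a for a in alts if a and re.fullmatch(r"[ACGTNacgtn]+", a)]
                if not plain or not re.fullmatch(r"[ACGTNacgtn]+", ref):
                    logger.warning("skipping record without SVTYPE at %s:%s", rec.contig, rec.pos)
                    continue

            gt = None
            if rec.samples:
                first = rec.samples[list(rec.samples)[0]]
                gt = first.get("GT")
            genotype = _genotype_from_gt(gt)
            support = _extract_support(info, support_keys)
            rec_sample = _info_scalar(info, "SAMPLE") or sample
            rec_caller = _info_scalar(info, "CALLER") or caller
            rec_cat = _info_scalar(info, "MCAT") or mapping_category

            common = dict(
                support=support,
                genotype=genotype,
                sample=rec_sample,
                caller=rec_caller,
                mapping_category=rec_cat,
            )

            if svtype == "BND":
                alt = alts[0] if alts else ""
                m = _BND_ALT_RE.search(alt)
                if m is None:
                    logger.warning("unparseable BND ALT %r at %s:%s", alt, rec.contig, rec.pos)
                    continue
                mate_contig, mate_pos = m.group(1), int(m.group(2))
                here = (rec.contig, rec.pos)
                there = (mate_contig, mate_pos)
                mate_id = _info_scalar(info, "MATEID")
                slot = None
                if mate_id is not None and mate_id in bnd_by_id:
                    slot = bnd_by_id.pop(mate_id)
                else:
                    slot = bnd_pending.pop((there[0], there[1], here[0], here[1]), None)
                if slot is not None:
                    continue  # second mate of an already-registered pair
                out.append(
                    SVRecord(
                        contig=here[0], start=here[1], end=here[1], svtype="TRA",
                        svlen=0, mate=there, **common,
                    )
                )
                idx = len(out) - 1
                bnd_pending[(here[0], here[1], there[0], there[1])] = idx
                if rec.id:
                    bnd_by_id[rec.id] = idx
                continue

            if svtype == "TRA":  # non-BND translocation encoding (CHR2/END2)
                mate_contig = _info_scalar(info, "CHR2") or rec.contig
                mate_pos = _info_scalar(info, "POS2") or rec.stop
                out.append(
                    SVRecord(
                        contig=rec.contig, start=rec.pos, end=rec.pos, svtype="TRA",
                        svlen=0, mate=(str(mate_contig), int(mate_pos)), **common,
                    )
                )
                continue

            start = rec.pos
            end = rec.stop
            svlen = _info_scalar(info, "SVLEN")
            if svtype is None:
                # explicit indel: one record per ALT allele
                for alt in alts:
                    if not re.fullmatch(r"[ACGTNacgtn]+", alt or ""):
                        continue
                    delta = len(ref) - len(alt)
                    st = "DEL" if delta > 0 else "INS"
                    ln = abs(delta)
                    if ln < min_len:
                        continue
                    e = start + ln if st == "DEL" else start
                    out.append(SVRecord(contig=rec.contig, start=start, end=e,
                                        svtype=st, svlen=ln, **common))
                continue

            svtype = str(svtype)
            if svtype not in SV_TYPES:
                logger.warning("skipping unknown SVTYPE %r at %s:%s", svtype, rec.contig, rec.pos)
                continue
            if svlen is None:
                svlen = end - start if svtype != "INS" else 0
            svlen = abs(int(svlen))
            if svtype == "INS":
                end = start
            if end < start:
                start, end = end, start
            if svlen < min_len:
                continue
            out.append(SVRecord(contig=rec.contig, start=start, end=end,
                                svtype=svtype, svlen=svlen, **common))

    return [r for r in out if r is not None]


def _vcf_header(
    records: Sequence[SVRecord],
    reference_name: str,
    contig_lengths: Optional[Mapping[str, int]],
    sample_column: str,
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##reference={reference_name}")
    contigs = sorted(
        {r.contig for r in records}
        | {r.mate[0] for r in records if r.mate is not None}
        | set(contig_lengths or {})
    )
    for c in contigs:
        if contig_lengths and c in contig_lengths:
            header.add_line(f"##contig=<ID={c},length={contig_lengths[c]}>")
        else:
            header.add_line(f"##contig=<ID={c}>")
    for line in (
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">',
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Source sample">',
        '##INFO=<ID=CALLER,Number=1,Type=String,Description="Source caller">',
        '##INFO=<ID=MCAT,Number=1,Type=String,Description="Mapping category">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP,Description="Duplication">',
        '##ALT=<ID=INS,Description="Insertion">',
        '##ALT=<ID=INV,Description="Inversion">',
    ):
        header.add_line(line)
    header.add_sample(sample_column)
    return header


_GT_OUT = {"hom": (1, 1), "het": (0, 1), "missing": (None, None)}


def write_sv_vcf(
    records: Sequence[SVRecord],
    path,
    reference_name: str = "unknown",
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write records as VCF v4.2; TRA records become two mated BND lines.

    Writing then reading back (:func:`read_sv_vcf`) is the identity on every
    :class:`SVRecord` field.
    """
    samples = {r.sample for r in records}
    sample_column = samples.pop() if len(samples) == 1 and "" not in samples else "SAMPLE"
    header = _vcf_header(records, reference_name, contig_lengths, sample_column)
    path = Path(path)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i, r in enumerate(records, start=1):
            base_info = {"SUPPORT": r.support}
            if r.sample:
                base_info["SAMPLE"] = r.sample
            if r.caller:
                base_info["CALLER"] = r.caller
            if r.mapping_category:
                base_info["MCAT"] = r.mapping_category
            if r.svtype == "TRA":
                mc, mp = r.mate  # type: ignore[misc]
                for tag, (c, p, oc, op) in (
                    ("_1", (r.contig, r.start, mc, mp)),
                    ("_2", (mc, mp, r.contig, r.start)),
                ):
                    rec = vf.new_record(
                        contig=c, start=p - 1, stop=p,
                        alleles=("N", f"N[{oc}:{op}["), id=f"sv{i}{tag}",
                    )
                    rec.info["SVTYPE"] = "BND"
                    rec.info["MATEID"] = f"sv{i}{'_2' if tag == '_1' else '_1'}"
                    for k, v in base_info.items():
                        rec.info[k] = v
                    rec.samples[sample_column]["GT"] = _GT_OUT[r.genotype]
                    vf.write(rec)
                continue
            rec = vf.new_record(
                contig=r.contig, start=r.start - 1, stop=r.end,
                alleles=("N", f"<{r.svtype}>"), id=f"sv{i}",
            )
            rec.info["SVTYPE"] = r.svtype
            rec.info["SVLEN"] = r.svlen
            for k, v in base_info.items():
                rec.info[k] = v
            rec.samples[sample_column]["GT"] = _GT_OUT[r.genotype]
            vf.write(rec)


def write_population_vcf(pop_svs, path, reference_name: str = "unknown",
                         contig_lengths: Optional[Mapping[str, int]] = None) -> None:
    """Write merged population SVs with SUPP/CALLERS/SAMPLES INFO tags."""
    header = pysam.VariantHeader()
    header.add_line(f"##reference={reference_name}")
    contigs = sorted({p.representative.contig for p in pop_svs}
                     | {p.representative.mate[0] for p in pop_svs
                        if p.representative.mate is not None}
                     | set(contig_lengths or {}))
    for c in contigs:
        if contig_lengths and c in contig_lengths:
            header.add_line(f"##contig=<ID={c},length={contig_lengths[c]}>")
        else:
            header.add_line(f"##contig=<ID={c}>")
    for line in (
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=SUPP,Number=1,Type=Integer,Description="Max supporting reads over members">',
        '##INFO=<ID=CHR2,Number=1,Type=String,Description="Mate contig (TRA)">',
        '##INFO=<ID=POS2,Number=1,Type=Integer,Description="Mate position (TRA)">',
        '##INFO=<ID=CALLERS,Number=.,Type=String,Description="Callers contributing members">',
        '##INFO=<ID=SAMPLES,Number=.,Type=String,Description="Samples carrying the SV">',
        '##INFO=<ID=MCAT,Number=1,Type=String,Description="Mapping category">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP,Description="Duplication">',
        '##ALT=<ID=INS,Description="Insertion">',
        '##ALT=<ID=INV,Description="Inversion">',
        '##ALT=<ID=TRA,Description="Translocation">',
    ):
        header.add_line(line)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i, p in enumerate(pop_svs, start=1):
            r = p.representative
            rec = vf.new_record(contig=r.contig, start=r.start - 1, stop=r.end,
                                alleles=("N", f"<{r.svtype}>"), id=f"psv{i}")
            rec.info["SVTYPE"] = r.svtype
            rec.info["SVLEN"] = r.svlen
            rec.info["SUPP"] = max((m.support for m in p.members), default=r.support)
            if r.mate is not None:
                rec.info["CHR2"] = r.mate[0]
                rec.info["POS2"] = r.mate[1]
            callers = sorted({m.caller for m in p.members if m.caller})
            if callers:
                rec.info["CALLERS"] = ",".join(callers)
            if p.samples_present:
                rec.info["SAMPLES"] = ",".join(sorted(p.samples_present))
            if r.mapping_category:
                rec.info["MCAT"] = r.mapping_category
            vf.write(rec)


def read_population_vcf(path, mapping_category: str = ""):
    """Read a merged population VCF (as written by :func:`write_population_vcf`)."""
    from .merge import PopulationSV  # local import avoids a cycle

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            svtype = str(_info_scalar(info, "SVTYPE"))
            samples = info.get("SAMPLES", ())
            if isinstance(samples, str):
                samples = (samples,)
            sample_set = {s for chunk in samples for s in chunk.split(",")}
            cat = _info_scalar(info, "MCAT") or mapping_category
            mate = None
            start, end = rec.pos, rec.stop
            if svtype == "TRA":
                mate = (str(_info_scalar(info, "CHR2")), int(_info_scalar(info, "POS2")))
                end = start
            sv = SVRecord(
                contig=rec.contig, start=start, end=end, svtype=svtype,
                svlen=abs(int(_info_scalar(info, "SVLEN") or 0)),
                support=int(_info_scalar(info, "SUPP") or 0),
                mapping_category=cat, mate=mate,
            )
            out.append(PopulationSV(representative=sv, members=[sv],
                                    samples_present=sample_set))
    return out


# ---------------------------------------------------------------------------
# show-coords style alignment TSV
# ---------------------------------------------------------------------------

_COORDS_COLUMNS = ["start_a", "end_a", "start_b", "end_b", "identity", "contig_a", "contig_b"]


def read_alignment_coords(path):
    """Read a show-coords ``-T -H`` style TSV into an :class:`~svscen.liftover.AlignmentBlockMap`.

    Columns: start_a, end_a, start_b, end_b, identity, contig_a, contig_b.
    A descending B interval means the block aligns on the reverse strand;
    coordinates are stored ascending with ``strand='-'``.
    """
    from .liftover import AlignmentBlockMap  # local import avoids a cycle

    path = Path(path)
    blocks: List[AlignmentBlock] = []
    if path.stat().st_size > 0:
        df = pd.read_csv(path, sep="\t", header=None)
        if df.shape[1] != len(_COORDS_COLUMNS):
            raise ValueError(
                f"{path}: expected {len(_COORDS_COLUMNS)} columns, found {df.shape[1]}"
            )
        df.columns = _COORDS_COLUMNS
        for row in df.itertuples(index=False):
            sb, eb = int(row.start_b), int(row.end_b)
            strand = "+" if sb <= eb else "-"
            blocks.append(
                AlignmentBlock(
                    contig_a=str(row.contig_a), start_a=int(row.start_a), end_a=int(row.end_a),
                    contig_b=str(row.contig_b), start_b=min(sb, eb), end_b=max(sb, eb),
                    strand=strand, identity=float(row.identity),
                )
            )
    return AlignmentBlockMap(blocks)


def write_alignment_coords(blocks: Iterable[AlignmentBlock], path) -> None:
    rows = []
    for b in blocks:
        sb, eb = (b.start_b, b.end_b) if b.strand == "+" else (b.end_b, b.start_b)
        rows.append((b.start_a, b.end_a, sb, eb, b.identity, b.contig_a, b.contig_b))
    pd.DataFrame(rows, columns=_COORDS_COLUMNS).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GFF3 / BED / FASTA
# ---------------------------------------------------------------------------


def read_gff3(path) -> List[GeneModel]:
    """Read gene models (gene spans + exons) from GFF3 via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = [(e.start, e.end) for e in db.children(g.id, featuretype="exon", order_by="start")]
        genes.append(GeneModel(gene_id=g.id, contig=g.seqid, start=g.start, end=g.end, exons=exons))
    return genes


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.contig}\tsvscen\tgene\t{g.start}\t{g.end}\t.\t+\t.\tID={g.gene_id}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(f"{g.contig}\tsvscen\tmRNA\t{g.start}\t{g.end}\t.\t+\t.\t"
                     f"ID={mrna};Parent={g.gene_id}\n")
            for k, (s, e) in enumerate(g.exons, start=1):
                fh.write(f"{g.contig}\tsvscen\texon\t{s}\t{e}\t.\t+\t.\t"
                         f"ID={mrna}.exon{k};Parent={mrna}\n")


BedFeature = Tuple[str, int, int, str, str]  # contig, start, end (1-based closed), name, strand


def read_bed(path) -> List[BedFeature]:
    """Read BED (0-based half-open) into 1-based closed features."""
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        vals = list(row)
        contig, start0, end0 = str(vals[0]), int(vals[1]), int(vals[2])
        name = str(vals[3]) if len(vals) > 3 else "."
        strand = str(vals[5]) if len(vals) > 5 else "+"
        out.append((contig, start0 + 1, end0, name, strand))
    return out


def write_bed(features: Sequence[BedFeature], path) -> None:
    with open(path, "w") as fh:
        for contig, start, end, name, strand in features:
            fh.write(f"{contig}\t{start - 1}\t{end}\t{name}\t0\t{strand}\n")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
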