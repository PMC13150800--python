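# svscen

**Fixed species-specific structural variants from reciprocal reference
mapping — with a planted-truth synthetic benchmark.**

When two closely related species each have a reference assembly and
population resequencing data, structural variants (SVs: DEL, DUP, INS, INV,
TRA; > 50 bp) that are *fixed* between the species can be separated from
polymorphisms and assembly artefacts by calling every cohort against both
references. `svscen` implements the downstream half of that design — it
starts from per-caller SV callsets (VCF) and ends at classified,
gene-annotated species-specific SV sets — plus a fully seeded simulator that
generates two diverged genomes with planted, labelled SVs so the whole
pipeline is verifiable against known truth without downloading anything.

## The model

Reads from species A and B are each mapped to both references, giving four
mapping categories A2A, A2B, B2A, B2B. Per sample, calls from ≥ 2 of the
configured callers with read support > 5 are consensus-merged
(single-linkage clustering with 500 bp breakpoint tolerance and 0.5
reciprocal overlap); population SVs must then be present in **100% of the
cohort** (fixation filter). Calls made against reference B are lifted into
genome-A coordinates through whole-genome-alignment blocks, and each SV's
4-bit detection pattern over the categories determines its scenario:

| pattern (A2A A2B B2A B2B) | scenario | meaning |
|---|---|---|
| 1 1 0 0 | 1 | fixed in A; allele missing/misassembled in ref A |
| 0 0 1 1 | 2 | fixed in B; allele missing/misassembled in ref B |
| 0 1 0 0 | 4 | fixed in A and carried by ref A |
| 0 0 1 0 | 5 | fixed in B and carried by ref B |
| 1 0 0 0 / 0 0 0 1 | 3 / 6 | conspecific-only: assembly artefact or singleton — excluded |

Scenarios 1, 2, 4, 5 are species-specific. Downstream, SVs are annotated for
gene impact (gene_level / exonic / intronic / intergenic), short-read and
long-read sets are intersected within genic space, and enhancer-motif
density (motifs per kbp, genic-masked) is compared across intergenic space,
SV flanks and fixed-SV flanks with a one-way ANOVA.

## Worked example

A full synthetic run — simulate two 2 Mb genomes with 20 fixed SVs per
species (plus 10 polymorphic negatives and 4 assembly artefacts), emit noisy
callsets for the default cohorts (57/22 short-read, 4/3 long-read samples),
and run merge → lift → classify → annotate → motifs:

```python
from svscen.simulate import SimConfig
from svscen.pipeline import run_synthetic_pipeline
from svscen.merge import MergeParams

cfg = SimConfig(seed=11, fn_rate=0.05, breakpoint_jitter_sd=20.0)
result = run_synthetic_pipeline(cfg, MergeParams())

for platform, pr in result.platforms.items():
    m = pr.metrics
    print(f"{platform}: {m['n_species_specific_called']} species-specific SVs, "
          f"sensitivity={m['sensitivity']:.2f}, specificity={m['specificity']:.2f}, "
          f"polymorphic leaks={m['polymorphic_leaks']}")
print(result.platforms["LR"].species_sets["summary"].to_string(index=False))
f_stat, p = result.anova
print(f"Motif density ANOVA: F={f_stat:.2f}, p={p:.3g}")
```

prints

```
SR: 29 species-specific SVs, sensitivity=0.70, specificity=0.97, polymorphic leaks=0
LR: 38 species-specific SVs, sensitivity=0.93, specificity=0.97, polymorphic leaks=0
 scenario  n_svs  DEL  DUP  INS  INV  TRA  n_genes  exonic  intronic  gene_level
        1     10    5    2    2    0    1        3       1         1           1
        2     10    2    3    1    1    3        5       1         0           4
        4      9    3    2    1    2    1        7       4         0           3
        5      9    3    2    3    1    0        1       1         0           0
Motif density ANOVA: F=14.54, p=1.45e-06
```

Read the numbers like this: the long-read branch recovers 38 of the 40
planted fixed SVs (the per-scenario table mirrors the per-type/impact tally
layout), none of the planted polymorphic SVs survives the fixation filter,
and motif density differs strongly across the three region sets. The
short-read branch is *less* sensitive for a structural reason worth knowing:
requiring an SV in 100% of 57 samples at a 5% per-caller miss rate loses
~0.993⁵⁷ ≈ ⅓ of true fixed SVs — exactly why large-cohort fixation sets are
small in practice. With noise turned off (`fn_rate=0`,
`breakpoint_jitter_sd=0`) both branches recover the planted sets exactly
(sensitivity = specificity = 1.0).

The same pipeline is scriptable from the shell:

```bash
svscen run --seed 11 --outdir run1          # full synthetic run + manifest
svscen simulate --seed 3 --outdir bench     # just the benchmark inputs
svscen merge sample1_*.vcf --out merged.vcf
svscen lift --coords aln.tsv --vcf b_calls.vcf --direction b2a --out lifted.vcf
svscen classify --a2a A2A.vcf --a2b A2B.vcf --b2a B2A.vcf --b2b B2B.vcf \
    --coords aln.tsv --out-prefix scen
```

Every output of `svscen run` is deterministic given the config (the manifest
records sha256 checksums; a rerun is bytewise identical).

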