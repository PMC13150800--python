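# Methods

## The inference

`svscen` identifies structural variants (SVs, events > 50 bp: DEL, DUP, INS,
INV, TRA) that are fixed between two closely related species, given only
resequencing data and one reference assembly per species. The key idea is
reciprocal mapping: each species' reads are called against both references,
giving four mapping categories — A2A, A2B, B2A, B2B (reads-species →
reference-species). After per-sample consensus merging and a fixation filter,
every SV carries a 4-bit detection pattern over those categories, and the
pattern alone classifies it:

| scenario | A2A | A2B | B2A | B2B | interpretation | species-specific |
|---|---|---|---|---|---|---|
| 1 | 1 | 1 | 0 | 0 | fixed in A, allele absent/misassembled in ref A | yes (A) |
| 2 | 0 | 0 | 1 | 1 | fixed in B, allele absent/misassembled in ref B | yes (B) |
| 3 | 1 | 0 | 0 | 0 | conspecific-only: assembly artefact or singleton | no |
| 4 | 0 | 1 | 0 | 0 | fixed in A and carried by ref A | yes (A) |
| 5 | 0 | 0 | 1 | 0 | fixed in B and carried by ref B | yes (B) |
| 6 | 0 | 0 | 0 | 1 | conspecific-only: artefact or singleton | no |

An all-ones pattern is a shared (ancestral) SV; any other non-zero pattern is
conservatively labelled `other` and never species-specific. Scenarios 3 and 6
are excluded from all downstream analysis. Pattern bits are computed from
fixation-filtered sets, so bit 1 means "detected, consensus-confirmed, and
present in 100% of that cohort".

### Filters

* **Consensus**: calls are clustered per sample across callers; a cluster
  survives iff ≥ `min_callers` (default 2) distinct callers contributed and
  its maximum read support is strictly greater than `min_support` (default 5).
* **Equivalence** (`sv_equivalent`): same type and contig, both breakpoints
  within `max_breakpoint_dist` (default 500 bp); additionally reciprocal
  overlap ≥ 0.5 for DEL/DUP/INV (shared span / longer span), insertion-length
  ratio ≥ 0.5 for INS, and both breakends within tolerance for TRA. TRA
  breakend pairs are kept in canonical lexicographic order so the two ends
  are comparable regardless of which one a caller reported first.
* **Clustering**: single-linkage connected components, computed by a
  position-sorted sweep that provably equals brute-force all-pairs linkage
  (the equivalence relation bounds the start distance). Representatives take
  the lower-middle median of each coordinate; all orderings are fixed by a
  total record key, so output is bytewise deterministic.
* **Population merge**: single linkage over *all member calls* of the
  per-sample consensus clusters (not just their representatives), with
  same-sample clusters kept united. Two samples therefore share an SV
  whenever any pair of their calls is equivalent — the tolerant semantics of
  multi-callset mergers.
* **Fixation**: an SV is retained iff its samples cover 100% of the cohort
  for that category and platform.

### Liftover

Cross-genome comparison happens in genome-A coordinates; calls made against
reference B are lifted through co-linear alignment blocks (show-coords style
TSV; blocks carry no per-base alignment, so within-block mapping is linear
interpolation by offset — exact for equal-length blocks, approximate
otherwise). Overlapping candidate blocks are resolved by identity, then
length, then leftmost position.

Interval SVs take one of three routes, in order of preference by how well the
lifted span preserves the original length: (1) plain endpoint projection when
both endpoints map consistently; (2) projection through the single
best-covering block, clamped at its edges — this resolves strand conflicts at
inversion boundaries and keeps a tandem-duplication span on its single
corresponding copy; (3) when most of the span is unaligned in the target
(i.e. the sequence is deleted there), the record collapses onto the junction
of the flanking blocks. Route 3 is what makes scenario-4/5 deletions —
carried by their own reference, hence absent from the partner genome —
classifiable at all; the collapse is canonical (independent of breakpoint
jitter), so collapsed calls still cluster with their truth location. A lifted
span may never exceed 2× the original (`length_tolerance`), which rejects
lifts through misjoined blocks; failures carry reason codes
(`endpoint_unmapped`, `contig_split`, `strand_conflict`, `length_distorted`).
`allow_gap_snap=False` restores strict endpoint-only semantics.

### Annotation and motif densities

Gene impact is classified at whole-feature granularity with precedence
gene_level > exonic > intronic (any-base overlap on closed intervals):
*gene_level* means the SV engulfs an entire gene, or is a translocation with
a breakend inside a gene — a definition chosen because translocations
dominate that column in per-scenario tallies; *exonic*/*intronic* are exon
vs gene-body overlap; everything else is intergenic. Codon-level consequence
prediction is out of scope.

Enhancer-motif analysis compares three genic-masked region sets: intergenic
space, ± `flank` (default 50 kb) around any SV, and ± flank around the fixed
species-specific SVs. Motifs are IUPAC consensus strings matched exactly on
both strands (a deterministic stand-in for score-thresholded PWM scanning;
it keeps the density statistic well defined). Density is hits per kbp per
region, counting a hit by its start coordinate so merged-region boundaries
never double count. Groups of per-region densities are compared with a
one-way fixed-effects ANOVA written from the sums of squares, with the
p-value from the upper tail of F(k−1, N−k) via the regularized incomplete
beta function; degenerate inputs are defined (zero within-group variance with
non-zero between → F = ∞, p = 0; all values identical → F = 0, p = 1).

## The synthetic benchmark

The generator plants labelled SVs on an ancestral genome (iid bases at a
configurable GC fraction) and derives both references by segment
decomposition, from which the exact alignment blocks fall out — what a
whole-genome aligner would report, with no aligner in the loop.

Planted classes and their expected patterns:

* `fixed_A`/`fixed_B` — fixed in one species; with probability
  `fixed_in_ref_fraction` (default 0.5) the derived allele is also in that
  species' reference (scenario 4/5), otherwise in neither reference
  (scenario 1/2).
* `polymorphic` — carried by a uniform strict subset {1..n−1} of one
  species' samples per cohort, so it can never pass fixation (negative
  control by construction).
* `artefact_A`/`artefact_B` — present in one reference but in no sample's
  genome; every conspecific sample calls the inverse difference against its
  own reference (scenario 3/6). Observed types are restricted to
  DEL/INS/INV, whose inverse reference edits are again simple edits.

Sizes are lognormal per type with default medians of DEL 206 bp,
DUP 1817 bp, INS 84 bp, INV 1294 bp and TRA 610 bp (log-sd 0.6) — typical
short-read merged-callset medians for closely related mammal genomes.
Cohort sizes default to 57/22 short-read and 4/3 long-read samples for
species A/B, an asymmetric two-platform survey design. Translocations are simulated as reciprocal
exchanges of equal-length internal segments between two contigs. The first
five fixed SVs per species cycle through all five types so every type is
always represented. Planted loci keep a 1.5 kb padding (breakpoint-tolerance
safe) and sizes are capped at contig_length/20.

Caller noise is modelled per (sample, caller, category) with an independent
RNG stream derived from the seed, so outputs are byte-identical across runs
and independent of iteration order: Bernoulli(fn_rate) missed calls per
caller, rounded-Gaussian breakpoint jitter (`breakpoint_jitter_sd`, default
20 bp, independent per breakpoint; mean |error| = σ·√(2/π)), support drawn
from a Poisson (`support_mean`, default 20) truncated at 1, and false
positives at `fp_rate_per_mbp` with random type/size/position.

Gene models are planted so a configurable fraction of fixed SVs realises a
drawn impact relation (geometry permitting; point-like anchors get an exon
over the anchor), background genes avoid all planted SVs. Motif hits are a
Poisson process over the exclusive partition of the three region sets, at
per-kbp rates decreasing from exclusive-intergenic (2.0) through SV-flank
(1.0) to fixed-SV-flank (0.5); genic space gets none. Because the three
*measured* sets nest (fixed flanks ⊂ SV flanks ⊂ intergenic complement of
genes), their measured densities are mixtures of the planted rates; the
planted ordering is preserved whenever the exclusive classes have
non-trivial extent, which requires SV flanks not to tile the whole genome —
at 50 kb flanks that means sparse SVs or multi-megabase contigs.

### What the generator does not model

Read-level errors (no FASTQ/BAM), diploid phasing, reference-relative type
flipping for non-artefact calls, correlated caller errors, repeat-induced
mis-mapping, and real aligner block fragmentation. Passing tests therefore
demonstrate the correctness of the post-caller pipeline logic under an
idealized but noise-bearing caller model, not caller performance on reads.

## Numerical and tie-breaking choices

Coordinates are 1-based closed everywhere in memory; BED (0-based half-open)
and descending reverse-strand coords rows are converted at the boundary.
Medians use the lower middle for even counts. Cluster output, VCF rows and
manifests are sorted by total keys, so identical configurations are bytewise
reproducible (checksummed in the run manifest). Genotypes normalise as
0/0 and ./. → missing, any single ALT → het, all-ALT → hom; missing
genotypes leave the zygosity denominator. Variants under 50 bp are dropped
at the VCF boundary.

## Problem sizes used in the shipped checks

The default verification runs use 2 contigs × 2 Mb with 20 fixed SVs per
species, 10 polymorphic and 4 artefacts (noise-free recovery), and 20
replicates of 100 fixed SVs with fn = 0.05 per caller, 3 callers, 20 bp
jitter and the long-read cohort sizes (noisy recovery); clustering is
cross-checked against brute force at 200 records × 50 seeds. These sizes
exercise every code path while keeping a full run in seconds.

## Known limitations

* Recovery under noise is limited by physics the model makes explicit: an SV
  is lost when some cohort sample misses it with ≥ 2 callers (per-SV
  probability 1−(3q²(1−q)+q³)ⁿ for per-caller hit rate q and cohort size n),
  and small deletions whose span is within a few jitter standard deviations
  fail the 0.5 reciprocal-overlap rule between samples. At the default noisy
  settings this puts mean sensitivity near 0.95–0.96.
* Liftover inside blocks is linear; base-level indel structure within a
  block (absent from coords-style input) shifts positions by up to the
  block's length imbalance.
* Duplication blocks map many-to-one: points in the extra copy lift to the
  single partner-copy and round-trip to the primary copy, by construction.
* The IUPAC scanner has no score model; motif densities are comparable only
  within a run, not across motif sets.
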