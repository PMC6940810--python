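# Methods

This note documents the models, conventions and numerical choices behind
`caprameth`, in the order the pipeline runs them.

## Coordinates and formats

Intervals are 0-based half-open internally and 1-based inclusive in every
emitted or consumed file (call tables, GFF3, DMR tables); BED output is
0-based half-open per the BED convention. Call tables are TSV with the
header `chrom pos strand context meth_depth total_depth`. Pipeline outputs
carry a `# caprameth <version> config=<hash> seed=<seed>` provenance header;
the config hash covers the scientific parameters only (not the output
path), so identical configs give byte-identical results.

## Read QC

Two rules, checked in order, both strict inequalities: a read is dropped
when its fraction of unknown bases (any character other than A/C/G/T,
case-insensitive) exceeds 10 %, otherwise when its fraction of bases at
Phred quality ≤ 20 exceeds 40 %. A 100-bp read with exactly 10 Ns or
exactly 40 low-quality bases is kept. Mate-pair linkage (drop both mates
when either fails) exists as an option; the default is per-read semantics
because no pairing rule is inherent in the filters themselves.

## Context classification

A cytosine's context is decided by the two bases 3′ of it on its own
strand: CG, then CHG, then CHH (H = A, C or T). On the minus strand the 3′
direction runs toward lower plus-strand coordinates and bases are read as
complements. Sites closer than two bases to the chromosome end, or with an
ambiguous base in the triplet, have undefined context and are skipped. The
vectorised classifier is tested for exhaustive agreement with a literal
rule enumeration on random sequence, both strands.

## Level pooling

Summaries (genome, chromosome, 2-kb tiling windows, DMR regions) pool
depth-weighted: level = Σ meth_depth / Σ total_depth. Metagene profile bins
instead average site levels unweighted within a bin and then average bin
means across features, so deeply covered sites do not dominate a profile.
Both conventions are deliberate and documented at the functions. CpG dyads
are *not* strand-merged by default; `merge_cpg` (CLI `--merge-cpg`) sums
the two strands' depths for users who want dyad-level calls.

Gene bodies in metagene profiles are length-normalised into 20 proportional
bins by default, because literal 100-bp body bins are ill-defined across
genes of different lengths; flanks always use literal 100-bp bins. The
`--body-mode fixed100` switch restores literal body binning. Features
shorter than the bin count simply use fewer bins.

## DMR calling

Per context, independently:

1. **Eligibility.** A methylated site has total depth > 10 and
   methylation-supporting depth > 4 (both strict) in a given sample.
2. **Chaining.** The union of eligible positions across all samples is
   chained into maximal runs with successive gaps < 200 bp. A run is a
   candidate when its span (first to last site, inclusive) lies in
   [40 bp, 10 kb] and at least one sample has ≥ 5 eligible sites inside
   it. The "more than five methylated cytosines" phrasing is ambiguous
   between ≥ 5 and > 5 and between sites and reads; the default is ≥ 5
   eligible *sites* (prevailing DMR practice), with `min_sites_mode="gt"`
   for the literal strict reading.
3. **Testing.** Samples within a group are pooled by summing depths over
   all covered sites in the candidate (no replicate-variance model — two
   animals per group do not support one). The 2×2 table of pooled
   methylated/unmethylated counts × group is tested with the uncorrected
   Pearson χ² (df = 1, two-sided); fold change is symmetric
   (max/min of the pooled levels). A region is a DMR when fold change > 2
   and p ≤ 0.05 (raw p by default; a BH flag exists but is off, matching
   the published criteria). When any pooled cell is zero, 0.5 is added to
   all four cells before both statistics. A candidate in which either
   group has zero depth is skipped with a logged reason.

Direction is anchored on group 2 (offspring): hyper means group 2 more
methylated. Swapping the group labels exchanges hyper and hypo exactly.

Calibration caveat: because candidate sites are selected on upward
methylation fluctuations (union eligibility), the χ² level on tested
candidates is slightly above nominal in the sparse CHG/CHH contexts
(~6 % observed at α = 5 % across seeds, CG itself at ~5 %). This is a
property of the chain-then-test scheme, shared with any caller built on
these criteria; the fold-change filter removes essentially all such
regions from the final calls.

## DMR-to-gene annotation

A DMR is assigned to every gene (or TE) whose body or ±2-kb flank it
overlaps by ≥ 1 bp, many-to-many; the relation is body when the body is
touched, else the strand-aware upstream2k (promoter side) or downstream2k.
A gene is hypermethylated when any assigned DMR is hyper (likewise hypo;
both labels can coexist). The genome-wide feature distribution assigns each
DMR one primary category by its midpoint with precedence promoter2k > exon
> intron > downstream2k > intergenic (the source criteria give no rule for
straddling DMRs; the midpoint is the least arbitrary single-point rule),
and reports CpG-island overlap as an independent boolean so the partition
property (category counts sum to the DMR count) is preserved.

## Differential expression

FPKM = count / (gene length in kb × library size in millions), with gene
length the exon-model length. The two-group test, standing in for an
external DE package so the pipeline has no heavyweight dependency:

- size factors by the median-of-ratios method (geometric-mean reference
  over genes expressed in all samples; library-size fallback);
- per-gene NB dispersion α by method of moments, (s² − μ)/μ², averaged
  over the two groups, then **moderated from below by the mean estimate
  across all genes**. With two samples per group the per-gene moment
  estimate collapses to zero for a few percent of genes; testing those
  genes at near-Poisson variance inflates the Wald statistic roughly
  five-fold and floods the null with false discoveries. Bounding every
  gene's dispersion by the genome-wide mean (genes may exceed it, not
  undercut it — the same shrinkage direction the established NB tools use)
  restores calibration: measured null rate of q ≤ 0.05 calls ≈ 0.1 %,
  power ≥ 95 % at |log2FC| = 2, mean 500, dispersion 0.05;
- Wald z = log mean ratio (pseudocount 1) / delta-method SE, two-sided
  normal p; BH step-up over all tested genes; genes with all-zero counts
  are excluded from testing and reported NS with a missing p;
- calls: DE-high at q ≤ 0.05 and log2 ratio ≥ 1, DE-low at ≤ −1 (the ratio
  is group 2 over group 1, matching the DMR direction anchor). The source
  also mentions a stricter adjusted p < 0.01 in one figure; the Methods
  threshold q ≤ 0.05 is the default and both are flags.

A precomputed DE table (gene, log2_ratio, p) can be supplied instead
(`calls_from_table`), so results from any external DE tool can drive the
integration.

## Integration and enrichment

Venn cells are exact set intersections of the DM gene sets with the DEG
sets; the hyper∩low and hypo∩high cells are the canonical
methylation-represses-expression pattern and are flagged. Enrichment is the
upper-tail hypergeometric P(X ≥ k) with BH across terms, significant at
adjusted p < 0.05. Backgrounds: all annotated genes for DM-gene enrichment,
all DE-tested genes for DEG enrichment (no background is inherent in the
data; these are the two defensible choices). Real GO/KEGG ontologies are
not bundled — the term map is an input (GMT-like TSV), so results never
depend on a database version.

## Embryo-stage statistics

Stage-success ratio = 100 × success/(failure + success), rounded half-up to
two decimals; overall rows are computed on summed counts, never by
averaging ratios. The packaged fixture transcribes a published cloning
program's 20 batches × 4 stages; every batch and overall ratio reproduces
the printed value exactly. The source's one internal inconsistency — the
2015 cleavage failures+successes (501) differ from the 519 fusion
successes feeding that stage — is transcribed as printed and asserted in
the tests as a property of the source, not repaired.

## The simulator

The simulator generates the study conditions the pipeline is validated
under: two groups of two samples, CG/CHG/CHH baselines 0.70/0.05/0.03,
mean coverage 30× (Poisson; depth overdispersion is out of scope), planted
DMR effect 0.5 with both signs, NB expression counts (default mean 500,
dispersion 0.05) with planted |log2FC| = 2 DEGs, a configurable subset
linked to promoter DMRs of the opposite sign.

**Methylome landscape.** CG methylation is laid down as alternating
highly methylated "sea" domains (2–8 kb) and unmethylated valleys
(400–900 bp at level 0.01), mimicking a mammalian methylome punctuated by
CpG-island-like troughs. The sea level is solved per genome from the
realised valley site fraction so the genome-wide mean equals the requested
`cg_level` exactly in expectation. Valleys are wide and unmethylated enough
that eligible-site chains terminate there, making each domain a separately
testable region — on a uniformly methylated genome the chain rule would
join entire chromosomes into one over-long run that the 10-kb cap
discards, and no caller built on these criteria could work. Planted DMRs
occupy whole domains (resized to the requested length, guarded by valleys
on both sides) so the chain a caller finds coincides with the truth
interval; inside them the low group sits at 0.3 and the high group at
0.3 + δ (the baseline-±δ construction cannot represent a hypermethylation
gain of 0.5 from a 0.7 baseline), giving a true-level fold change of 2.67.
Per-site true levels wobble around their mean by a Beta with concentration
80; outside planted DMRs both groups share the same per-site draw, so
between-group noise is purely binomial and the null χ² level is honest.

**What the simulator does not model**, and hence what passing tests do not
show about real data: sequencing error and bisulfite non-conversion,
coverage overdispersion and mappability gaps, strand-asymmetric
methylation, biological replicate variance beyond sampling noise,
correlated gene expression, and real genome structure (repeats, real CpG
island statistics). Recovery scores on this generator are best-case
figures for the criteria themselves, not field performance estimates.

**Reads.** QC-benchmark reads carry exact planted label counts: failing
reads exceed the 10 % N or 40 % low-quality thresholds by construction,
and passing reads include boundary cases sitting exactly at both
thresholds, so the filter's strict inequalities are pinned.

## Problem sizes

The test suite and acceptance script use 100–600 kb genomes, 20–40 planted
DMRs, 200–300 genes and five seeds per stochastic benchmark — sizes chosen
so every planted effect is comfortably detectable under the stated depths
and effect sizes while a full run stays in the seconds-to-minutes range.
Sensitivity and precision of DMR recovery are scored at ≥ 50 % reciprocal
interval overlap with matching direction.

## Known limitations

- The χ² DMR test models no biological replicate variance; with two animals
  per group, group-level conclusions ride on pooled counts (a beta-binomial
  caller is explicitly out of scope).
- The NB Wald test is a pragmatic stand-in: no shrinkage of fold changes,
  no outlier handling, normal-tail p-values at n = 2 per group.
- The feature-distribution vocabulary (promoter2k/exon/intron/
  downstream2k/intergenic + CGI flag) is one reasonable choice; sources
  differ on shore/shelf categories.
- Whether "hyper" anchors on the offspring group is a convention
  (configurable via the group order).
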