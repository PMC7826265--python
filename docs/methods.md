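# Methods

This note documents the models, statistics, and design choices behind
`mutatlas`, in the order the pipeline runs them.

## Consensus somatic calls

Per-sample call sets from four callers (MuSE, MuTect2, VarScan2,
SomaticSniper) are read as VCF 4.2. Because the four tools place read
support and quality fields differently, the package fixes one explicit
dialect contract per caller (see `mutatlas/dialects.py`): all callers
report `FORMAT/AD` as `ref,alt` read counts on TUMOR/NORMAL columns;
the somatic score SSC lives in `INFO/SSC` (VarScan2) or `FORMAT/SSC`
(SomaticSniper); the tumor alt-read base quality lives in `FORMAT/BQ`
(MuSE) or `INFO/MBQ` (MuTect2). Allele frequencies are derived as
`alt/(ref+alt)`. This contract is an emulation of heterogeneous caller
output, not a claim about any specific archive's internals.

Only PASS records enter the pipeline. A call is then retained iff every
*applicable* criterion holds:

1. **alt reads** — ≥ 2 tumor alt-supporting reads, enforced only when the
   matched normal has zero alt-supporting reads. When the normal shows alt
   reads, criterion 2 governs instead. (The alternative — enforcing the
   read minimum unconditionally — is a one-line change in
   `passes_reliability_filters`; the conditional reading follows the
   criterion's own parenthetical scope.)
2. **frequency ratio** — tumor alt-read frequency ≥ 5× the normal's,
   enforced when the normal frequency is > 0. The boundary is inclusive;
   a zero normal frequency counts as an infinite ratio.
3. **SSC** — strictly > 30, only where the caller reports one.
4. **BQ** — strictly > 20, only where the caller reports one.

An absent field never rejects a call.

Calls surviving the filters are merged across callers on the key
(sample, chrom, pos, ref, alt) so that a variant seen by several callers
appears once, with the union of supporting callers. Indel representations
are parsimony-normalized first (shared suffix then shared prefix trimmed,
position advanced), which makes anchor-base variants from different
callers collapse to one canonical key without needing a reference genome.

Mutations are restricted to the analyzed gene regions — coding exons
extended by 2 nt on each side, supplied as BED. Regions of different genes
must not overlap (validated at load); a retained mutation is assigned the
gene of its containing interval.

## Consequence classification

A deliberately simple single-transcript CDS model replaces a full
variant-effect predictor (multi-transcript ranking and HGVS engines are
out of scope). Each gene carries ordered coding-exon intervals, a strand,
and the spliced CDS. SNVs are classified by codon translation
(missense / synonymous / nonsense; disruptions of the start or stop codon
are `start_stop`), indels by length mod 3 (frameshift vs in-frame), and
any variant anchored in the 2-nt windows flanking an *internal* exon
junction is `splice_site`. The terminal extensions of the first and last
exon have no adjacent intron and classify as `other`, as do
multi-nucleotide substitutions. The deleterious class is
{frameshift, nonsense, splice_site}; start/stop and complex changes are
tallied separately.

## Cohort statistics

* **Hypermutated samples** — exome-wide burden strictly greater than
  10,000 mutations; flagged samples and their panel mutations are removed
  before every downstream statistic.
* **Mutation density** — mutations per kbp of analyzed coding sequence.
* **Mutated-sample frequency** — per gene × cancer, the percentage of
  samples with ≥ 1 mutation (a sample counts once however many mutations
  it carries), plus a pan-cancer column.
* **Overmutation** — per gene × cancer, a one-sided (greater) Fisher exact
  test on the 2×2 table of mutation counts {gene, other panel genes} ×
  {cancer, rest of cohort}. Two ambiguous choices are flags with
  documented defaults: counts are *mutations* (not mutated samples;
  `count_samples=True` switches), and the background *excludes* the tested
  cancer (`include_self=True` switches). Bonferroni over the gene × cancer
  grid controls the family-wise error; with a 29-gene × 33-cancer grid the
  nominal per-test cut for adjusted p < 0.05 is 0.05/957 ≈ 5 × 10⁻⁵, which
  is why `overmutation_nominal` defaults to 0.00005.
* **Hotspots** — residues (gene, AA position) carrying ≥ 3
  protein-changing mutations by default; 3 is the smallest recurrence the
  analysis treats as a hotspot and is configurable. Indel hotspots group
  by the same protein-level key. Printed percentages round half-up.

## miRNA differential analysis

Two expression dialects are supported. *Batch-normalized* levels are
additively comparable and may be negative; *RPM* levels (reads per million
miRNA-mapped) are non-negative counts. Undetectable means exactly zero;
miRNAs zero in more than 30% of samples (pan-cancer) or 10%
(single-cancer) are dropped.

For pan-cancer comparisons, each miRNA is normalized within each cancer
type to median 0 and range within [−1, 1] by subtracting the per-cancer
median and dividing by the maximum absolute deviation from it. Among the
transforms compatible with "median 0, range −1..1", this one preserves the
median exactly, maps constant miRNAs to 0, and is idempotent; a min–max
variant would not keep the median at 0.

Mutation groups: *mutated* = samples with ≥ 1 mutation of the requested
class in the gene; *reference* = samples with no mutation of any class in
that gene. Samples carrying only other-class mutations in the gene belong
to neither group, so class effects are never diluted by the reference.

The differential test is a two-sided Wilcoxon rank-sum per miRNA — exact
enumeration when the smaller group has ≤ 8 samples and the data are
tie-free, otherwise the normal approximation with tie correction. The
effect size is the difference of group medians on the normalized (or any
log) scale and the log₂ fold change of medians (pseudocount 1 RPM) on the
RPM scale. Volcano-style outputs report nominal p-values, with
Benjamini–Hochberg adjusted values as an extra column; significant-miRNA
counts quoted at p < 0.05 are nominal by design.

**Reference re-normalization.** Total-count normalization makes a global
5p deficit masquerade as a 3p increase. To separate real 3p changes from
this artifact, RPM levels are re-expressed per sample relative to a
reference miRNA whose maturation bypasses the perturbed nuclease
(miR-451a, which is processed independently of Dicer):
`log2(x + 1) − log2(x_ref + 1)`. The transform cancels any per-sample
global rescaling exactly and zeroes the reference row; a plain-ratio
variant is available. **Arm asymmetry** then counts 5p- vs 3p-annotated
miRNAs (arm taken from the canonical `-5p`/`-3p` ID suffix; unsuffixed
miRNAs are excluded) among significantly down- and upregulated results and
tests the arm × direction table with a two-sided Fisher exact test.

## isomiR main fractions

For 3p-miRNAs whose per-sample total RPM has cohort median ≥ 100 (median
rather than mean/min so single outlier samples cannot promote or demote a
miRNA; configurable), the main 5′ isoform is the offset with the highest
total RPM across the *unmutated reference samples*, defined cohort-wide so
that group comparisons always address the same isoform (a per-sample
definition is available behind a flag). Per sample, the main fraction is
that offset's share of the miRNA's total RPM; upstream/downstream minor
fractions complete the unit sum. All-zero samples are excluded and
counted. Groups are compared per miRNA and pooled with the rank-sum test;
groups with fewer than 3 informative samples yield a missing p-value with
a warning.

## Clinical association

Survival uses Kaplan–Meier product-limit curves per group, the log-rank
test for the comparison, and a univariate Cox proportional-hazards fit on
the group indicator (Breslow tie handling) for the direction and magnitude
of the effect. Stage association stratifies by cancer type with the
Cochran–Mantel–Haenszel test (no continuity correction; with one stratum
it reduces to (n−1)/n times the Pearson chi-square), alongside per-cancer
Fisher tests. Stages dichotomize early (I–II) vs late (III–IV); sub-stage
suffixes (IIIa…) reduce to the base numeral; both choices are
configurable. Copy-number co-occurrence partitions samples by mutation
class (priority hotspot > deleterious > other when a sample carries
several), counts thresholded calls ≤ −1 as deletions (shallow or deep)
and ≥ +1 as amplifications, and Fisher-tests deletion × mutation presence.

## Synthetic cohort generator

The generator emulates every input with planted, fully recorded effects:

* **Genes** — random CDSs (start codon, no internal stops, terminal stop)
  split into exons with 300-bp introns, one gene per contig; defaults give
  a six-gene panel with realistic protein lengths on both strands.
* **Mutations** — hotspot missense carriers at configured residues and
  cancer types; per-gene deleterious carriers (nonsense / frameshift /
  splice at 0.45/0.45/0.10); Poisson benign background (missense or
  synonymous), inflated 10× in hypermutated samples. Every planted
  mutation appears in 1–4 callers with field values drawn to pass all four
  reliability criteria; noise calls are constructed to violate exactly one
  named criterion each, and non-PASS records exercise the PASS filter.
* **Expression** — per-miRNA baselines (Gaussian on the normalized scale,
  log-uniform on the RPM scale); carriers of the arm-effect mutation class
  are shifted additively (normalized) and by 2^shift (RPM) on 5p- and
  3p-annotated miRNAs, sparing the reference miRNA; a small set of
  low-expression miRNAs has planted dropout to exercise the detectability
  filter. Noise is additive Gaussian (sd 1.0) on the normalized scale and
  log-normal (sd 0.5 in log₂) on the RPM scale — additive where levels can
  be negative, multiplicative where they are counts.
* **isomiRs** — per sample and 3p-miRNA, total RPM is split over 5′
  offsets (−1, 0, +1) by a concentrated Dirichlet (main fraction ≈ 0.96,
  concentration 300, so the null main-fraction median exceeds 0.95);
  carriers of the nuclease hotspot or deleterious mutations have the main
  fraction reduced by `main_fraction_shift` (default 0.05).
* **Survival** — exponential event times under proportional hazards
  (baseline 1/1000 per day) with uniform censoring over a 3000-day
  follow-up (~25–30% censoring at these hazards); carriers of the survival
  effect class have their hazard multiplied by the configured ratio.
* **Copy number** — thresholded calls in {−2..2}; deletions enriched in
  mutated samples of the CNV-effect gene (0.6 vs 0.1 by default).

All randomness derives from `config.seed` through fixed per-family stream
offsets with per-sample substreams, so bundles are byte-reproducible and
appending samples does not reshuffle earlier ones.

**What the generator does not model** — and hence what green tests do not
show about real data: read-level evidence (no FASTQ/BAM, so no alignment
artifacts), trinucleotide mutational signatures, germline contamination,
transcript isoform complexity, correlated miRNA co-expression structure
(miRNAs are independent given the group), batch effects, and non-uniform
clinical follow-up. Recovery results demonstrate that the statistics
detect the effects they were built for at the stated sizes, not that real
cohorts behave this way.

## Problem sizes and numerical choices

Default test and validation runs use deliberately modest sizes chosen to
exercise every code path at comfortable statistical power: six cancers ×
40 samples for end-to-end runs; 200 mutated / 200 reference samples for
arm-asymmetry recovery (100 replicates); 500/500 with ~30% censoring for
survival recovery (200 replicates); 10⁴ null miRNAs for type-I
calibration; 10⁴ randomized records for the filter oracle; exhaustive
Fisher-vs-enumeration agreement for 2×2 tables with margins ≤ 30 plus a
2000-table random sample with margins ≤ 60 (|Δp| ≤ 1e−12).

Degenerate inputs are handled explicitly: constant miRNAs give p = 1 and
effect 0; empty contingency margins give p = 1 with a warning; a cancer
type with a single sample is a normalization error; identical survival
groups give log-rank p = 1 and HR = 1. Ties in the rank-sum test fall back
to the corrected normal approximation. Printed percentages round half-up.

One validation suite is expected to sit at the edge of its own tolerance:
with 500/500 samples and ~30% censoring there are ~690 events, so the Cox
estimator's se(log HR) ≈ 0.08, and the recovery band [1.7, 2.3] around a
true HR of 2 corresponds to only ±1.7–2.0 standard errors — per-replicate
coverage ~93–95%, right at the suite's 95% pass requirement. The estimator
itself is unbiased (mean log HR ≈ log 2 across replicates); the strict
replicate-count assertion is kept as is rather than widened.
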