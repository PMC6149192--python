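# Methods

pdxkit implements the genomic analyses of a patient-derived xenograft (PDX)
precision-oncology workflow as a tested library: xenograft read
deconvolution, read-density copy-number estimation with a panel-of-normals
baseline, amplicon-panel copy-number preprocessing, somatic-variant
filtering and substitution-spectrum analysis, RPKM/fold-change expression
analysis, and a plasma cell-free-DNA (cfDNA) qPCR copy-ratio biomarker
calibrated against Epstein–Barr virus (EBV) DNA load. A synthetic-data
module generates every input with the statistical structure the estimators
assume, so each estimator can be validated by parameter recovery against
planted truth.

## Xenograft read deconvolution

PDX sequencing mixes human tumor reads with mouse stromal reads, which must
be discarded before any quantitative analysis. The production approach —
aligning to both genomes and dropping mouse-mapping reads — is a binary
keep/discard contract; pdxkit implements that contract with canonical k-mer
containment, which is deterministic, alignment-free and fast at desk scale.

Each read's k-mers (canonical form: lexicographic minimum of a k-mer and
its reverse complement, because read strand is unknown) are counted against
prebuilt indexes of the two references. A read is called for the genome
whose index contains at least `margin` more of its k-mers; otherwise it is
**ambiguous**. Ambiguous reads are excluded from downstream counts and
reported — the class is made explicit rather than silently assigned,
because a read matching both genomes equally carries no species signal.
Defaults `k = 15`, `margin = 1`: at the simulated 10% inter-species
divergence the probability that a 15-mer survives unchanged in both genomes
is 0.9^15 ≈ 0.21, so a 100 bp read scores ≈ 86 against its own genome and
≈ 18 against the other, and margin 1 prevents exact ties from passing. On
5,000 labeled synthetic reads the classifier exceeds 99% accuracy; with
identical references every read of length ≥ k is ambiguous, by
construction.

Sequencing errors are simulated at 1% per base by default; they reduce the
own-genome score roughly by a factor 0.99^15 ≈ 0.86 and do not affect the
margin decision in practice.

## Read-density copy-number estimation

For a gene *g* with total (merged) exon length L(g) and uniquely mapped
read count c(g), the read density is d(g) = c(g)/L(g). The diploid
reference is the per-gene mean density of a panel of normal-karyotype white
blood cell (WBC) samples. The copy number is

    cn(g) = ploidy(g) · [ d_tumor(g) / d_panel(g) ] / m

where ploidy(g) is 2 for autosomes and 1 for sex chromosomes (all samples
are modeled as male; a female mode is rejected explicitly rather than
mishandled), and *m* is the median of the density ratio over autosomal
genes. The median-centring makes the estimate invariant to a global
scaling of the tumor library — the standard normalization of read-depth
CNV tools — under the assumption that the median autosomal gene is
copy-neutral. Genes with zero panel density are omitted and logged, not
imputed. Inputs must already be unique-read counts; the module does not
re-deduplicate.

Gain/loss calls default to cn ≥ 3.0 (gain) and cn ≤ 1.0 (loss) on the
autosomal scale, rescaled by ploidy/2 on sex chromosomes, with closed
boundaries. These defaults describe one-copy changes in the *true* copy
number; when calling from a noisy continuous estimate, thresholds at the
midpoints between copy states (2.5 / 1.5) are the appropriate decision
boundaries and are what the recovery tests use — an unbiased estimate of a
true 3-copy gene falls below 3.0 half the time, so boundary-exact
thresholds would miss half of all one-copy events at any finite depth.

Profile concordance is the Pearson correlation of log2(cn + 0.01) over the
shared gene set (≥ 3 genes; zero-variance profiles are an error, not
r = NaN). The pseudocount keeps homozygous deletions finite on the log
scale. Two tumors simulated from the same truth correlate at r > 0.9; a
tumor against an independently simulated diploid sample gives |r| < 0.2 at
200 genes — the correlation structure one expects between a tumor and its
archival counterpart versus a tumor and blood.

At depth 100 reads/kb and a 4-sample normal panel, planted copy numbers in
{0, 1, 2, 3, 6} over 200 genes are recovered with mean absolute error
< 0.3 (typically ≈ 0.14).

## Amplicon-panel copy number

Targeted panels amplify exons in primer pools, which induces pool- and
amplicon-level count bias. Preprocessing, evaluated on the control
samples:

1. **Detectability**: amplicons with zero mean count are removed.
2. **Low count**: amplicons with mean ≤ the 5th percentile (linear
   interpolation; ties at the threshold removed) of detectable amplicons'
   means are removed. The threshold is established once from the full
   detectable panel and returned, so the filter can be re-applied
   idempotently with the recorded threshold; recomputing a percentile on
   its own survivors would trim a new bottom 5% on every pass, which is
   why a literal re-run is not idempotent.
3. **High variability**: amplicons with CV = sd/mean ≥ 0.3 across control
   samples are removed, using the sample (n−1) standard deviation. CV is
   computed across control samples (not replicates); a single control
   provides no variability evidence and removes nothing.

Pool normalization rescales each pool's counts per sample so all pool
medians equal the sample's global median (a "unit" target is available for
pure relative values); within-pool relative values are preserved.

Gene copy number is 2 × the median over the gene's amplicons of the
tumor/normal count ratio, after dividing each sample column by its median
over shared amplicons (so a global tumor-library scaling cancels). The
median-of-ratios aggregation replaces full segmentation: gene-level copy
number is what the downstream biomarker needs, and the median is robust to
single-amplicon outliers. On a scaled-down panel (40 genes × 10 amplicons,
emulating a 409-gene/15,992-amplicon design), panel-based and read-density
profiles of the same truth correlate at r > 0.9.

## Somatic variants and substitution spectrum

Retention rules, with boundary semantics taken literally from their
phrasing: coverage "lower than 25" removed ⇒ retained at exactly 25; VAF
"lower than 5%" removed ⇒ retained at exactly 0.05; population MAF
"> 1%" removed as a polymorphism ⇒ retained at exactly 0.01 or when no
population record exists. The removal report counts each rule
independently. The "frequency" filter is interpreted as variant allele
frequency (the fraction of reads supporting the alternate allele, taken
from the input table, never recomputed) because the population-MAF rule is
stated separately.

The substitution spectrum is tallied over the 12 ordered ref>alt classes
with **no** pyrimidine-strand collapsing, because C>T and G>A are reported
as distinct classes in this context. Percentages sum to 100 when the total
is positive and are reported as undefined (None) — not 0 — for an empty
set.

Because the original five-tumor mutation list is not publicly deposited,
the package ships a deterministic synthetic stand-in
(`simulate.synthetic_snv_catalog`): 282 records whose class counts follow
the largest-remainder quota of the default spectrum (C>T 26.2%, G>A 20%,
remainder uniform) across five tumors with 34–99 variants each. Recomputing
the spectrum from it returns C>T 26.24% and G>A 20.21% — 282 records cannot
realize the one-decimal percentages exactly.

## Plasma cfDNA biomarker

**Quantification.** Copy numbers come from the comparative-Ct (ΔΔCt)
method: replicate Cts are averaged (replicates > 0.5 cycles apart are
flagged), ΔCt = Ct(target) − Ct(RAD52) within a sample, ΔΔCt subtracts the
healthy-PBMC calibrator's ΔCt, and CN = 2·A^(−ΔΔCt) with amplification
factor A = 1 + efficiency (2 at perfect doubling, the default; an
efficiency-corrected mode is available). RAD52 serves as the copy-neutral
internal control. A non-detected target is reported as CN 0 with a flag;
zero-noise generated data round-trips to the planted copy number at
machine precision.

**Ratio and regression.** The biomarker is the ratio CN(CCND1)/CN(CDKN2A)
with the denominator floored at ε = 0.05 (flagged) so homozygous CDKN2A
deletions give a very large but finite ratio. The ratio is regressed on
x = log10(EBV copies/ml) by ordinary least squares; the log base is
confirmed by the reference worked example, 11.11·log10(5000) − 36.93 =
4.17 ≈ 4 (natural log would give ≈ 57.7). Samples with non-positive load
are excluded with a warning; a constant ratio returns slope 0 with r
reported as 0 by convention.

**Classification.** A patient is a CDK4/6-inhibitor candidate when
ratio > cutoff, strictly, with default cutoff 4 — the ratio the reference
regression predicts at ~5000 EBV copies/ml, the load at which clinical
deterioration is expected. A ratio exactly at the cutoff is not a
candidate.

## Expression analysis

RPKM(g, s) = counts(g, s)·10⁹ / (library_size(s)·length(g)), with library
sizes the column sums. Genes are quantifiable at ≥ 10 total reads across
the samples of a comparison (the summation scope is a documented choice;
the source rule states no scope). A gene is differentially expressed when
its fold change — the ratio of pseudocounted (+1 read), depth-normalized
condition means, so label-swapping maps fc to 1/fc — is ≥ 2 or ≤ 0.5 *and*
p < 0.05. The count test is self-contained rather than a dispersion-
modeling package: an exact conditional binomial test on pooled counts for
1-vs-1 designs (conditioning on the gene's total, null success probability
= treated library share), and a two-sample t-test on log2(normalized + 1)
for replicated designs. No multiple-testing correction by default,
matching the stated p < 0.05 rule; Benjamini–Hochberg is available as an
option. On 3-vs-3 replicates with 50 genes planted at 4-fold among 2000,
recall ≥ 0.8 at ≤ 5% false positives (typically 100% / 0).

## Synthetic-data generators

All randomness flows from one integer seed through named sub-streams (one
per output), so individual files are reproducible and identical
configurations give byte-identical outputs. Every generator has a
zero-noise mode in which the downstream estimator recovers truth exactly.

- **References**: two chromosomes ("autosome", 20 kb; "chrX", 10 kb),
  uppercase ACGT; the mouse-like genome substitutes each base independently
  with probability `divergence` (default 0.1). This exercises the
  autosome/sex baseline logic minimally; it does not model repeats, indels
  or GC structure, so classifier accuracy on real genomes (with repetitive
  and homologous regions) will be somewhat lower than on these tests.
- **Reads**: uniform positions, hidden origin labels, 1% base errors,
  constant Q30 qualities. No paired ends or quality gradients.
- **Coverage**: Poisson counts with mean depth·L(g)/1000·CN(g)/ploidy(g)
  (depth default 100 reads/kb); normals at CN = ploidy. Poisson is the
  simplest model matching the read-density semantics; real exome counts
  are overdispersed, so real-data errors exceed the simulated ones.
- **Variants**: classes multinomial from the configured spectrum; planted
  fractions (default 10% each) independently fail the coverage, VAF and
  MAF filters, with exact bookkeeping returned for testing.
- **Plasma cohorts**: loads log-uniform on (5×10³, 4×10⁵) copies/ml — the
  upper bound chosen so the expected fraction of samples above 10⁵ is 7/22,
  matching the reference high-load cohort's composition; ratio =
  11.11·log10(load) − 36.93 + N(0, 8.7), floored at 0.01. The residual sd
  8.7 is derived from the target Pearson correlation 0.576 via
  r = s/√(s²+σ²) with signal sd s = slope·width/√12; the Normal residual
  model itself is an assumption (the true noise structure of plasma CNV
  measurements is unknown) and is exposed in the configuration. CDKN2A is
  drawn from {2, 1, deletion (CN 0.05)} with one-copy-loss probability
  ramping linearly from 0 at 5×10³ to 0.7 at 10⁵ copies/ml and constant
  above; CCND1 = ratio × CDKN2A, so the per-sample ratio reproduces the
  linear model exactly and both per-gene directions (CCND1 gain, CDKN2A
  loss) emerge; RAD52 ≈ 2 with sd 0.1. Under these defaults the expected
  cohort statistics are r ≈ 0.58, OLS slope ≈ 10.5 (the ratio floor
  slightly flattens the fitted line relative to the generating slope
  11.11), mean CCND1 CN ≈ 21, and ≈ 70% one-copy CDKN2A loss above 10⁵
  copies/ml.
- **qPCR**: Ct = base_Ct(target) − log_A(CN/2); CN 0 emits a non-detect;
  optional per-replicate Ct noise.
- **Expression**: per-gene means log-normal (σ = 1) around 100; planted
  genes all up-regulated at the configured fold change (a deliberate
  simplification — direction labels are returned); counts Poisson.

Passing recovery tests on these generators demonstrates the estimators are
correct under their own model assumptions; they do not demonstrate
robustness to overdispersion, GC bias, batch effects, tumor purity or
subclonality, none of which are simulated.

## Problem sizes and numerical choices

Default test/validation sizes are deliberately modest — 20–30 kb genomes,
5,000 reads, 200 genes, 400 amplicons, 22-patient cohorts (averaged over
50–100 seeded replicates where a cohort-level mean is asserted) — chosen
so the full validation suite runs in minutes while keeping every asserted
statistic well inside its sampling tolerance. Stochastic assertions use
fixed seeds and 3-SD (or stated) bounds computed from the generating
model. Floating-point outputs are serialized with 6 significant digits;
tests compare numerically with explicit tolerances, never via serialized
strings. BED input is 0-based half-open; variant positions are 1-based;
conversions are centralized in the readers.

## Known limitations

- No segmentation, GC/length correction or arm-level aggregation: copy
  number is strictly per-gene.
- Only male baselines (2 autosomal / 1 sex); female samples are rejected.
- The qPCR normalization formula of the original assay is not published;
  the ΔΔCt model with perfect doubling is a documented stand-in, and
  primer efficiencies default to ideal.
- The DEG test substitutes a simple exact/t-test for negative-binomial
  dispersion modeling; with one sample per condition its p-values are
  anti-conservative for overdispersed data.
- Indels are skipped everywhere; the spectrum covers single-nucleotide
  substitutions only.
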