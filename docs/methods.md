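# Methods

`eqtlkit` re-creates, on fully synthetic data with known ground truth, the
analysis chain used to build a multi-study molecular-QTL compendium: genotype
and expression quality control, cis-eQTL mapping with permutation-based
empirical p-values, single-effect Bayesian fine mapping, cross-dataset
harmonization of independent signals, effect-size sharing summaries, and
approximate-Bayes-factor colocalization summarized over LD blocks.  This note
documents the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic data do and do not establish.

## Synthetic data

**Genotypes.**  Haplotypes follow a first-order Markov copying process: the
allele at variant *j* is copied from variant *j − 1* with probability
`ld_rho` and drawn fresh from Bernoulli(MAF) otherwise; dosages are the sum
of two independent haplotypes.  When adjacent MAFs are equal, the adjacent
haplotype (and dosage) correlation equals `ld_rho` exactly, which gives a
closed-form handle for LD-sensitive tests.  This model has no recombination
map, demography, or admixture; LD decays geometrically (`ld_rho^d`), which is
faster and more regular than real human LD.  Tests that pass here show the
methods behave correctly under a known LD law, not that they are robust to
realistic LD pathologies (e.g. long-range haplotypes).

**Expression.**  A trait is `beta * dosage + loadings @ covariates + N(0,
noise_sd)` — a single cis effect per gene, Gaussian noise, linear covariate
structure.  Real expression counts are overdispersed, GC-biased and
heavy-tailed; the pipeline addresses that by mapping everything through TPM
and a rank-based inverse normal transform (INT), after which the Gaussian
generator is the intended input scale.  GC-content (conditional quantile)
normalization of the upstream counts is deliberately out of scope; TPM + INT
stands in for it, which discards mean-variance and GC structure rather than
modeling it.

**Cross-dataset sharing.**  No generative model for cross-tissue eQTL
sharing is established in the literature this package mirrors (the published
estimators — Mash, matrix factorization — are descriptive), so the generator
plants a simple group-activity structure as a stand-in: each signal picks a
dataset group uniformly; with probability *f* every group member is active
with one common effect, otherwise a single uniformly chosen member is
active.  Observed effects add N(0, `se_scale`) noise; inactive entries are
explicit missing values (NaN), never zeros — the zero/one substitution is a
property of the downstream effect-matrix construction, not of the truth.
Under the default sharing denominator ("non-missing in at least one of the
pair"), the within-group sharing estimand is `f / (f + 2(1 − f)/m)` for
groups of *m* datasets, which equals *f* exactly only when *m* = 2.  Sharing
recovery is therefore evaluated on two-member groups; larger groups are used
where only cluster structure (not the value of *f*) matters.

**Seeding.**  All randomness flows from one integer seed.  Each operation
draws from a child generator keyed by (seed, CRC32 of an operation label),
so stages can be regenerated independently and identical seeds reproduce
byte-identical outputs.

## Genotype QC

Pre-imputation filters remove variants with Hardy-Weinberg p < 10⁻⁶
(asymptotic 1-df chi-square against expected genotype proportions; the exact
test is a noted alternative, not implemented; monomorphic variants return
p = 1 by convention), missingness > 0.05, or MAF < 0.01.  Post-imputation
filters remove MAF < 0.01 or imputation R² < 0.4, combined with OR.  All
thresholds are strict inequalities, so boundary values are retained.

LD pruning is a greedy left-to-right windowed scan (defaults 50 000 variants
per window, step 200, r² > 0.05 drops the later variant), deterministic in
column order.  PCA is SVD on the centered/standardized matrix with a fixed
sign convention (largest-magnitude loading positive) so outputs are
reproducible.  Superpopulation assignment computes, on the first three PCs,
the mean Euclidean distance from a sample to each reference population's
members and assigns the closest label iff second-closest/closest ≥ 1.7
(inclusive at the boundary); a single-population panel assigns
unconditionally (ratio +∞).  The reference panel is an explicit input — the
package does not decide whether reference PCs are projected or recomputed.

## Expression normalization

TPM divides the per-trait count rate (count/length) by the per-sample rate
sum, times 10⁶; all-zero samples warn and stay zero.  A trait is dropped
when the fraction of samples with TPM < 1 is ≥ 0.95 (the boundary itself is
read as excluded-at-0.95, tested explicitly).  Median expression profiles
for dataset-similarity analyses keep genes with median TPM ≥ 1 and use
log₂(x + 1); the +1 pseudocount is a package choice.  Usage ratios divide a
transcript's (or event's) TPM by its gene/event-group total per sample, with
zero totals producing missing values.  Sex inference compares log₂(XIST
TPM + 1) against the mean TPM of Y-chromosome genes with configurable
cutoffs (both default 1; upstream practice was visual inspection, so there
is no canonical number); both-high or both-low patterns are labeled
ambiguous as a contamination signature.  The INT uses averaged tied ranks
and the offset (rank − 0.5)/n (Blom's constant is a noted alternative);
missing values are preserved.  Covariate regression fits per-trait OLS
against an intercept plus covariates and errors on rank deficiency, naming
the collinear columns via pivoted QR.

## cis-QTL mapping

The nominal scan regresses each trait on each variant's dosage inside a
±1 Mb window around the gene's cis anchor, with the first six genotype and
six phenotype PCs entered as covariates (implemented by shared
residualization with full-model degrees of freedom n − 2 − k, which is
numerically identical to the joint fit).  Traits with fewer than five
cis variants or zero variance are skipped with reason codes.  The anchor is
the strand-aware transcription start.

The permutation scheme is grouped: the observed statistic is the minimum
nominal p over all variants and all traits of a gene group, each permutation
shuffles sample labels jointly across the group's traits (preserving
cross-trait correlation), and the empirical p is
(1 + #{permuted min ≤ observed min}) / (n_perm + 1) with 1 000 permutations
by default.  Direct counting replaces the beta-distribution approximation
used by some tools; the +1 smoothing bounds the p away from 0.  Phenotypes,
not genotypes, are permuted (after residualization) — the standard fast
approximation.  Genes are called significant by Benjamini-Hochberg across
group empirical p-values (q-value estimation is a noted alternative).

## Fine mapping

A single-effect model: assuming one causal variant with effect prior
N(0, W²), per-variant Wakefield log approximate Bayes factors are
`0.5·log(1 − r) + 0.5·z²·r` with `r = W²/(se² + W²)`; PIPs are the softmax
of the log ABFs under a flat prior over variants, and the 95% credible set
is the smallest PIP-sorted prefix reaching 0.95 cumulative mass (ties broken
by position, then alleles; equality at the coverage boundary is included
with a 10⁻¹² tolerance).  W defaults to 0.15 on the INT trait scale.  Inputs
are the INT-transformed trait and dosages with the 6+6 PCs regressed out.
Multi-signal regions are a known limitation: a multi-effect model (e.g.
sum-of-single-effects with L > 1) would emit one credible set per signal,
whereas this model fine-maps only the strongest effect; the downstream
harmonization consumes credible sets with PIPs and is agnostic to which
fine-mapping model produced them.

## Harmonization of independent signals

Credible sets are filtered to confident ones — size < 30 and maximal
univariate |z| > 3, both strict — and a set associated with several genes
yields one record per gene (these multi-gene links are also the basis of the
pleiotropy fraction).  Per gene, sets from different datasets join the same
connected component iff they share at least one variant, with transitive
closure (union-find keyed by variant membership; verified against an O(n²)
transitive-closure oracle).  Within a component, candidate leads are the
variants contained in member sets from the largest number of datasets; the
lead is the candidate with the largest |β| in any dataset ("largest effect
size" is read as largest absolute value since signs differ across datasets),
with deterministic position-then-allele tie-breaking added because no
canonical rule exists.  Components whose retained variants have no measured
effect anywhere are dropped with a reason; components supported by a single
dataset are retained and flagged via `n_datasets`.

Transcript-level traits (exon, transcript usage, splicing/promoter events)
are highly correlated within a gene, so they take a separate path: per
(gene, dataset) the smallest credible set is kept (ties: largest member
PIP), one per-dataset selection is drawn uniformly at random per gene
(seeded), and the lead is chosen by support then |β| as above.

The effect matrix places lead-variant β and SE per dataset from the nominal
scan; unmeasured entries become β = 0, SE = 1 with the missingness mask kept
alongside, because downstream sharing treats an unmeasured eQTL as evidence
of absence in that dataset.

## Sharing and MDS

Two effects are shared iff same sign and magnitude ratio ≤ 2 (inclusive at
exactly twofold; zeros never share).  The sharing matrix divides shared by
eligible signals per dataset pair; the default denominator counts signals
measured in at least one of the two datasets (so zero-substituted entries
count against sharing), approximating the "significant in at least one"
convention of posterior-based estimators; a "both measured" policy is
selectable.  Posterior shrinkage of effects (Mash-style) is deliberately not
implemented — sharing operates on raw or externally shrunken β.

Non-metric MDS is Kruskal's formulation: disparities are fitted by
pool-adjacent-violators isotonic regression of configuration distances on
the dissimilarity order (ties use the primary approach — tied blocks are
pre-sorted by current distance so they do not constrain each other), and the
configuration is updated by SMACOF/Guttman majorization from a classical
(Torgerson) initialization.  Stress-1 = √(Σ(d − d̂)²/Σd²) is recorded every
iteration; iteration stops when stress would increase (keeping the previous
configuration) or improves by less than `tol`, so the reported history is
non-increasing.  An all-zero dissimilarity matrix returns the zero embedding
with stress 0 rather than erroring.

## Colocalization

Per-variant Wakefield log ABFs for the eQTL and GWAS traits combine into
posteriors over five hypotheses with priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ (the
standard defaults; configurable).  All sums use log-sum-exp; H3's
cross-term subtraction is done in log space via log1p, and H3 is exactly
zero for single-variant regions.  Equivalence with brute-force enumeration
over all causal-variant configurations is tested on regions of ≤ 10
variants.  Variants are matched by (chrom, pos) with allele harmonization:
swapped ref/alt flips β, strand-palindromic (A/T, C/G) variants with
MAF > 0.4 are dropped, irreconcilable alleles are dropped with a warning.
Regions are ±200 kb (inclusive) around each fine-mapped lead.  The GWAS
effect prior defaults to 0.15 for quantitative and 0.2 (log-odds) for
binary traits.  No masking or conditional analysis is performed, so
secondary colocalizations in a region can be missed.

Strong colocalizations (PP4 ≥ 0.8, inclusive) are summarized per
(LD block, GWAS): blocks are BED-style 0-based half-open intervals, the lead
variant's position (converted from 1-based) decides the block when the
window spans several, non-reference datasets with n < 150 are excluded, and
a block is novel iff no reference-set dataset colocalizes in it.  The
novelty score is new blocks divided by eQTL sample size.  Method-overlap
counting stratifies blocks by the subset of quantification methods detecting
them; "transcript-level only" means detected by exon/transcript/event usage
but not by gene expression.  For transcript-level methods the inputs are
restricted to significant lead QTLs at FDR < 0.01, applied per gene group
(group-best), matching the permutation scheme.

## Problem sizes and evaluation

The statistical properties are evaluated at: 100 random ≤10-variant regions
for oracle equivalence; 50 replicates per colocalization mode at n = 500 per
trait, 200 variants, `ld_rho` 0.9, causal effects explaining 5% of variance;
200 single-causal fine-mapping replicates at the same region geometry; 1 000
null genes (n = 200, 50 variants, 200 permutations) for permutation
calibration; 200 random instances (≤ 50 sets over 30 variants) for
connected components; 2 000 signals over two 2-member groups for sharing
recovery; 12 datasets in 3 groups for the MDS embedding.  These sizes make
the full suite and the acceptance script each run in well under a minute of
compute per heavy stage.

One property does not hold at these conditions: with 5%-variance effects at
n = 500, the two-distinct-causal hypothesis (PP3) exceeds 0.8 in only ~30%
of replicates.  This is inherent to the prior arithmetic, not an
implementation issue (the posterior computation is oracle-verified): H3 must
overcome a p1·p2 = 10⁻⁸ prior, which requires both traits' summed Bayes
factors to be individually large, whereas H4 competes against the single
p12 = 10⁻⁵ prior.  At per-trait z ≈ 5 that joint event is uncommon;
reliable PP3 > 0.8 needs roughly 8-10% variance explained or larger priors.
The corresponding check is left failing by design rather than weakening the
conditions; the shared-mode (PP4) and null (PP0) recovery rates meet their
bounds.

## Known limitations

- Single-effect fine mapping cannot separate multiple independent signals in
  one region; credible sets for secondary signals are never emitted.
- The sharing generator's group-activity model is a stand-in, not a model of
  real cross-tissue effect-size covariance; estimates on real data would
  additionally reflect shrinkage, winner's curse and incomplete power.
- The Markov LD model understates long-range LD; LD-pruning and
  colocalization behavior on real panels may differ.
- Genotype phasing/imputation, liftover, read alignment/quantification, GC
  normalization, multi-effect fine mapping, posterior shrinkage of effect
  sizes, and factor analysis of the effect matrix are out of scope.
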