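# Methods

## Mixture model and contamination correction

Every observed quantity is modeled as a linear mixture of tumor cells
(fraction 1 − α) and diploid normal cells (fraction α); this is the unique
linear two-population model when the normal compartment is diploid and
heterozygous wherever the matched normal is. The forward maps are

- observed VAF: v = (1 − α)·f·m / ((1 − α)·nₜ + 2α), with multiplicity m,
  cancer-cell fraction f, tumor total copy number nₜ;
- observed LAF: ℓ = ((1 − α)·n₋ + α) / ((1 − α)·nₜ + 2α);
- observed (normal-scaled) total copy number: c = (1 − α)·nₜ + 2α.

`correct_vaf` and `correct_allelic_cn` are their exact algebraic inverses
(round-trip to 1e−9, property-tested). Corrected values pushed outside
their ranges by sampling noise are clipped with a warning rather than
rejected, since read-count noise guarantees occasional excursions.

### Purity estimation

α is recovered by grid search on [0, 0.5] in steps of 0.005 (the upper
bound excludes samples that are mostly normal, where the mixture is not
identifiable from a single biopsy; the grid is cheap and immune to the
objective's non-convexity). The objective is the unweighted (1:1) sum of

1. the segment-length-weighted mean squared Euclidean distance, in
   (copy number, LAF) space, between the corrected imbalanced segments and
   their nearest integer allelic states, and
2. the squared distance between the dominant corrected VAF mode of
   mutations on balanced diploid segments and its nearest lattice value
   m/nₜ ∈ {0.5, 1}.

The VAF mode is located once on the observed scale by a Gaussian KDE with
Silverman bandwidth (robust to the subclonal tail) and rescaled per
candidate α — on balanced diploid segments the correction is the scalar
1/(1 − α), so this is exact. Ties break toward smaller α, which makes the
uncontaminated sample the default when the objective is flat. Sex
chromosomes are excluded (single-copy states are ambiguous with LOH).
Within the grid's domain the two objective terms have no common spurious
zero: the mode term's second root (corrected mode at 1.0) lies at
α = 1 − 2·mode ≥ 0.5 for any observed mode ≤ 0.5.

## Segment LAF and integer states

Segment LAF is the read-count-weighted mean of the per-site folded
fraction min(v, 1 − v) over germline heterozygous sites, requiring ≥ 10
sites (`InsufficientSitesError` otherwise). Folding biases the estimate
slightly toward 0 for truly balanced segments (≈ 0.04 at 105x), which is
why "balanced" classification uses a 0.42 threshold rather than 0.5; for
imbalanced segments, whose per-site fractions sit away from 0.5, the bias
is negligible at the depths simulated. Likelihood-based phasing would
remove the bias but requires haplotypes that single-sample read counts do
not provide.

Integer-state assignment minimizes Euclidean distance in (copy number,
LAF) space over all states with total ≤ 8, ties toward smaller total and
then larger minor count (parsimony; prefer the less extreme imbalance).
A corrected segment within ε = 0.05 of an integer state in *both*
coordinates is clonal; ε is approximately two binomial standard
deviations of a segment LAF at ~100x with hundreds of sites, and is a
keyword argument wherever it is used.

### Subclonal copy-number mixtures

An off-lattice segment is explained as (1 − φ)·state₁ + φ·state₂ in the
linear space of (total copies, minor-allele copies), where state₁ is the
nearest integer state and state₂ ranges over states within ±1 copy per
allele (parsimony bound on a single CNA step). φ is the orthogonal
projection onto the segment between the two states — the exact
least-squares solution — and calls are restricted to φ ∈ (0.05, 0.95) so
purity error is not misread as subclonality. At φ = 0.5 the labeling of
major vs minor state is arbitrary; callers comparing to truth should fold
accordingly. No more than two states per segment are fitted.

## VAF clustering

Mutations sharing a copy-number context are clustered on raw (alt, depth)
counts with a k-component binomial mixture fitted by EM — binomial rather
than Gaussian because depth varies per site and the likelihood should
weight a 150x site more than a 60x one. k = 1..5 is scored by BIC,
−2 log L + (2k − 1) log n. Initialization takes component probabilities at
VAF quantiles plus 9 jittered restarts; each restart runs 25 EM steps and
the best continues to convergence (tolerance 1e−6 on the log-likelihood,
cap 500 iterations with a best-so-far warning). Cluster means are
re-expressed on the corrected scale.

The subclonal flag is one-sided: a mutation is subclonal when its
corrected VAF is strictly more than 0.10 (absolute VAF units) below the
clonal expectation of its segment. Mutations *above* expectation are
handled by multiplicity assignment, not subclonality. The detection-limit
procedure walks a descending VAF grid {0.30 … 0.05}, simulating 1000
clonal + 100 subclonal mutations per replicate at Poisson depths, and
reports the smallest VAF whose subclonal cluster (mean within 0.05) is
recovered in ≥ 90% of replicates before the first failure.

## Molecular timing

Time is the fraction of biopsy-time mutations already accumulated when an
event occurred, assuming a constant per-copy accumulation rate λ per Mb
per unit time. For a segment of length L the expected multiplicity-class
counts, and hence the estimators, are:

- AB → AA (loss + duplication as one timed event): pre-event mutations on
  the surviving allele are duplicated (N₂ ~ λLt) and post-event mutations
  land on either of 2 copies (N₁ ~ 2λL(1 − t)), so t̂ = 2N₂/(2N₂ + N₁).
  The estimator is identical under the alternative
  duplicate-first-then-lose order, which read counts cannot distinguish.
- AB → AABB: both alleles duplicate (N₂ ~ 2λLt, N₁ ~ 4λL(1 − t)), same
  t̂ = 2N₂/(2N₂ + N₁).
- AB → AAB: only one chromatid duplicates; pre-event mutations on the
  *other two* copies stay at multiplicity 1
  (N₂ ~ λLt, N₁ ~ λLt + 3λL(1 − t)), giving t̂ = 3r/(1 + 2r), r = N₂/N₁.

Each estimator inverts its expected counts exactly (identity-tested on a
t grid) and is validated against an independent generative oracle. λ and
L cancel, so no rate needs to be known. Multiplicities are
maximum-likelihood under the binomial read-count model on the lattice
m ∈ {1..n_major}, ties toward smaller m. Pure losses leave no
multiplicity signal and are untimeable; states that require two or more
sequential duplications from AB (AAAB, AAAA, …) are reported
"complex, untimed" rather than guessed — single-event histories are the
only ones whose estimator is well-posed here.

Confidence intervals come from 200 multinomial resamples of the
multiplicity counts (percentile 95%, widened to contain the point
estimate). Mutation time intervals follow from multiplicity: on AA/AABB,
m = 2 → [0, t̂] and m = 1 → [t̂, 1]; on AAB, m = 2 → [0, t̂] but m = 1 is
uninformative ([0, 1]) because pre-event mutations on the unduplicated
alleles are also single-copy; balanced segments give [0, 1].

WGD is called when ≥ 50% of the autosomal genome by length is consistent
with AABB (corrected copy number within 0.4 of 4, LAF within 0.05 of
0.5); each tetraploid chromosome with ≥ 10 mutations is timed separately
and the SD of the per-chromosome times measures single-event concordance
(SD < 0.05 in the single-event simulations; two independent half-genome
tetrasomies at t = 0.3/0.8 give SD ≈ 0.25). The fusion-junction test
scores the junction read count under binomial models at 2/4 vs 1/4 of
local coverage and requires a likelihood ratio of 3 (a pragmatic
"substantial evidence" default) to classify before/after the WGD. Rate
consistency across chromosomes is an ordinary least-squares fit of count
vs length through the origin (statsmodels OLS without intercept; its r²
is the uncentered one appropriate for a no-intercept model).

## Timelines and cohort summaries

Trunk items sort by point time — the event estimate, or the interval
midpoint for mutations (the median of a uniform interval) — with
deterministic (time, chromosome, label) tie-breaks so serialization is
byte-identical for identical inputs. Subclone calls group into branches
when their fractions agree within 0.1; a wider spread emits sibling
branches with a warning, since nesting cannot be resolved from a single
biopsy. Cohort summaries aggregate copy-number lesions at chromosome
level (the genome templates used here carry no centromere coordinates, so
arm-level splitting is not attempted) and report the median interval time
for mutations. Newick export encodes molecular-time spans as branch
lengths.

## Synthetic tumors

The generator simulates explicit copy genealogies per segment: each copy
accrues Poisson(λ·L·Δt) mutations per epoch, duplications clone a copy
together with its mutation list, losses remove one, and a subclone forks
the whole cell lineage at its branch time (snapshotting the copy state)
and evolves privately while the major lineage continues. Observed tables
are then read-count draws: depth ~ Poisson(mean 105), alt ~
Binomial(depth, v) at the mixture-model VAF, het-site counts likewise per
parental allele, and the segment table carries the exact mixture copy
number (optionally Gaussian-perturbed) with the LAF estimated from the
simulated het sites. Defaults: λ = 0.7 mutations/Mb/copy/unit time
(≈ 3,900 mutations on the full diploid autosome template, a typical deep
WGS somatic burden), 105x mean coverage, 500 het sites/Mb (≈ 0.5/kb,
typical human heterozygosity), hg19-scale autosome lengths. Everything is
deterministic under a fixed seed.

What the generator does *not* emulate — and what passing recovery tests
therefore cannot certify on real data: sequencing error and mapping
artifacts, GC/mappability coverage waves, read-depth overdispersion
beyond Poisson (a config hook exists but is off by default), focal/
sub-chromosomal segmentation error, kataegis-like rate heterogeneity, and
multi-sample designs. Named fixtures (`pfn_like`, `pfp_like`,
`null_diploid`) run on a 25%-length genome with the per-Mb rate raised to
keep per-chromosome counts realistic; recovery tests likewise use scaled
genomes (chromosome subsets at 20–25% length with λ chosen so that λL
per segment is in the hundreds), which preserves the count regimes the
estimators actually see. In the `pfn_like` fixture the subclone branches
at t = 0.98, after the last trunk event, so all configured chromosomal
events remain clonal as intended.

## Known limitations

- Purity and subclonal copy number are partially confounded when a single
  subclonal CNA dominates the imbalanced genome; the φ ∈ (0.05, 0.95)
  restriction and the VAF term mitigate but cannot remove this.
- Multiplicity assignment at 105x separates m = 1 from m = 2 cleanly on
  2–4 copy states but degrades for high-ploidy lattices (v spacing
  shrinks as 1/nₜ).
- Timing assumes rate constancy at chromosome scale; the rate-consistency
  check (r² of count vs length) is the guard, not a proof.
- One branching per tumor is the default generative and interpretive
  model; sibling subclones are supported, nested ones are not resolved.
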