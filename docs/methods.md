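# Methods

This note records the models, conventions and numerical choices behind
`tissueqtl`, in the order the pipeline runs them.

## Coordinates, samples, containers

All intervals are 0-based half-open internally; VCF positions are shifted
by −1 on read, BED intervals are native. The TSS is the leftmost base on
the + strand and the rightmost on the −; signed distances to the TSS are
positive downstream in transcription direction. A sample is an
(individual, cell type) pair written `individual.celltype`; cross-tissue
operations join on the individual part. Genotypes are ALT-dosage matrices
(missing allowed; each cis pair is tested on the intersection of
non-missing samples, since the upstream handling of missing genotypes in
the emulated design is not recorded). Variants failing the MAF > 5%
inclusion rule are flagged rather than dropped, and mapping applies the
filter.

## Cis association mapping

Spearman ρ is the Pearson correlation of average ranks. The nominal
two-sided p uses the t approximation for n ≥ 10 and exact enumeration of
all rank permutations for n < 10; the choice of approximation is ours, as
is treating dosage 0/1/2 (including minor homozygotes) as the regressor
coding. Pairs with zero variance on either side are skipped and counted.
Window sizes per family: 1 Mb (genotype→expression and genotype→splicing,
anchored at the TSS), 5 kb (genotype→methylation, anchored at the CpG),
50 kb (methylation→expression/splicing, anchored at the TSS). All pairs in
the window are tested; there is no pre-screening.

### Fixed-permutation threshold (expression/methylation families)

Phenotype sample labels are permuted 1000 times within a cell type
(preserving regressor LD). In each round the per-unit minimum nominal p
(unit = gene, minimised over its features' cis pairs; or CpG site) is
recomputed on a random subset of units (1000 genes / 50,000 CpG sites;
all units when fewer exist). The "median p-value distribution" is read as
the rank-wise median of the sorted per-round minima — a pooled-null
alternative is available by flag. The nominal threshold is the largest
observed unit-level p with estimated FDR(t) = E(t)/obs(t) ≤ 10%, where

    E(t) = (#null ≤ t + 1) · N_obs / (N_sub + 1).

The +1 pseudo-count is our numerical choice: without it the extreme tail
of a rank-wise-median null is degenerate (with probability ≈ ½ the smallest
observed unit p undercuts the smallest null median, E(t) = 0, and the unit
certifies itself at FDR 0 on fully null data). The pseudo-count is the
standard permutation-test correction and restores control; its cost is
that no threshold exists until roughly 10 units (at 10% FDR) beat the null
tail, so very sparse signal at desk scale declares nothing — visible in
the analysis drivers and intentional.

### Adaptive permutations and q-values (splicing families)

Per link/regressor pair, the link fractions are permuted in growing
batches until 100 permutation p-values fall below the observed nominal p,
or 100,000 permutations (10,000 in the scaled-down tests) are reached;
empirical p = hits/permutations, floored at 1/permutations so it is never
zero, with a (hits+1)/(n+1) variant by flag. Because permutation preserves
the tie structure, "permutation p < nominal p" is implemented as
|ρ_perm| > |ρ_obs|. Empirical p-values then go through the Storey
procedure: π0(λ) = #{p > λ}/(m(1−λ)) on λ = 0.05, 0.10, …, 0.95, a cubic
polynomial fit evaluated at λ = 0.95 (our analogue of the reference
implementation's df≈3 smoothing spline), clipped to (1/m, 1]; q-values are
the step-up cumulative minima of π0·m·p/rank. With fewer than 100 tests
π0 falls back to 1, i.e. Benjamini–Hochberg, and forcing π0 = 1 reproduces
BH exactly (tested to 1e-12). π1 = 1 − π0 shares this smoother.

## Splicing quantification

Overlapping exons form exon groups (transitive closure); each exon's
unique portions are its interval minus the union of the other members.
Exons with no unique portion cannot anchor links and are flagged. A read
is assigned to an exon when it overlaps a unique portion by ≥ 1 bp (the
minimum overlap is our choice); reads overlapping unique portions of two
exons are ambiguous and drop the pair, counted. A pair with mates in two
different exons increments that exon pair once; fractions are computed in
the forward direction (primary = 5'-most exon) and reverse (primary =
3'-most) separately.

Raw counts are normalised by removing the leading principal components of
the log1p count matrix (centred, SVD), re-centred, and back-transformed;
constant links pass through. The genome-scale default removes 15
components with min(n−1, 15) as fallback; the scale of the transform
(log1p) is a documented choice, configurable. Normalised counts are
divided by the link's placement probability: on the concatenation of the
two exons in transcript order, for every insert size in the sample's
empirical distribution, every fragment start is enumerated; a placement is
valid when the upstream read lies fully inside the 5' exon overlapping its
unique portion and the downstream read likewise in the 3' exon. Uniform
fragment start is assumed (the source method does not state its placement
model). The probability is the mass-weighted valid/total ratio; zero
probability makes the coverage undefined and excludes the link. Fractions
are coverage over the primary exon's summed coverage; an all-zero
denominator yields missing, not zero. Inclusion filters: the primary
exon's group makes ≥ 10 links in the direction in ≥ 80% of individuals;
the primary exon makes ≥ 5 in ≥ 30%; and at most 95% of individuals share
the modal fraction value ("non-variable" = equal to the mode, our
definition — robust for fraction data with point masses at 0/1).
Differential link usage between tissues is a Welch t-test.

## Allele-specific expression

Sites need ≥ 16 reads (≥ 30 for the depth-equalised analysis) and may be
excluded by a mapping-bias blacklist. The reference-bias correction is
implemented as a stratified null probability p0 — pooled REF fraction per
library (individual × cell type) and ordered REF/ALT base pair, falling
back to the library-wide estimate below 200 sites per stratum; the
original correction formula is unpublished, so this stratified-p0 reading
is ours and is labelled as such. Coverage is equalised by drawing exactly
30 reads without replacement (hypergeometric REF count). The test is the
exact two-sided binomial: p = Σ pmf(k) over all k with pmf(k) ≤ pmf(obs),
significant at p < 0.005; the per-sample FDR estimate is
α·n_tests/n_observed. At depth 30 the attainable sizes of this exact test
near α = 0.005 are 0.0028 and 0.0058, so the realised null rejection rate
under the corrected null is ≈ 0.0028 — below α by discreteness — and a
reference bias of 0.02 at this depth is inside the granularity, which is
why the bias correction's effect on rejection rates only becomes visible
at higher depth.

The allelic-ratio distance between two samples is the weighted median of
|REF/TOTAL ratio differences| over shared heterozygous sites covered by
≥ 40 reads in both, with weight = the two samples' summed coverage at the
site (the weighting by "total reads covering the site" does not specify
one or both samples; both is our default, min available by flag). The
weighted median is the lower weighted median with midpoint interpolation
at exact 50% mass. Distances based on fewer than 50 shared sites are
excluded (the emulated design excluded low-coverage samples without
stating a cutoff; 50 is our default). Group comparisons (same individual /
same cell type / different) use two-sided Wilcoxon rank-sum tests.

## Effect sizes and sharing

Scaling subtracts the mean and divides by the sample SD (ddof = 1).
Genotype effect sizes are median(scaled | het) − median(scaled | hom-major)
— the main-figure sign convention; a supplementary legend in the source
material states the reverse order and we resolve in favour of the main
figure — with minor homozygotes excluded and a configurable minimum group
size (default 2). Methylation effect sizes are the OLS slope on scaled
values, identical to Pearson r. Pairwise tissue sharing reports π1 of the
second tissue's p-values at the first tissue's significant pairs (best
pair per feature by default; all-pairs mode available — which of the two
the source used is not recorded), effect-size R² over the union (tested in
both, significant in either) and the shared set (significant in both), and
the percentage of sign-discordant shared pairs. On planted cohorts
R²(shared) exceeds R²(union), reproducing the winner's-curse pattern.

## Enrichment

The enrichment unit is the best associated SNP/CpG per gene, site or link
(lowest nominal p; ties broken by smaller |distance|, then lexicographic
id). Null sets are drawn one per query, without replacement (the source
does not state the ratio or replacement policy), from candidates matched
jointly on distance to the anchor (10 kb bins), MAF (0.05 bins) and
phenotype level (pool quartiles); empty bins are widened once (×2) before
the query is reported unmatched. Candidates must not be nominally
associated (p ≥ 0.01) to the relevant phenotype. Overlap uses half-open
point-in-interval queries; significance is the two-sided Fisher exact
test, starred at p < 0.05 and p < 5e-4. Derived feature sets: promoters
−1 kb..+2 kb around the TSS in transcription direction (built by strand
reflection on the − strand), gene bodies from +2 kb to the gene end, CpG
island shores the 2 kb flanks excluding the island. Positional profiles
bin QTLs into 10 kb flanking windows and ten gene-length deciles;
proportions sum to 1 over the profiled range.

## The synthetic cohort

The generator emulates the study design: three cell types (F/L/T) sharing
genotyped individuals — defaults of 185 individuals for genotype tests and
110 for methylation tests, 100 genes with three 150 bp exons and 5 kb
introns, 20 Hardy–Weinberg SNPs per gene within ±100 kb of the TSS, MAF
drawn in (0.1, 0.5). Planted eQTL effects are in phenotype-SD units per
allele; the residual variance is shrunk by the planted genetic variance so
the total SD stays 1 and the planted β is recoverable by the
median-difference estimator. eQTL SNPs are chosen with weight
exp(−|d_TSS|/25 kb), mirroring the TSS clustering of real regulatory
variants. Methylation is generated on the logit scale
(β = logit⁻¹(a + b·dosage + c·scaled expression + noise)) to respect
[0, 1]; association testing consumes β directly. Tissue sharing of each
planted effect follows a 1/2/3-tissue class distribution
(0.45/0.25/0.30). Read pairs are placed on two isoforms (full inclusion
and middle-exon skipping) with usage depending on planted dosage or
methylation; inserts longer than the transcript are redrawn (counted), and
reads that would span an exon junction make the pair unmappable (the
emulated cohort had no split mapping), so the expected link fractions used
as truth are computed by exact enumeration of the same placement model.
Allelic counts are binomial around p0 = 0.52 (reference bias) plus an
individual-specific baseline shift at every site (SD 0.10, shared across
cell types), an extra individual shift at ASE sites (20% of sites,
SD 0.15) and a smaller tissue shift (SD 0.04) — the individual components
dominating is what produces the same-individual < same-cell-type <
different distance ordering.

What the generator does not emulate: GC/insert/batch artefacts (a generic
covariate-residualisation operation exists instead), LD between SNPs,
sequence-context mapping bias beyond p0, split reads, array probe effects.
Passing tests therefore demonstrate the statistical machinery under clean
noise models, not robustness to those artefacts.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run desk-scale versions of each
analysis: 20 null replicates of 200 genes × 50 SNPs at n = 100 for FDR
behaviour; 100 planted genes at n = 185 for effect recovery; 10,000-test
p-value mixtures (20 replicates) for π1; 100,000 sites for binomial
calibration; 50 individuals × 3 cell types × 300 sites for distance
structure; 20,000 fragments for link accuracy; 500 null links at 10,000
maximum permutations for adaptive-p uniformity. These sizes are the
package's chosen study conditions for verification and complete in about a
minute in total.

## Known limitations

- The fixed-permutation threshold needs tens of true signals before it can
  declare anything at 10% FDR (pseudo-count floor); it is a global, not
  per-gene, threshold.
- The exact binomial ASE test is conservative at depth 30 (attained size
  ≈ 0.0028 at α = 0.005) and cannot distinguish a 0.02 reference bias at
  that depth; conclusions about the bias correction require higher depth.
- π0 estimation by cubic polynomial can undershoot slightly for very
  spiky alternative distributions; estimates are clipped to [0, 1].
- Link placement probabilities assume uniform fragment starts and
  per-sample insert distributions independent of the gene.
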