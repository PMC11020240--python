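# Methods

This note documents the models, estimators and numerical choices behind
each stage, what the synthetic-data generator does and does not emulate,
and the design decisions taken where more than one reasonable convention
exists.

## Synthetic cohort generator

**Genotypes.** Population structure follows the Balding–Nichols model:
each variant draws an ancestral frequency `p` uniformly from a configurable
interval (default (0.05, 0.95)), and each subpopulation draws its own
frequency from `Beta(p(1−F)/F, (1−p)(1−F)/F)`, which has mean `p` and
variance `F·p(1−p)`. `F` is the divergence (Fst) parameter; a brute-force
Hudson-Fst computation on simulated cohorts recovers it within ±0.02 at
F = 0.1. Genotypes are Hardy–Weinberg within subpopulation. This was chosen
as the simplest model with a single tunable divergence knob; no demographic
history or coalescent LD is implied. Relatives are built by Mendelian
gamete transmission from designated founders (parent–offspring, full
siblings, and half-sibling "second-degree" pairs), so expected kinship is
exact by construction. Missing genotypes are injected uniformly at a
configurable rate (default 0.5%) purely so missingness filters have
something to act on. Variants are placed with uniform spacing on a
configurable number of chromosomes; sites are independent unless blocks
are explicitly copied, so LD-sensitive behavior is exercised through
constructed fixtures rather than through the generator.

**Read counts.** Depth is Poisson (default mean 30); alternate-read counts
are Binomial(depth, p) with p = 0, 0.5, 1 for genotypes 0/1/2. The batch
effect is modeled only at heterozygous calls — the allele-balance statistic
is informative only where both alleles are expected — by shifting the
heterozygous success probability to a configured value (default 0.65) for
samples in the affected batch. The 0.65 default is a free parameter chosen
to represent a clearly pathological but not extreme shift; it is not an
estimate of any real platform's bias.

**Traits.** All traits share one causal-variant set (default size
configurable); per-variant effects are drawn jointly across traits from
N(0, rg), so the correlation of true genetic values converges to the
requested genetic-correlation matrix. Genetic values are rescaled to
variance h² and environmental noise to 1 − h², making the realized
variance ratio match h² essentially exactly. Trait-level causal edges are
applied last (`outcome += γ·exposure`). Sex, age and BMI are drawn from
simple parametric distributions (Bernoulli(0.5), N(50, 10), N(24, 3));
only their role as covariates matters. Because the causal set is finite,
the *realized* genetic correlation of nominally independent traits
fluctuates around zero with sd ≈ 1/√(n_causal); parameter-recovery tests
therefore compare estimates against realized truth values recorded in the
generator's truth block, not against the model-level parameters alone.

What passing tests on this generator do **not** show: robustness to LD
between markers, to sequencing error in read counts, to non-normal trait
distributions, to informative missingness, or to cryptic structure beyond
the island model.

## Variome QC

**Allele balance.** Per heterozygous call, AB = alt/(alt+ref) over calls
with positive depth; the per-variant mean is undefined (NaN, never
silently 0) when a variant has no usable het call. The genome-wide mean
and SD are computed once over all defined-mean variants before any
exclusion (single pass, no iteration), and a variant is excluded when its
mean falls strictly outside the closed interval mean ± 1 SD — boundary
values are kept. Undefined-mean variants are kept. A degenerate SD of 0
keeps everything and warns. Computing AB at heterozygous calls only is an
interpretation: homozygous calls have expected AB 0 or 1 and would swamp
the statistic, and het-only makes the genome-wide mean ≈ 0.5
interpretable.

**Sample filters.** Missing-rate threshold 0.10; het/hom-ratio outliers at
mean ± 3 SD of the cohort distribution (SD = 0 treated as no outliers);
samples with zero non-reference homozygotes get an undefined ratio and a
review flag rather than a pass/fail.

**Kinship.** Method-of-moments IBD-state estimation in the PLINK style:
per pair, IBS 0/1/2 counts over jointly-called variants are compared to
their expectations given the allele frequencies under IBD 0/1/2, solved
sequentially, truncated to [0, 1] and renormalized;
PI_HAT = P(IBD=1)/2 + P(IBD=2). Expectations use the hypergeometric
(without-replacement) forms evaluated on the cohort's allele counts, which
removes the finite-sample bias of plugging estimated frequencies into the
with-replacement formulas — measured raw-scale bias is ~10⁻⁴. Truncation
at zero still leaves a small positive mean (~0.02 at 5,000 markers) and a
right tail: a few percent of truly unrelated pairs exceed PI_HAT 0.05 at
that marker count. This is a property of the estimator, not a bug; the
0.05 relatedness threshold is aggressive (typical third-degree cutoffs sit
near 0.1) and is configurable. Estimation refuses to run on fewer than 100
usable markers. Unrelated-set selection is greedy: repeatedly drop the
sample in the most over-threshold pairs, ties broken lexicographically —
deterministic, and equal to the minimum vertex cover on the small family
structures tested.

**HWE.** The exact conditional test: enumerate heterozygote counts
compatible with the observed allele counts via the standard stable
recurrence and sum the probabilities of configurations no more probable
than the observed one. No mid-p correction. Monomorphic sites give P = 1.
Agreement with a direct log-gamma enumeration oracle is asserted to 10⁻¹²
for every table with total ≤ 50.

**LD pruning and PCA.** Pruning is sliding-window (200 variants, step 4,
r² > 0.1 by default), per chromosome, removing the later variant of each
offending pair — a deterministic convention. PCA eigendecomposes the
covariance of mean-imputed, column-standardized dosages; mean imputation
is used for PCA and LD only, never for association. Scores are scaled by
the root eigenvalues; signs are arbitrary. The "non-target ancestry"
outlier rule flags samples more than k·SD (default 6) from the
target-population centroid on PC1–2; k is configurable because no
principled universal value exists.

**Order.** Sample filters → unrelated selection → allele-balance filter →
genotyping-rate filter (variants with rate < 0.9 dropped).

## Profiling and population specificity

Category membership (singleton, doubleton, very rare, rare, common, very
common) is defined on alternate-allele count/frequency with boundaries
inclusive downward, computed once from the full cohort and held fixed
along saturation curves — re-categorizing at each subset size would be
ill-defined. Discovery counts a variant at the first position of a carrier
in a random sample ordering; curves average over 10 seeded permutations by
default. The χ² specificity test is the 2×2 Pearson statistic on allele
counts (2N alleles per diploid population), one df, no continuity
correction — the common population-genetics convention; its null rejection
rate at α = 5×10⁻⁵ is calibrated within 3 binomial SDs over 10⁶ simulated
tests. Variants untyped in any reference population are excluded rather
than imputed at frequency zero (conservative; configurable). The test is
consequence-agnostic; restricting to missense or any other class is a
pre-filter on the input table.

## WGWAS

Linear association uses exact per-variant OLS via residualization against
the covariates (Frisch–Waugh–Lovell), with per-variant complete-case
refits where dosages are missing; inference is the t-test on the dosage
coefficient. Logistic traits use IRLS with a 25-iteration cap and
separation detection (separated variants yield NA rather than a wild
estimate). P values are floored at the smallest positive double so they
remain in (0, 1]. Covariates are sex, age, age², BMI and the top 10 PCs;
BMI is dropped from the covariate set for BMI itself and BMI-derived
traits. λ_median = median(χ²₁)/0.4549364. Clumping is greedy index-first:
ascending-P scan, each index absorbs unassigned variants within 250 kb
with dosage r² > 0.1; every variant lands in exactly one clump.
Significance thresholds default to 5×10⁻⁸ (significant) and 10⁻⁵
(suggestive), both configurable. BH FDR uses the standard step-up
(statsmodels implementation). Null calibration at n = 500 over 20×10,000
simulated variants: type-I error within 0.05 ± 0.005 and λ within
[0.9, 1.1].

## Phenomics

**Trait screening** drops quantitative traits missing in > 90% of samples
and binary traits with a minority class under 20% (imbalance worse than
1:4); with repeated measurements the most recent record wins.

**Phenotypic correlation** is pairwise-complete Pearson with Fisher-z 95%
CIs and BH FDR over all pairs; a pair is significant only when FDR < 0.05
*and* the CI excludes zero.

**VSI** is reported on the percentage scale with one-decimal rounding,
total = |S_i| + |S_j| − shared by the union identity. The percentage
convention matches how such sharing tables are printed; the underlying
quantity is a plain Jaccard index.

**GREML.** The GRM is the standardized-genotype cross-product,
`A_jk = (1/M)·Σ_i (x_ij − 2p_i)(x_ik − 2p_i)/(2p_i(1−p_i))` over MAF ≥ 0.01
variants, with per-pair M adjusted for missing calls. REML is maximized on
the GRM eigenbasis, where the covariance is diagonal (univariate) or
2×2-block-diagonal (bivariate), making each likelihood evaluation O(n)
after one O(n³) eigendecomposition that is cached per GRM. The univariate
fit uses bounded L-BFGS-B from three variance-split starts; convergence
tolerance is the optimizer default on a log-likelihood that is cheap to
evaluate exactly. h² SEs come from the analytic expected (Fisher)
information — a numeric Hessian proved unreliable near the σ²_g = 0
boundary — with the delta method; CIs are Wald intervals truncated to
[0, 1], and estimates at the boundary are flagged. The bivariate model
(six components: two genetic variances, genetic covariance, two residual
variances, residual covariance) is fitted by adaptive Nelder–Mead with
non-positive-definite proposals rejected; rG is the genetic covariance
over the geometric mean of genetic variances, truncated to [−1, 1]; the
rG = 0 test is an LRT against a five-parameter null refit, and
non-convergence produces an excluded-with-reason record, never a silent
NA. Recovery at n = 2,000 / M = 5,000: h² within ±0.1 of 0.5 and rG
within ±0.15 of 0.8 over 10 replicates. The analytic power formula uses
SE(h²) = √(2/(N²·var_A)) with var_A the variance of GRM off-diagonals
(default 2×10⁻⁵, typical of conventionally unrelated samples) and a
two-sided α = 0.05 — the parameterization that reproduces both published
operating points (0.72 at N = 2,685 and 0.97 at N = 4,000 for h² = 0.3).

**Mendelian randomization.** Instruments are suggestive exposure variants
thinned to one per LD block (clumping at r² 0.1 / 250 kb, smallest P
kept); fewer than three instruments yields a skip record. IVW is the
fixed-effect weighted slope through the origin with weights 1/se_y²
(Wald ratio for a single instrument). Egger sign-aligns instrument effects
so β_x > 0 (the orientation its intercept interpretation assumes), fits
weighted regression with intercept, and applies a multiplicative
random-effects floor (residual scale ≥ 1) with t inference on k − 2 df.
MR-PRESSO is re-implemented from its published sketch: the observed
statistic is the leave-one-out weighted residual sum of squares of the
IVW fit; the null distribution comes from parametric resampling of the
outcome effects (default 10,000 draws, seeded); per-instrument outliers
are Bonferroni-flagged against their own simulated residual distributions
and removed before an IVW re-fit. The global-test P is uniform under the
null (KS-checked over 200 simulated pairs). FDR for the consensus is
applied within each method across all tested exposure–outcome pairs (the
natural scope when all pairs are tested together); a pair is causal when
≥ 2 of 3 methods pass FDR < 0.05, and pairs significant in both
orientations are labeled bidirectional.

**Network export** emits GC and pleiotropy edges unconditionally and PC /
MR edges only for pairs that also carry a GC or pleiotropy edge, as a
GraphML multigraph with edge type, weight (|coefficient| or VSI) and
direction.

## Imputation evaluation

Per-variant R² is the squared Pearson correlation between true genotypes
and dosages; constant-genotype variants are undefined and counted but
excluded from aggregation. "Aggregated R²" is the mean of per-variant R²
within alternate-AF bins (the Minimac-style convention); a
pooled-correlation mode is available behind a flag. Default interior bin
edges: 0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5. When two panels are
compared, an overlap mask restricts to variants imputed in both.

## Problem sizes

The test and acceptance suites run at desk scale, chosen so each
statistical property is measured with useful precision: batch-filter
recovery on 500 samples × 2,000 variants at depth 30; kinship on 5,000
markers with 40 parent–offspring pairs; association calibration over
20×10,000 null variants at n = 500; REML recovery at n = 2,000 /
M = 5,000 with 10 trait replicates sharing one cached GRM
eigendecomposition; MR direction recovery over 20 replicates of 1,200
samples × 400 independent loci; saturation ordering on 1,600 samples ×
8,000 low-frequency variants (the very-rare class, AC > 2 at AF ≤ 0.001,
is only populated at all above ~1,500 samples).

## Known limitations

Markers are simulated without LD, so pruning and clumping are validated on
constructed fixtures rather than realistic haplotypes. The logistic scan
loops per variant and is not tuned for millions of markers. Bivariate REML
assumes both traits are observed on the same samples. MR-PRESSO follows
the published algorithm sketch; exact numerical agreement with the
reference implementation's RNG is not a goal. X/Y/MT chromosomes, phasing,
and functional annotation are out of scope.
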