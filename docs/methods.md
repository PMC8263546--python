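# Methods

This note documents the statistical models, numerical choices and design
decisions behind `clonalgp`, and what its synthetic-data tests do and do not
establish about real breeding data.

## Data model

Genotypes are biallelic pseudo-diploid SNP calls: all heterozygous dosage
classes of a polyploid are collapsed into one class and coded 0 (homozygous
reference), 1 (heterozygous), 2 (homozygous alternate), with −1 for missing.
This is an approximation for high, variable ploidy; true allele dosages are
out of scope. Phenotypes are spatially adjusted clone values (second-stage
inputs), one record per clone × year × crop × region × trial; the first-stage
spatial adjustment is assumed done upstream.

Quality control removes clones with call rate < 90%, then loci with call
rate < 90% or alternate-allele frequency < 1% (the alternate-allele
frequency itself, not the folded MAF — an all-alternate locus is kept,
an all-reference one dropped). Clone-first order is a documented convention;
QC is idempotent. Missing calls surviving QC are imputed to the locus mean
(Gaussian kernel) or to the expected orthogonal coefficient, which is exactly
zero (incidence matrices) — the latter keeps every incidence column centred
under the observed genotype frequencies.

## Orthogonal (NOIA) kernels

With per-locus genotype frequencies (p_AA, p_Aa, p_aa) estimated from all
analysed clones (training and prediction sets together, since one
relationship matrix covers both):

- additive coefficients: h_A = (p_Aa + 2p_aa) − x for code x ∈ {0,1,2};
- dominance coefficients: with D = p_AA + p_aa − (p_AA − p_aa)²,
  h_D = (−2 p_Aa p_aa, 4 p_AA p_aa, −2 p_AA p_Aa)/D.

Both vectors have zero mean under the genotype-frequency weights, and they
are orthogonal when the locus is at Hardy–Weinberg proportions. Monomorphic
or D = 0 loci (no homozygotes) contribute zero columns and are excluded from
the heterozygosity normaliser Σ 2 p q. Relationship matrices are
G = H H′/(tr(H H′)/n); epistatic kernels are Hadamard products rescaled to
mean diagonal 1. A kernel whose smallest eigenvalue is below −1e−8 × the
largest gets 1e−6 diagonal jitter (logged). The Gaussian kernel uses raw
(mean-imputed) 0/1/2 codes, K = exp(−h·d²/p), since it operates on marker
vectors rather than the orthogonal coding.

## REML engine

The six models share the fixed design mean + Year + Crop + Region + Trial
(treatment coding, first level as reference; no interactions) with an
optional centred heterozygosity covariate, and one clone-level random effect
per kernel; repeated records of a clone share its effects
(repeatability-style), residuals are i.i.d. Because the trial factor is
nested in region × year, the full dummy coding is rank-deficient by
construction; `build_design(..., on_aliased="drop")` removes aliased columns
(keeping the earliest) with a warning, the way mixed-model packages absorb
singularities, and the REML likelihood is invariant to which full-rank
subset survives. The strict mode raises instead and lists the aliased
columns.

Estimation is average-information REML. All solves use the Woodbury
identity, V⁻¹ = R⁻¹ − R⁻¹Z(G⁻¹ + Z′R⁻¹Z)⁻¹Z′R⁻¹ with G = Σ σ²_m K_m, so the
per-iteration cost is cubic in clones rather than records. Specifics:

- initialisation: each of the k+1 components starts at var(y)/(k+1);
- the first 3 iterations use a positive multiplicative fixed-point update
  σ² ← σ²·(y′PBPy)/tr(PB); later iterations take AI (Newton-type) steps with
  step-halving whenever the restricted likelihood would decrease;
- convergence: relative log-likelihood change < 1e−8, max 200 iterations;
  non-convergence returns a flagged result, not an exception;
- boundary handling: a variance driven below 1e−6·var(y) is pinned there and
  flagged (reported like the "~0 (NA)" convention of commercial REML
  software); pinned components get no SE. Because pinned components sit at a
  small positive floor, a larger nested model can trail the smaller model's
  optimum by ~1e−5 in log-likelihood; tests allow 1e−4 slack.
- an ill-conditioned AI matrix (condition number > 1e12, e.g. two identical
  kernels with one record per clone) triggers the fixed-point fallback and a
  "singular average-information matrix" warning rather than an arbitrary
  variance split;
- SEs come from the inverse AI matrix over free components; BLUPs from the
  mixed-model equations at the final estimates. GEBV is the additive BLUP;
  GPCP the sum of all fitted genetic BLUPs, for all clones the kernels
  cover (prediction-set clones get BLUPs through their kernel covariance
  with phenotyped clones).

Model comparison uses 2·(logL_full − logL_reduced) against χ²(1) at 5%, as
the motivating analysis applies it. A null variance component lies on the
boundary of the parameter space, so this test is conservative; the package
reproduces the plain-χ² procedure deliberately rather than the
½χ²₀ + ½χ²₁ mixture, and the null-calibration test documents rejection
rates well below nominal. Identical fits are allowed (stat 0); fits with
different fixed designs are rejected as non-comparable.

A note on "orthogonality": even with orthogonal NOIA coding, the
additive-only model absorbs clone-level dominance/epistatic variance into
σ²_A when the truth is non-additive, because it is the only clone-level
variance term available. The variance partition is trustworthy only when
the relevant kernels are all in the model; tests assert exactly this
behaviour (A-model σ²_A ≈ var_a + var_d; AD-model separates them).

## RKHS sampler

The Bayesian model is y = 1μ + Σ_m g_m + ε with g_m ~ N(0, K_m σ²_gm). Each
kernel is eigendecomposed once; g_m is sampled in its eigenbasis where the
full conditional factorises into independent normal coordinates, giving
O(n²) per sweep. Eigenvalues below 1e−10 × the largest are truncated
(logged). Variances get scaled-inverse-χ² updates with prior df = 5 and
scales set so the prior *mode* splits 50% of var(y) equally across kernels,
the rest to the residual — comparable, documented defaults standing in for
the reference software's. The intercept has a flat prior. Defaults follow
the published protocol: single-kernel bandwidth grid {0.1, 0.5, 1.0, 2.5,
5, 10}, multi-kernel bandwidths {0.1, 0.5, 1.0}, 5,000 iterations with
1,000 burn-in, thinning 1; chains are bit-reproducible given a seed, and
effective sample sizes are reported, not enforced. Bandwidth selection takes
the top-3 grid accuracies on a clone-disjoint validation year, ties
preferring smaller h. Out-of-sample prediction extends the posterior-mean
fit to unphenotyped clones via the kernel covariance at the posterior-mean
variance ratio. With several near-identical kernels the individual σ²_gm
are not identified — only their sum is (documented, tested).

## Evaluation

Forward scenarios: test clones are those first recorded in the test year;
clones with records on both sides are removed from training, so the sets
are disjoint. Accuracy is the Pearson correlation between predictions and
clone-mean adjusted phenotypes, per region (a clone tested in several
regions is evaluated in each); SE = √((1−r²)/(n−2)); strata with n < 3 or
zero-variance predictions yield missing values with a warning. The overall
figure is the unweighted mean over regions (an n-weighted mean is also
reported, since the weighting convention is a free choice). Relative
improvements are rounded half-away-from-zero to integer percent, matching
the reporting granularity of the published tables. Connectedness is the
mean over validation clones of their top round(fraction·|ref|) (≥ 1)
relationships to the reference set.

## Synthetic-data generator

The generator emulates the study conditions, not real genomes: independent
biallelic loci (no LD by default) with alternate-allele frequencies
~ Uniform(0.05, 0.5); an inbreeding coefficient f controls heterozygote
deficit (f = 0 is exact HWE); clones are assigned one region and one
series-year, recorded in one trial × three crops (plant, two ratoons), with
22% of clones replicated in a second trial — the partial-replication rate of
the motivating trials. Trait values sum a breeding value (orthogonal
additive coding × N(0,1) effects), dominance deviations (dominance coding ×
N(directional_dominance_mean, 1) effects — a positive mean makes Het
predictive of performance), additive×additive epistasis (products of
centred additive codes over random locus pairs), fixed year/crop/region/
trial effects, and i.i.d. residual noise. Each genetic component is rescaled
to hit its target variance across clones exactly, and all realized effects
are recorded for recovery tests.

Preset scales: `mini` = 500 clones × 2,000 SNPs (default working scale for
tests and the acceptance run), `full` = 3,000 × 25,000 (the scale of the
motivating data set). Trait presets: a TCH-like complex trait
(var 50/30/40 additive/dominance/epistatic + 36 residual, broad-sense ratio
120/156 ≈ 0.77, directional dominance), a mostly additive CCS-like trait,
and a high-h² Fibre-like trait.

Because loci are independent, the generator cannot reproduce the
LD-driven confounding between additive and epistatic kernels that the real
data likely exhibit; passing recovery tests therefore demonstrate
correctness of the estimation machinery under the model's own assumptions,
not robustness to LD, population structure or genotyping error. Block-wise
dependence can be probed by lowering the number of epistatic pairs or by
raising f, but no coalescent-style LD is simulated.

## Problem sizes and test design

Recovery testing fits the AD model to 20 mini-preset replicates with an
AD-matched truth (var_aa = 0) and requires both variance estimates within
2 SE of the realized truth in ≥ 90% of replicates. Null calibration uses
200 replicates of 150 clones × 300 SNPs with zero genetic variance. The
GPCP-vs-GEBV contrast uses 20 replicates of 400 clones × 600 SNPs with a
strongly non-additive, directionally dominant architecture
(30/60/40 + residual 25) against a purely additive one (80/0/0); the full
model's advantage appears only in the former. These sizes were chosen as
the smallest at which the respective effects are statistically resolvable
with seeded replicates.

## Known limitations

- Pseudo-diploid coding ignores true allele dosage; variance components are
  statistical constructs on that scale, not physiological gene action.
- The plain-χ² boundary LRT is conservative; no mixture correction.
- The RKHS model carries no fixed covariates beyond the intercept.
- Genotype-by-environment interaction is not modelled (records share one
  clone effect across regions/years).
- Kernel persistence is plain TSV; at the `full` scale (3,000 clones) files
  are large and HDF5 storage via h5py is preferable for repeated runs.
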