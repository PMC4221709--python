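# Methods

`dimorph` analyses sexual dimorphism of quantitative traits in a two-breed
F2 intercross: genotype quality control, phenotype preparation,
kinship-corrected mixed-model genome scans run separately by sex and
combined, per-sex heritability with a permutation test for sex differences,
and a z-test for sex-differential SNP effects.  A gene-dropping simulator
reproduces the statistical structure of such a cross so that every stage is
testable without access to real data.

## The synthetic F2 cross

**Mating design.** The default pedigree mirrors the classic White Duroc x
Erhualian resource population: 2 F0 boars x 17 F0 sows produce the F1;
9 F1 boars x 59 F1 sows produce 1912 F2 pigs allocated round-robin to 6
batches.  F0 dams are assigned to sires round-robin, F1 breeders are spread
across F0 litters round-robin, and F2 litter sizes are as equal as possible
(the real litter structure is not part of the design specification).  F2
sex is Bernoulli with configurable male fraction (default 0.5).

**Founders and gene dropping.** Per-SNP allele frequencies for the two
breeds are drawn from Beta distributions (defaults Beta(8,2) and Beta(2,8),
i.e. strongly divergent breeds), or pinned to constants for controlled
experiments.  Founder haplotypes are drawn per breed frequency; offspring
receive one recombinant gamete per parent under Haldane's no-interference
model (crossover count Poisson in the map length, positions uniform,
default 18 autosome-like chromosomes of 100 cM).  Genotypes are haplotype
sums, so the clean matrix contains zero Mendelian errors by construction;
missingness and genotyping errors are injected afterwards at configurable
rates, leaving the clean matrix untouched.

**Trait model.** For each trait,

    y = offset * 1[male] + batch + sum_q dosage_q * beta_{q,sex} * sd_e
        + u + e

with batch effects iid N(0, sd_batch^2), QTL effects in residual-SD units,
residuals N(0, sd_e^2), and a polygenic term u drawn from the
pedigree-expected additive relationship matrix A (Wright's numerator
relationship), *not* from the realized marker matrix — the generator stays
independent of the estimator under test.  Per-sex genetic variance is
sigma_g^2(s) = h2_s / (1 - h2_s) * sd_e^2, so the configured h2 is exactly
sigma_g^2 / (sigma_g^2 + sigma_e^2) within each sex; QTL and batch variance
sit on top of that budget.  `cross_sex_rg` sets the genetic correlation
between the sexes: 1 (default) shares one polygenic background, 0 gives
each sex an independent one.

**What the generator does not emulate.** Sequence-level variation, real pig
linkage maps and interference, dominance/epistasis, maternal and litter
environments, selection, and X-specific inheritance (an optional X
chromosome is simulated autosomally and excluded from trait architecture
and kinship).  Passing tests therefore demonstrate correctness of the
statistical machinery under an additive, autosomal, environment-simple
model — not robustness to every feature of real data.

## Quality control

Samples first, SNPs second, one pass each.  Samples are kept with call
rate > 0.10 and per-sample Mendelian inconsistency rate < 0.05; SNPs with
call rate > 0.9, MAF > 0.05, Hardy-Weinberg exact p > 1e-6 and Mendelian
error rate < 0.1.  All comparisons are strict, and every threshold is a
function argument.  The 0.10 sample call-rate default is deliberately
permissive (it mirrors the chip-QC convention of discarding only failed
arrays); users wanting the stringent 0.90 set it explicitly.

The HWE test is the exact conditional test: conditioning on the observed
allele counts, the p-value sums the probabilities of all heterozygote
counts whose conditional probability does not exceed the observed one.  It
is evaluated on F2 individuals only when the pedigree identifies them,
since founder and F1 genotype frequencies are not expected to be in
equilibrium.  Mendelian errors are offspring dosages impossible given both
parents' non-missing dosages; rates divide errors by assessable trio calls.

## Phenotype preparation

Traits strongly deviating from normality (Shapiro-Wilk p < 1e-8) are
log2-transformed; the transform demands strictly positive values and an
optional offset is available but off by default.  Because the Shapiro
statistic loses accuracy beyond n = 5000, larger samples are deterministically
thinned to 5000 order statistics for the decision only.  Sex effects are
least-squares fits of trait ~ sex + batch; fold differences are reported on
the raw scale.  q-values are Benjamini-Hochberg (pi0 = 1) by default — the
conservative special case of the Storey estimator, whose lambda = 0.5
variant is available — and hue angle H* = arctan(b*/a*) is reported in
degrees, the meat-science convention.

## Mixed models

**Kinship.** VanRaden's centred cross-product matrix: dosages centred by
twice the allele frequency and scaled by sum(2p(1-p)), monomorphic and
(by default) sex-chromosome SNPs excluded, missing dosages mean-imputed for
this computation only.  This matrix is PSD by construction.

**REML.** The polygenic model y = Xb + u + e with var(u) = sigma_g^2 K is
profiled over h2 = sigma_g^2/(sigma_g^2 + sigma_e^2): one eigendecomposition
of K turns every likelihood evaluation into a weighted least-squares solve;
a 50-point grid brackets the optimum and golden-section search refines it
to 1e-6.  The one-parameter profile makes this derivative-free strategy
robust; a flat profile (e.g. identity kinship) is flagged unidentifiable
and estimates within 1e-3 of the h2 in {0, 1} boundary are flagged but not
fatal.  Total variance is profiled out, and REML (not ML) removes the
fixed-effect bias.

**Score scan.** Each SNP is centred, mean-imputed, and projected against
the covariates in the fitted inverse-covariance metric; with null residuals
r,

    beta = g~' V^-1 r / (g~' V^-1 g~),   se = (g~' V^-1 g~)^(-1/2),

and (beta/se)^2 is referred to chi-square(1).  Because the covariates are
fitted by GLS, this equals the joint GLS coefficient for the SNP when the
variance is known (verified to 1e-8 against an independent joint-fit
oracle).  No per-SNP variance re-fit is performed; monomorphic SNPs are
flagged untested.

**A note on F2 designs and the GRM.** In an F2 cross, linkage
disequilibrium spans whole chromosomes, so the effective number of
independent markers is small and the realized GRM is a noisy, shrunken
image of the pedigree-expected relationship (measured regression slope
~0.6 at 10 Morgans of genome).  Fitting a trait whose polygenic values were
generated from the pedigree-expected kinship with the realized GRM
therefore attenuates h2 substantially — a property of the design, not of
the estimator.  Parameter-recovery experiments consequently fit with the
generating (pedigree-expected) kinship, the correctly specified covariance;
scan calibration and power experiments use the genomic kinship exactly as
the pipeline does, since score-test calibration is insensitive to this
mismatch.  Heritability estimates from the pipeline on marker data should
be read as internally comparable rather than unbiased absolute values.

## Dimorphism statistics

**z-test.**  Z = (beta_m - beta_f) / sqrt(se_m^2 + se_f^2), standard normal
under equal allelic effects in independent strata.  SNPs with MAF < 0.05 in
either sex (unstable stratum estimates) or untested in either stratum are
flagged rather than tested.  The default is two-sided in Z; one-sided modes
(`male` / `female`) are exposed because directional use is sometimes wanted,
but discovery of dimorphic loci is direction-free.

When the two sexes share one polygenic background (cross_sex_rg = 1),
opposite-sex sibs correlate both in genotype and in trait, the stratum
effect estimates become positively correlated (measured score correlation
~0.28 on the default design), and the z-test is conservative (empirical
type-I rate ~0.02 at nominal 0.05).  This is intrinsic to applying an
independent-strata statistic in a family design and is left as documented
behaviour; calibration experiments use sex-specific backgrounds
(cross_sex_rg = 0), where the empirical rate is 0.048 and p-values pass KS
uniformity.

**Heritability permutation test.** Observed statistic |h2_m - h2_f| from
per-stratum REML fits (batch covariate, kinship restricted to the stratum);
sex labels are shuffled B times (default 1000, stratum sizes preserved) and
p = (1 + #{null >= observed}) / (1 + B), the add-one estimator that bounds
p below by 1/(B+1).  A trait matrix may be passed so that one permutation
set and its per-stratum eigendecompositions are shared across traits — the
natural batching for trait panels; permutation draws are then common across
traits, which leaves each trait's p-value exact.  Stratum kinship is the
row/column restriction of one global autosomal matrix, not re-estimated per
permutation.

**Scan comparison.** Significant sets at a per-scan threshold (suggestive
1/N_snp, genome-wide 0.05/N_snp); a SNP-trait pair is stratified-detected
if significant in either sex's scan.  The accounting reports intersection,
stratified-only (also as % of the combined count) and shared as % of the
union; "loci" are SNP-trait pairs, without LD clumping.  A Welch t-test
compares |Z| of the stratified-only SNPs against all tested SNPs.

## Problem sizes and tolerances in the validation studies

Validation cohorts keep the paper-like parent design (2, 17, 9, 59) and
scale only the F2 count: ~900 F2 with 2016 SNPs (18 x 112) for scan
studies, 500-600 F2 for variance-component studies, B = 200 permutations
with 50 null traits for calibration and 10 replicates for power.  These
sizes give binomial error bands (3 SD) that the checks use explicitly and
complete in a few minutes on one CPU.  Empirical fractions are pooled over
5 seeds for z-test calibration because cross LD correlates SNPs within a
cohort, inflating the single-cohort variance of the rejection fraction
beyond the binomial band.

## Known limitations

- Heritability from marker-based kinship in an F2 is attenuated (above);
  no bias correction is attempted.
- The z-test assumes independent strata; with a fully shared polygenic
  background it is conservative, never anticonservative, in this design.
- X-chromosome inheritance is not modelled; X SNPs are excluded from
  kinship and handled with autosomal coding in scans.
- No genotype-by-sex interaction terms inside the mixed model, no LD
  clumping of loci, no imputation of missing genotypes.
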