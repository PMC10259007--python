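# Methods

`thermoqtl` re-implements, as a tested pipeline on synthetic data, the
quantitative-genetic analysis of acute hyperthermia resistance in juvenile
rainbow trout: time to loss of equilibrium (TLE) under a controlled heating
challenge, its heritability and maternal (dam) variance share, its genetic
correlations with production traits, and Bayesian variable-selection GWAS
with Bayes-factor QTL calling. The raw data of such studies are typically
not public, so the package ships a first-class generator that emulates the
study design and uses the published estimates as generating truth; every
analysis stage is then validated by parameter recovery.

## The animal model

The analysis phenotype of fish *k*, challenged on day *i*, from dam *j*, is

    y_ijk = mu + day_i + dam_j + u_ijk + e_ijk

with `day` a fixed factor (one challenge group per day), `dam` an IID
common-environment effect shared by maternal sibs, and `u` an additive
genetic effect with covariance proportional to a pedigree (**A**) or
genomic (**G**) relationship matrix. Heritability is
`h2 = sigma_u^2 / sigma_p^2` with
`sigma_p^2 = sigma_u^2 + sigma_dam^2 + sigma_e^2`; the dam share is
`sigma_dam^2 / sigma_p^2`. Genetic correlations come from bivariate fits,
`r_g = cov(u_x, u_y) / sqrt(sigma_ux^2 sigma_uy^2)`.

**A** is built by the tabular recursion (diagonal 1 + inbreeding
coefficient). **G** is VanRaden's first method with observed allele
frequencies — columns centred by `2p`, cross-products divided by
`2*sum p(1-p)` — after per-SNP mean imputation of missing calls. By
default **G** is blended as `0.95 G + 0.05 A` so the mixed-model
coefficient matrix is positive definite; the weight is configurable.

### REML

Variance components are estimated by average-information (AI) REML with an
EM safeguard: an AI step whose candidate leaves the parameter space
(Cholesky failure, negative variance below the floor of `1e-8 sigma_p^2`)
or decreases the restricted likelihood is halved up to 12 times and then
replaced by the monotone EM update. Convergence requires a relative
parameter change below `1e-8` on a minimally-halved step; a flat-likelihood
plateau (improvement < 1e-9 over three accepted steps) is also accepted as
a stationary point. Estimates at the variance floor are flagged
`boundary`. Standard errors are read from the inverse AI matrix; ratios
(h2, dam share, r_g) carry first-order delta-method errors. Model choice
for the dam term uses `AIC = -2 logL + 2 * (number of variance
parameters)`; a tie keeps the simpler model.

Bivariate fits are run internally on unit-variance trait scales (the AI
matrix is badly conditioned when trait variances differ by ~100x) and
back-transformed. Covariance parameters are kept inside the correlation
bound |r| <= 0.999. For traits recorded on disjoint sets of animals the
residual covariance is structurally fixed at zero. For traits on the same
animals it is estimated by default, but at desk-scale n the genetic and
residual covariances trade off along a nearly flat likelihood ridge, so the
recovery experiments set `fix_residual_cov=True` — which matches the
generator, whose residuals are independent across traits.

## BayesC-pi GWAS

The GWAS model replaces the polygenic term with explicit SNP effects:

    TLE_ijk = mu + day_i + dam_j + sum_l delta_l z_kl a_l + e_ijk

where `z_kl` is the (centred) reference-allele dosage, `delta_l` is an
inclusion indicator with prior `P(delta_l = 1) = pi`, included effects are
`N(0, sigma_a^2)`, and `pi` has a Beta(alpha, beta - alpha) prior — alpha
expected non-zero SNPs among beta total (both default from the panel:
`alpha = max(4, 0.01 beta)`). Each Gibbs cycle updates the day effects
(flat-prior Gaussian conditionals), the dam effects and their variance, all
SNP indicator/effect pairs in a seeded fixed permutation, `pi` from its
Beta conditional on the current model size, and the effect and residual
variances from scaled inverse-chi-square conditionals (df 4; the effect
scale is derived from a prior heritability of 0.5 spread over alpha SNPs).
The sweep is compiled with numba in SNP-major memory layout.

Evidence per SNP is `logBF = 2 ln[(P_l/(1-P_l)) / (pi/(1-pi))]` with `P_l`
the posterior inclusion probability capped into
`[1/n_saved, 1 - 1/n_saved]` and `pi` the posterior mean (a prior-pi mode
is available). Convergence checks: visual traces of the sampled variances,
and the correlation of genomic values (GEBVs) from two differently seeded
runs, which must exceed 0.99.

Desk-scale MCMC default is 20,000 cycles / 2,000 burn-in / thinning 10
(about 20 s for 1,000 fish x 2,000 SNPs on one core); the dense-array
setting of 600,000 / 10,000 / 40 is a configuration choice.

## QTL calling

On each chromosome, peaks are local maxima with `logBF >= 6`. A credibility
interval grows outward from the peak by chaining: any SNP with
`logBF >= 3` within 200 kb of the current boundary extends the boundary,
until a window holds none (a strict fixed-window mode is selectable).
A peak with *no* supporting SNP inside the window is discarded as a
genotyping artifact — the rule that removes spurious isolated hits of the
kind seen on chromosome 30 in the emulated study. Overlapping intervals on
a chromosome merge under the higher peak.

Variance explained: peak share `2p(1-p) a_hat^2 / sigma_u_hat^2 * 100` and
an LD-aware region share (variance of the summed regional genomic value),
both against the empirical variance of the total GEBVs. Note the caveat:
the sparse sampler recovers a planted QTL's *absolute* variance
contribution almost exactly, but at desk scale it cannot include the
hundreds of tiny background effects, so the GEBV-variance denominator
understates the total genetic variance and the *share* is biased upward.
Percentages from desk-scale runs should be read as upper bounds.

Gene annotation counts genes (GFF3 gene features or BED intervals) whose
1-based closed interval overlaps the credibility interval by at least 1 bp.

## Peak contrasts and isogenic concordance

At a peak SNP the phenotype is corrected by subtracting the null model's
day estimates and dam BLUPs (the SNP is not co-fitted). The homozygote
difference is reported as a positive fraction of the phenotypic SD with the
favourable homozygote named; significance is a Tukey HSD across the three
genotype classes. The dominance deviation
`d = mean(het) - (mean(hom0) + mean(hom2))/2` is tested, following the
emulated study, with a one-sample t-test of the heterozygotes against the
observed homozygote midpoint treated as a constant. That convention is
anticonservative — it ignores the midpoint's sampling error and the family
correlation of sibs; measured size on purely additive desk-scale data is
roughly 20% at nominal 5%. A bootstrap alternative over all three classes
(`dominance_test="bootstrap"`) accounts for the midpoint error and is close
to nominal; the t-test remains the default for comparability.

The isogenic-line check reports every SNP above the logBF threshold at
which two line genomes carry different alleles, marks the favourable allele
(reference if the model-averaged effect is positive, alternate otherwise),
and flags whether the resistant line carries it.

## The synthetic-data generator

The generator emulates the study design rather than any particular dataset:

* **Matings.** 10 independent full-factorial blocks of 9-10 sires x 7-8
  dams (99 sires, 76 dams); offspring are drawn uniformly over mated pairs,
  giving hatchery-like variable family sizes.
* **Genotypes.** Linkage-free Mendelian gene dropping: founders at
  Hardy-Weinberg proportions for per-SNP founder frequencies
  (Uniform(0.1, 0.9) by default), offspring from independent gametes per
  locus. Missingness is the only error model.
* **Challenge phenotypes.** Latent resistance = day effect + dam effect +
  planted QTL effects + polygenic + residual, with the polygenic part a sum
  of small effects at all non-QTL markers (so REML/GBLUP and the sampler
  see the same genome that generated the data) and planted-QTL variance
  `2p(1-p)a^2` counted inside the configured additive variance. The latent
  value maps to a raw time by inverting the group heating curve's
  cumulative-heat function (3.1 degC/h for 1.5 h then 0.9 degC/h, group
  initial temperatures 16.1-18.4 degC), first-order matched to the group's
  target raw-time mean and SD. The seven groups' targets (318.7 +/- 14.1
  through 473.8 +/- 61.6 min, sizes 187:196:192:195:199:196:162) reproduce
  the published between-group heterogeneity, and the concave map yields the
  characteristic negative skew of standardized TLE. An affine map is
  selectable for diagnostics; the two give statistically indistinguishable
  recovery.
* **Correlated body weight.** Juvenile body weight (mean 87.4 g, SD 12.2 g,
  h2 0.19) shares marker effects with resistance at a configurable genetic
  correlation (default -0.49); no dam effect, matching the emulated
  finding.
* **Harvest traits.** The genetically governed basis is body weight, fork
  length, fat at two sites, carcass yield % and head %, drawn with a
  configurable genetic covariance (moderate heritabilities, strong
  weight-length correlation by default). Component weights derive from the
  basis: HGCW = HGC% x BW2, HeadW = Head% x BW2, and viscera close the
  weight balance to within 10 g; exactly `n_violations` records (24 by
  default) receive a planted inconsistency larger than 10 g, with truth
  labels returned. Note the closure constraint means the component weights
  themselves cannot carry an arbitrary independent covariance; the
  configurable covariance lives on the basis traits.

What the generator does **not** emulate: linkage and LD (each locus
segregates independently), genotyping error beyond missingness, selection
or non-random mating, genotype-by-environment interaction, and the
acclimation-day confound beyond its mean effect (the emulated study could
not separate acclimation from heating-rate effects either). Consequently,
passing recovery tests shows the estimators are correct for family-
structured data of this design; it does not show robustness to LD between
markers and causal loci — on real arrays credibility intervals derive their
meaning from LD, which is exactly the part replaced here by toy maps with
explicit support structure.

## Experiment scales

Replicated experiments run at desk scale, chosen so one replicate takes
seconds and a 20-replicate experiment minutes on one core: n = 800
offspring x 3,000 SNPs for heritability/dam-share recovery (truth 0.29 /
0.06; per-replicate SE of h2 ~0.09), n = 1,000 x 2,000 for the
homozygote-contrast recovery (truth 69% of SD at MAF 0.42), n = 800 x
2,000 with 12 replicates for the genetic correlation (truth -0.49,
per-replicate SD ~0.14), and n = 400-1,000 x 1,000-2,000 for sampler
calibration and power. The full-array configuration (420K SNPs, 600K
cycles) is reachable through the same config surface.

## Numerical conventions

Sample SDs use denominator n-1 throughout. Cumulative degree-minutes sum
whole minutes from t = 1, truncating partial final minutes. QC thresholds
are strict inequalities in the stated directions (individual call rate
removed when < 0.90; SNPs kept when call rate > 0.97, MAF > 0.05,
Hardy-Weinberg p > 1e-5); the Hardy-Weinberg test is a 1-df Pearson
chi-square against expectations from the observed allele frequency, no
continuity correction, undefined (and MAF-removed anyway) for monomorphic
SNPs. MAF uses non-missing calls only. Individuals are filtered before SNP
statistics are computed, so QC is idempotent. Coordinates are 1-based
inclusive bp; report tables round Mb to 2 decimals. All randomness flows
from explicit integer seeds; identical seeds give bit-identical outputs.
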