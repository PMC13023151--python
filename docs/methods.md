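# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limitations of `pigiris`.

## Phenotype model

Each eye is scored with a dominant color (dark, medium, or light brown,
or pale) and, when a single iris shows two colors, a secondary color.
Medium brown is merged into dark brown before classification because the
two shades are not reliably separable under field conditions. The
animal-level phenotype is then one of five categories:

* **heterochromia iridis** — at least one eye carries a secondary color
  (*unilateralis* one eye, *bilateralis* both);
* **heterochromia iridum** — the two single-colored eyes differ;
* otherwise the shared color: **dark brown**, **light brown**, or **pale**.

Animals with a single scored eye are excluded rather than classified.
Note that two differently colored eyes are classified as *iridum*
(binocular heterochromia); the within-iris condition is *iridis*. The
prevalence table prints percentages at one decimal with half-up
rounding; aggregate rows ("any brown", total iridis) report the sum of
the rounded component percentages, which is the convention of published
prevalence tables and can differ from the percentage of the summed
counts by one unit in the last decimal. Carrier/allele frequencies, by
contrast, are rounded with Python's default (half-even) rule.

## Liability-threshold animal model

The categorical trait is modelled with a latent Gaussian liability

    l = X b + Z a + e,   a ~ N(0, K sigma2_a),   e ~ N(0, I),

cut by ordered thresholds t1 < t2 < t3 < t4 into the five categories
(ordered dark < light < pale < iridum < iridis, mirroring the
prevalence table; the order is configurable since no biological
ordering is self-evident). Fixed effects are farm-date (6 levels) and
sex (3 levels: sow, boar, barrow), intercept included, dummy coding
with the first level dropped. K is a pedigree (A) or single-step (H)
relationship matrix. Identifiability is fixed by sigma2_e = 1 and
t1 = 0, so the liability-scale heritability is
h2 = sigma2_a / (sigma2_a + 1).

The bivariate extension couples the liability with a continuous
production trait through a 2x2 additive-genetic covariance matrix
(Kronecker product with K); the residual covariance is diagonal, the
categorical residual variance stays fixed at 1, and the continuous
trait additionally carries a centered age covariate. The genetic
correlation is r_g = sigma_a12 / sqrt(sigma2_a1 sigma2_a2). The
continuous trait is standardised internally, which leaves h2 and r_g
unchanged.

### Gibbs sampler

Latent liabilities are drawn from truncated normals between the
thresholds of the observed category (inverse-CDF sampling, interval
probabilities clipped at 1e-12). Fixed effects have flat priors and are
drawn from their multivariate-normal conditionals. Free thresholds are
drawn uniformly between the adjacent liability extremes. The genetic
variance carries a scaled inverse chi-squared prior (nu = 4, S2 = 0.5
by default, configurable); the 2x2 genetic covariance an inverse
Wishart conditional; the continuous residual variance a scaled inverse
chi-squared conditional.

Two implementation choices matter for speed and mixing:

1. **Marginalisation to phenotyped animals.** The sampler works on the
   relationship matrix restricted to the phenotyped individuals. This
   is an exact marginalisation of the multivariate normal — the
   submatrix of A (or H) is the covariance of the corresponding
   subvector — and changes no estimand reported here (variance
   components, thresholds, h2, r_g). Breeding values of unphenotyped
   relatives are not produced, which this package does not need.
2. **Eigenbasis parameterisation and a collapsed variance update.**
   With K = U D U' the genetic values are represented as a = U v, so
   the conditional of v is diagonal and one iteration costs two dense
   matrix-vector products. The genetic variance is updated from its
   *partially collapsed* conditional p(sigma2_a | l, b) with v
   integrated out — in the eigenbasis the rotated residuals are
   independent N(0, sigma2_a d_i + 1), so this one-dimensional density
   is cheap and is sampled by slice sampling. Collapsing removes the
   strong v–sigma2_a coupling that otherwise makes the variance chain
   wander (split-R-hat values well above 1.1 at desk scale); with the
   collapsed update split-R-hat of h2 is typically close to 1.

Chain defaults are 20,000 iterations, 5,000 burn-in, thinning 10
(1,500 retained samples), one explicit seed; production-scale settings
(500,000 / 100,000 / 1,000) are available through `ChainConfig`.
Summaries report posterior means and 95% highest-posterior-density
intervals; the HPD is the shortest contiguous window containing
ceil(0.95 n) sorted samples, ties broken toward the lowest start.

A note on the variance prior: a scaled inverse chi-squared density
vanishes extremely fast as sigma2_a -> 0, so under a true h2 of exactly
zero the posterior cannot concentrate arbitrarily close to zero under
the default prior. Tests of null behaviour therefore use a weaker
configured prior (nu = 1, S2 = 0.1).

## Relationship matrices

* **A** by the tabular method (founders diagonal 1,
  a_ii = 1 + a_sd/2, a_ij = (a_js + a_jd)/2).
* **A-inverse** by Henderson's rules with inbreeding: the Mendelian
  sampling variance is d_i = 1 − (a_ss + a_dd)/4 = 0.5 − (F_s + F_d)/4.
* **G** as the centered dosage cross-product scaled by the sum of
  2p(1−p) with allele frequencies observed in the data (VanRaden
  method 1), after mean imputation of missing dosages.
* **H-inverse** as A-inverse plus the genotyped-block correction
  Gw^-1 − A22^-1, where Gw = (1−w) G* + w A22, w = 0.05, and G* is G
  rescaled so its mean diagonal and mean off-diagonal match A22's.
  A dense textbook H assembly is provided both as the covariance for
  samplers and as the test oracle for the inverse.

PCA covariates come from the SVD of the mean-imputed, centered,
unit-variance-scaled dosage matrix (monomorphic SNPs dropped, no LD
pruning); each component's sign is fixed so its largest-magnitude SNP
loading is positive.

## Quality control

Filters and their boundary conventions:

* duplicate positions: **all** variants at a duplicated (chrom, pos)
  are removed (deterministic; no survivor is chosen);
* samples: call rate < 0.95, or autosomal heterozygosity deviating more
  than 3 standard deviations from the cohort mean (two-sided; with zero
  variance nobody is an outlier);
* variants, in order: call rate < 0.95, MAF < 0.01, Hardy–Weinberg
  exact p < 1e-4 (autosomes only; per breed when breeds are analysed
  separately, then panels are intersected on (chrom, pos, ref, alt)
  with no strand flipping);
* X chromosome: male heterozygous calls outside the pseudoautosomal
  region (positions <= 7,000,000) are set to missing; remaining X
  genotypes are treated as homozygous diploid;
* post-imputation: retain MAF > 0.01 **and** imputation r2 > 0.5
  (strict, as printed).

The Hardy–Weinberg exact test conditions on allele counts and sums the
probabilities of all heterozygote counts (same parity) no likelier than
the observed one; probabilities are computed in log space with a 1e-12
relative tie gate and the implementation is verified against an
exact-rational enumeration for n <= 200.

## Association scans

Twelve case-control contrasts of the five categories are defined
(any-brown or dark-brown cases against pale / iridis / iridum controls
and combinations, dark vs light brown, and iridum against the rest);
animals in neither set are excluded per scenario.

**SNP scan.** A mixed linear model per SNP with the binary phenotype as
a 0/1 linear response, covariates (4 PCs, sex), and a polygenic term
with GRM covariance. Variance components are estimated once under the
null by REML (profiled over the variance ratio in the GRM eigenbasis,
grid search plus bounded refinement), then each SNP gets a
generalized-least-squares effect with the fitted ratio. The Wald
statistic uses a per-SNP residual variance (null weighted RSS minus the
SNP's contribution, df = n − p − 1), so with an identity GRM the scan
collapses exactly to ordinary regression. Monomorphic SNPs are skipped.

**Haplotype scan.** Phased genotypes are cut into sliding windows of 10
SNPs with step 5 per chromosome; a trailing partial window is emitted
only when at least 2 SNPs would otherwise stay uncovered. Every
haplotype allele with frequency in [0.01, 0.99] is tested with a
two-sided Fisher exact test on (this haplotype vs all others) x (case
vs control chromosomes); odds ratios use the Haldane–Anscombe 0.5
correction when a cell is empty. The covariate-adjusted reading
(logistic regression on haplotype dosage with 20 PCs and sex) is
available as a secondary mode; the Fisher test admits no covariates, so
the two cannot be combined in one test.

The genomic inflation factor is the median association chi-squared over
the null chi-squared median (~0.4549). Significance tags use strict
thresholds p < 5e-8 (genome-wide) and p < 1e-5 (suggestive). The
per-megabase summary keeps the minimum-p record per (breed, chromosome,
1-Mb bin) over all scenarios, haplotypes binned by span midpoint.
Candidate genes are those whose half-open span intersects hit ± 2 Mb.

## Structural-variant screen

Sequenced samples are grouped by focal-allele copy number (homozygous /
heterozygous / non-carrier), the focal allele being either a haplotype
string in a phased window or a variant allele. Mean depth per 250-bp
window is z-scored per sample across the analysed interval (e.g. the
92–96 Mb region) using the population (n-denominator) standard
deviation; normalisation is regional, not genome-wide, and is invariant
to per-sample affine depth rescaling. The primary contrast is the
difference of hom-carrier and non-carrier group-mean z-scores, flagged
at |difference| > 3 (strict); with no homozygous carriers the contrast
downgrades to het-vs-non with a warning. Flagged windows are checked
for the deletion-consistent ordering hom <= het <= non (tolerance 0.1).
LD with a focal variant is the squared Pearson correlation of dosages;
the SV screen retains r2 > 0.8 (strict) and reports the perfect-LD
subset separately.

## Synthetic-data generator

The generator produces every input with known truth:

* **Pedigree**: founders split evenly between sexes; each later
  generation mates every female of the previous generation with a
  random male and produces a fixed litter size. Offspring sexes
  alternate within a litter (random phase) so both sexes always exist;
  a third sex level (barrow) is assigned at phenotype time to half of
  the males. Pedigree depth and family sizes are free parameters. The
  heritability-recovery experiments use 500 founders, 2 generations,
  litter size 2 (n = 1,500): many moderately sized families keep the
  between-replicate spread of heritability estimates small. The
  bivariate genetic-correlation experiments use an even shallower
  750-founder, 1-generation design (same n), which minimises the
  family-level sampling noise of the realized cross-trait genetic
  correlation.
* **Genotypes**: founder haplotypes are Bernoulli draws at per-SNP ALT
  frequencies uniform in [maf_low, maf_high]; gametes recombine under
  the Haldane model at 1 cM/Mb, chromosomes segregating independently.
  Phase is recorded; Mendelian transmission is exact by construction.
* **Phenotypes**: liability = farm-date effect + sex effect + additive
  genetic value + residual, with genetic values drawn through the
  Cholesky factor of A (or of G on request) so their covariance is
  exactly proportional to the chosen relationship matrix; total
  variance 1 (sigma2_a = h2, sigma2_e = 1 − h2) so the generating
  thresholds live on the standard-normal scale. The companion
  continuous trait shares the fixed effects and gets genetic values
  drawn jointly with the liability's at correlation r_g. Both public
  views (`simulate_liability_phenotypes`, `simulate_continuous_trait`)
  are slices of one seeded run with a documented stream order, so the
  same seed yields exactly the requested cross-trait correlation.
  Default generating thresholds (−0.04, 0.39, 0.59, 1.34) give category
  proportions close to the observed prevalence spectrum.
* **Coverage**: negative-binomial depth per 250-bp window with variance
  mu + phi mu^2 (phi = 0.02 by default, roughly the overdispersion of
  short-read depth at 30x; Poisson in the limit phi -> 0). Expected
  depth is scaled by 0 in deletions for homozygous carriers and by 0.5
  for heterozygous carriers, and is identical across groups elsewhere.

What the generator does **not** emulate: demography, selection and
breed divergence (founders are exchangeable, so breed labels carry no
allele-frequency signal); linkage disequilibrium beyond what descent
from 500–600 founders induces (haplotype frequencies in founders are
products of allele frequencies); genotyping and phasing error;
sequencing-read-level artefacts (GC bias, mappability — depth is drawn
directly at window level). Passing tests therefore demonstrate
correctness of the estimators under the stated generative models, not
robustness to real-data artefacts.

## Problem sizes and runtimes

The test suite runs the samplers at n = 1,500 with 20,000-iteration
chains (about 40 s univariate, 90 s bivariate on one core; the
heritability-recovery experiment repeats 10 seeds), the GWAS
calibration and power checks at n = 480–600 with 200–800 SNPs, and the
coverage screen at the full 92–96 Mb / 120-sample scale (16,000 windows
per sample). These sizes were chosen so the whole suite completes in
well under half an hour on a single core while keeping every check at
the scale its claim refers to.

## Known limitations

* The ordinal model imposes an ordering (dark < light < pale < iridum
  < iridis) on categories with no self-evident biological order; the
  order is configurable and the estimates should be read with this
  assumption in mind.
* The bivariate sampler requires both traits observed on every fitted
  individual; animals with only one trait are dropped rather than
  handled by missing-data augmentation.
* The mixed-model scan treats the binary phenotype as a linear 0/1
  response (as the standard tools do), not through a liability link.
* REML assumes the null variance ratio transfers to every SNP
  (one-ratio approximation); a per-SNP refit is not implemented.
* The exact Fisher test is conservative at small haplotype counts; its
  realised size at nominal 0.05 is below 0.05 by construction, which
  the calibration test accounts for by comparing against the exact
  expected size given each table's margins.
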