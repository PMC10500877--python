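# Methods

## The model

Generation proxy selection mapping (GPSM) asks whether a SNP's genotype is
associated with *when* an animal was born. Under sustained directional
selection an allele's frequency trends over time, so dosage and birth date
correlate; under drift alone any such correlation is bounded by what
pedigree structure produces, and a genomic relationship matrix (GRM)
absorbs exactly that structure. The dependent variable is AGE, the number
of months between an animal's birth month and a fixed epoch (January 2006
by default); animals born before the epoch have negative AGE.

Three fits share the machinery:

1. **Null variance components** (`AgeVarianceModel`):

       y = 1 mu + g + e,   g ~ N(0, G sigma2_g),   e ~ N(0, I sigma2_e)

   estimated by average-information REML. The quantity of interest is
   PVE = sigma2_g / (sigma2_g + sigma2_e), the proportion of AGE variance
   captured by genome-wide SNPs. PVE here is *not* a heritability: AGE is
   not a biological trait, and PVE instead reflects how strongly pedigree
   and sampling structure predict birth date.

2. **Per-SNP scan** (`SelectionScanModel`): for each SNP s,

       y = mu + x_s b_s + g + e

   with the variance components *fixed* at the null fit (the per-SNP
   components are of no interest and re-estimating them is two orders of
   magnitude slower while moving p-values only in the third decimal). Each
   test is then generalized least squares under V = G sigma2_g + I sigma2_e
   with a Wald chi-square(1) p-value. P-values are converted to Storey
   q-values and SNPs with q < 0.10 are called significant.

3. **Bivariate model** (`BivariateAgeModel`): two populations measured for
   the same proxy, sharing one GRM over the union sample, with genetic
   covariance sigma_g12 and zero residual covariance (no animal has records
   in both populations, so the residual cross term is structurally absent).
   The genetic correlation r_G = sigma_g12 / sqrt(sigma2_g1 sigma2_g2)
   summarises whether the same loci change frequency concordantly in both
   populations.

## The GRM

The Yang et al. estimator: off-diagonals average the cross-products of
centred, standardised dosages; diagonals use the less biased
`1 + [x^2 - (1+2p)x + 2p^2] / 2pq` form. Allele frequencies come from the
analysed subset (multi-population subsets use pooled frequencies, because
one GRM serves the pooled analysis). Missing genotypes are handled by
per-pair deletion with a pair-specific SNP count, which preserves
unbiasedness at the cost of carrying a count matrix. Note that with
in-sample allele frequencies the expected mean off-diagonal among
unrelated individuals is -1/(n-1), not 0; tests assert that value.

## Numerics

* The univariate REML and the scan run in the eigenbasis of G: one
  symmetric eigendecomposition makes every candidate covariance diagonal,
  so each REML iteration is O(n) and each SNP costs one rotation, executed
  as a single blocked matrix product over all SNPs.
* AI-REML: Newton steps with the average-information matrix; an EM-style
  step replaces an AI step that would leave the parameter space, and any
  step that would decrease the restricted likelihood is halved until it
  does not (so accepted iterations are monotone). Start values split
  var(y) evenly; convergence at |delta logL| < 1e-8 or 100 iterations;
  variances floored at 1e-6 var(y).
* GRM eigenvalues below 1e-8 are clipped to 1e-8 (pedigree data yields
  near-singular GRMs; the clip is logged).
* Standard errors come from the inverse AI matrix at convergence; PVE and
  r_G use the delta method. r_G is reported clamped to [-1, 1] with a
  warning when the unconstrained covariance exceeds the bound.
* Likelihood-ratio tests for a variance component on the boundary
  (sigma2_g = 0) use the 50:50 mixture of chi2(0) and chi2(1); the
  covariance sigma_g12 = 0 is an interior point and uses plain chi2(1).
* Zero-variance SNPs (after mean imputation) are reported with b = 0,
  p = 1 and a flag. Missing dosages are mean-imputed per SNP for the scan
  only, keeping the one-time decomposition valid for every SNP.

## q-values

Storey's estimator: pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on the
grid 0.05..0.95, smoothed with a cubic polynomial fit and read off at the
largest lambda, clamped to (0, 1]. (The reference implementation uses a
df-3 smoothing spline; a cubic polynomial over the same 19-point grid is
the dependency-free equivalent and agrees to well within the estimator's
sampling noise.) q-values are monotonised from the largest p-value down,
so tied p-values receive identical q-values. Below 100 p-values the
smoother is unreliable and the code falls back to pi0 = 1, i.e. plain
Benjamini-Hochberg, with a warning.

## The gene-drop null

The drift null re-creates a pedigree's genotypes without selection:

* **Founder pool** — haplotypes at sites evenly spaced along the 18 pig
  autosomes, allele frequencies drawn from a U-shaped Beta(0.5, 0.5)
  spectrum truncated to [0.01, 0.99], alleles i.i.d. Bernoulli (linkage
  equilibrium), fixed sites redrawn. This replaces a coalescent founder
  simulation deliberately: the drift-null contract needs a realistic
  frequency spectrum, not realistic founder LD. Founder LD would add some
  short-range correlation among test statistics but does not bias the
  per-SNP null, which is what the false-positive bound measures; this is
  the one structural difference from coalescent-founded runs worth
  remembering when interpreting the bound.
* **Assignment** — each pedigree founder receives a distinct pool
  individual without replacement (with replacement, warned, only if
  founders outnumber the pool). Two-population runs support a shared pool
  (`method1_shared`: recently diverged extreme) or independent pools per
  population (`method2_independent`: unrelated extreme).
* **Drop** — per meiosis and chromosome, a Poisson(1 Morgan) crossover
  count with uniform breakpoints and no interference; the genetic map is
  uniform at 1 Morgan per autosome (only physical evenness of sites is
  specified by the design). Individuals with one recorded parent get the
  missing gamete from a fresh "phantom" pool founder. Mendelian
  consistency is checkable per trio and asserted in tests.
* **Array extraction** — genotyped individuals' dosages at a uniform
  random subset of sites that segregate and pass the same MAF >= 0.01
  screen as real arrays (flag `min_maf`), with AGE taken from the
  pedigree's birth months.

## The synthetic breeding program

`BreedingConfig` describes a closed nucleus herd with discrete
generations: founder sires and dams, one litter of 8 per dam, truncation
selection keeping the top 10% of male and 25% of female candidates (which
makes the herd size stationary), a 27-month generation interval with +/-3
months of birth jitter, and population defaults of 40 sires / 400 dams.
Selection acts on a single index: each candidate's true breeding value is
the dot product of its causal dosages (default 50 loci) with N(0, 1)
effects, and the ranking criterion correlates with it at `index_accuracy`.
Accuracy 0 is exact drift — the ranking is pure noise and the genotype
path is the same meiosis engine the gene-drop uses. Genotyping is assigned
to the most recent five generations by default, with weights growing
quadratically in generation ("left-skewed" sampling: counts per birth year
rise toward the present, matching how array platforms enter a program);
a uniform scheme is available. A `terminal_cross` helper produces a
commercial crossbred cohort with sire-side-only pedigree records, whose
maternal gametes a gene-drop draws from phantom founders.

What the generator does *not* emulate: overlapping generations (approximated
by birth-month jitter), founder linkage disequilibrium, multi-trait indices
(collapsed into `index_accuracy`), BLUP evaluation, and culling on
realised phenotypes. Passing tests therefore show the pipeline's behaviour
under pedigree-structured drift and single-index truncation selection, not
under every feature of commercial data.

## Benchmark problem sizes

The replicated drift-null benchmark (also recomputed by
`scripts/acceptance.py`) uses a 10-generation pedigree of 25 founder sires
and 120 founder dams (~9,300 animals), 3,000 genotyped animals sampled
left-skewed from the last five generations, and per replicate a
5,000-founder pool with 25,200 sites reduced to a 20,000-SNP array — five
replicates, pooled error rate = 100 x significant / tested. The pool
carries more sites than the array because the MAF screen must leave at
least 20,000 eligible sites. The power benchmark uses deliberately strong
selection — top 5% of sires at accuracy 0.9, 50 causal loci, 2,500
genotyped across all 10 generations — because weak selection observed
through a short sampling window is genuinely hard for any temporal method
at n ~ 1,500; enrichment of significant SNPs within 1 Mb of causal loci is
then tested by Fisher's exact test per replicate.

## Known limitations

* Founder linkage equilibrium (above) — the null bound is per-SNP, not a
  statement about clustered hits.
* The bivariate fit is dense O(n^3) per iteration and is intended for up
  to a few thousand animals; the univariate path scales to tens of
  thousands via the one-time eigendecomposition.
* The scan keeps the candidate SNP in the GRM (no leave-one-chromosome-out),
  matching the cited mixed-model GWAS behaviour; proximal contamination
  slightly deflates effect sizes but does not inflate the null.
* `af_change_per_year` is a descriptive OLS slope of dosage/2 on birth
  year; unlike the scan it is not adjusted for relatedness.
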