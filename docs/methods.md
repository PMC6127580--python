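# Methods

## The models

All three estimators are animal models: mixed models in which every pedigree
member carries an additive-genetic effect (breeding value) whose covariance
is proportional to Wright's numerator relationship matrix **A**.

**Linear animal model** (`LinearAnimalModel`). For a continuous trait,

    y = X beta + Z alpha + e,
    alpha | A, sa2 ~ N(0, A sa2),   e ~ N(0, I se2),

with flat priors on the fixed effects `beta` and on both variances (the
variance conditionals are scaled inverse-chi-squares with prior df -2 and
zero scale, i.e. the improper flat-on-variance limit). Heritability is
`h2 = sa2 / (sa2 + se2)`.

**Threshold (liability) model** (`ThresholdAnimalModel`). An ordinal score
with K categories is modelled through a latent Gaussian liability `U`
following the same linear animal model; fixed thresholds
`-inf = t0 < t1 < ... < tK = +inf` cut `U` into the observed categories,

    P(y = j | eta, t) = Phi((t_j - eta)/se) - Phi((t_{j-1} - eta)/se).

Location and scale of the liability are not identified by ordinal data, so
two constraints are required.  This package supports two identification
schemes:

* **Fixed thresholds (default, K >= 3).** All thresholds are fixed at the
  probit quantiles of the observed category frequencies, shifted so t1 = 0,
  and the residual variance se2 is estimated.  This is the scheme of the
  THRGIBBS1F90 family.  Because the threshold spacing pins the liability
  scale, the flat priors stay proper and the sampler is stable.
* **Sampled thresholds** (`sample_thresholds=True`). The Albert-Chib scheme:
  se2 = 1, t1 = 0, and interior thresholds drawn from their uniform full
  conditionals `U(max U in category j, min U in category j+1)`.  We found
  this scheme to drift upward in scale on synthetic 5-category data (h2
  biased high by ~0.1-0.2), degenerating into a runaway whenever the
  fixed-effect classes can nearly separate the categories: joint expansion of
  the fixed effects, thresholds and liabilities leaves the truncated-data
  likelihood unchanged, and fully flat priors put no cost on that ridge.  The
  scheme is retained for comparison but is not the default.

For binary traits only t1 = 0 is available, so se2 = 1 is always fixed.
Liability heritability is reported as `sa2/(sa2+se2)` (equal to
`sa2/(sa2+1)` under the Albert-Chib scheme).

**Bivariate linear-threshold model** (`BivariateAnimalModel`). One ordinal
(K >= 3) and one continuous trait fitted jointly:

    a | G0, A ~ N(0, G0 (x) A),    e | R0 ~ N(0, R0 (x) I),

with G0 the 2x2 additive-genetic and R0 the 2x2 residual covariance matrix.
The ordinal trait's thresholds are fixed as in the single-trait default, so
the full R0 — including the liability residual variance r11 — is estimable;
both covariance matrices get flat (improper-limit) inverse-Wishart
conditionals, df = N - 3 and n - 3 respectively, with a 1e-6 identity scale
added so the Bartlett decomposition stays defined when a cross-product
matrix is nearly singular.  (The common alternative — constrain
R0[cat,cat] = 1 by rescaling the liability-scale state after every residual
draw — proved numerically fragile here: the rescale injects multiplicative
noise into the weakly identified liability scale and the chain performs an
unbounded random walk.  A minimal-proper inverse-Wishart prior, df = +3, was
also rejected: it shrinks G0 by a factor ~N/(N+3) per cycle whenever the
data momentarily decouple, which turns the near-zero-variance region into an
absorbing trap.)  The genetic correlation is
`rg = G0[0,1]/sqrt(G0[0,0] G0[1,1])` and the ordinal trait's heritability
`g11/(g11 + r11)`, which is invariant to the liability scale.

## Gibbs sampling

All samplers are single-site Gibbs with residual updating, compiled with
numba: the residual vector `e = y - X beta - Z alpha` is kept current, so
each scalar (or, for bivariate breeding values, 2x1) conditional costs only
the records carrying that effect plus one sparse row of A-inverse.  The
mixed-model equations are never formed; an exact blocked solve
(`solve_mme`) exists for validating the location conditionals on toy data.
Liabilities are drawn from truncated normals by inverse CDF with
complementary-tail evaluation (accurate for intervals far in a tail);
variance components from scaled inverse-chi-square (single trait) or
inverse-Wishart via Bartlett (two traits) conditionals.  Chains are
bit-reproducible given the seed.

A-inverse is assembled directly by Henderson's rules with inbreeding:
Mendelian-sampling variances `d_i = 0.5 - 0.25 (F_s + F_d)` (terms dropped
for unknown parents, which are treated as unrelated non-inbred founders),
with F computed by the Meuwissen-Luo algorithm — O(N * pedigree depth)
without forming the dense A.

Fixed effects use full-rank treatment coding: a global intercept plus all
levels but the first of every factor.  With flat priors a rank-deficient
incidence matrix would leave individual levels without a proper posterior.
Contemporary groups are farm x birth-year x sex; each animal has at most
one record per trait, so no permanent-environment effect is fitted.  In the
bivariate analysis only animals with both traits observed enter (no
cross-trait missing-data augmentation).

## Chain defaults and diagnostics

Production defaults mirror a field-scale analysis: 2,000,000 cycles,
1,000,000 burn-in, thinning 250 — 4,000 retained draws.  The estimator
defaults (20,000 / 10,000 / 10) are working sizes for the synthetic data in
this repository; the tests and the acceptance script use 12,000-60,000
cycles depending on the check, sizes at which the recovery results below are
stable across seeds.

Diagnostics follow the usual post-Gibbs toolkit:

* **MCE** — `sqrt(sample variance / n draws)`, the Monte Carlo standard
  error of the posterior mean; the report flags when adding the MCE to the
  mean leaves its second decimal unchanged.
* **Geweke Z** — means of the first 10% and last 50% of the chain compared
  with spectral variances at frequency zero estimated by 20 non-overlapping
  batch means; two-sided p from the standard normal.
* **Credible intervals** — equal-tail 95% by default (the level is
  configurable); HPD available as an option.

Model comparison: DIC = Dbar + pD with pD = Dbar - D(theta_bar), computed on
the observable scale for both models (Gaussian density on the scores for the
linear model, probit category probabilities for the threshold model) so the
two are comparable; the deviance at the posterior mean uses the posterior
means of the location effects, variances and thresholds.  The Bayes factor
uses the harmonic-mean estimator of each marginal likelihood, stabilized by
log-sum-exp.  The harmonic mean is simple but high-variance and biased
upward when the prior is much more diffuse than the posterior, so DIC is the
primary criterion and the BF is reported with its verdict string only.

## Synthetic data

The generator emulates a small goat carcass study: 93 founders plus four
generations of 175 (793 animals), 385 recorded in the last three cohorts;
body condition score (5 categories) and rib-eye marbling (6 categories)
generated from the liability model, and five continuous anchors (rib-eye
area, sternal fat thickness, hip height, leg perimeter, body weight) with
heritabilities 0.13/0.09/0.28/0.24/0.32/0.41/0.54 and the published
phenotypic variances; genetic correlations between score traits and anchors
follow the published pattern (e.g. marbling-hip height 0.88,
marbling-sternal fat 0.58), assembled into a correlation matrix and
eigenvalue-clipped to the nearest positive-definite matrix when needed.
Trait means for the anchors (8 cm^2, 2.5 mm, 70 cm, 30 cm, 45 kg) are
realistic values for adult meat goats; they only shift intercepts.

Breeding values are gene-dropped: founders ~ N(0, G0), descendants take the
parent average plus a Mendelian deviate with variance
`(0.5 - 0.25 (F_s + F_d)) G0`, so realized covariances follow G0 (x) A
including inbreeding (sires and dams are drawn from the previous generation;
full-sib matings are allowed, selfing is impossible).  Fixed-effect levels
(CG from farm x year x sex, collection year, age class, animal category) are
assigned at random with level effects evenly spaced across +-0.5 residual
SD — estimable but not dominant.  Ordinal traits threshold the liability
(residual variance 1) at configured cutpoints; a configuration that leaves a
category empty is resampled up to 10 times and then rejected.

What the generator does **not** emulate: real contemporary-group imbalance,
age/parity structure correlated with the traits, selection (records missing
not at random), measurement error in the ultrasound scores beyond the
liability residual, or maternal effects.  Passing recovery tests therefore
demonstrates correctness of the samplers under the assumed model, not
robustness to these violations.

## Numerical choices and degenerate inputs

* Truncated-normal draws are clamped into their interval after the inverse
  CDF (guards the last ulp in extreme tails).
* Variance draws have a 1e-12 floor; a non-finite sampler state aborts with
  the cycle index.
* Thresholds passed or estimated must be strictly increasing; an unobserved
  category is an error instructing the user to merge categories.
* `(n_cycles - burn_in)` must be divisible by `thin`; the retained count is
  exact.
* Geweke on a constant window raises (zero spectral variance) rather than
  returning NaN.
* The equal-tail interval uses linear-interpolation percentiles
  (`numpy.percentile` defaults).

## Known limitations

* Single-site Gibbs mixes slowly for the genetic/residual partition of the
  correlation in the bivariate model; the posterior mean of `rg` needs
  ~60,000 cycles at n = 800 for stable recovery, and longer chains are
  advisable for real analyses (the production default is 2,000,000).
* The Albert-Chib threshold scheme is exposed but can be unstable (see
  above); results obtained with it should be checked against the
  fixed-threshold default.
* The harmonic-mean marginal likelihood is unreliable when prior and
  posterior differ greatly; treat BF values as directional only.
* No multi-chain (Gelman-Rubin) diagnostics, genetic groups, maternal or
  permanent-environment effects, or >2-trait models.
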