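# pedgibbs

Bayesian estimation of genetic parameters for pedigreed populations via
Gibbs sampling: single-trait **linear** and **threshold (liability)** animal
models and a **bivariate linear–threshold** model, with pedigree
relationship matrices, MCMC diagnostics (Geweke, Monte Carlo error),
posterior summaries, and DIC / Bayes-factor model comparison.  A synthetic
data generator emulating a small goat carcass study (793-animal pedigree,
385 recorded animals, ordinal body-condition and marbling scores plus
continuous carcass anchors) makes the whole pipeline testable without any
external data.

The package is aimed at quantitative geneticists and breeders who analyse
categorical carcass or fitness traits — where linear mixed models are
misspecified — and want Bayesian liability-scale heritabilities and genetic
correlations with honest uncertainty.

## The model

The animal model, `y = Xβ + Zα + e` with `α | A, σ²ₐ ~ N(0, A σ²ₐ)`, links
each record to fixed environmental classes (contemporary group = farm ×
birth year × sex, collection year, age class, animal category) and to the
animal's additive genetic value, whose covariance is Wright's numerator
relationship matrix **A**.  For an ordinal score with K categories the model
acts on a latent liability `U` cut by thresholds:
`P(y=j) = Φ((tⱼ−η)/σₑ) − Φ(tⱼ₋₁−η)/σₑ)`.  Heritability is
`h² = σ²ₐ/(σ²ₐ+σ²ₑ)`; for two traits the genetic correlation is
`r_g = G₀[1,2]/√(G₀[1,1]·G₀[2,2])`.  All models are fitted by single-site
Gibbs sampling (numba-compiled; bit-reproducible given a seed) with flat
priors on fixed effects and variance components; identification of the
liability scale is via fixed probit-quantile thresholds (residual variance
estimated), see `docs/methods.md`.

## Worked example

```python
import pedgibbs as pg

# a full synthetic study: pedigree (793), records (385), true breeding values
ped, records, bvs, G0 = pg.simulate_study(seed=7)

thr = pg.ThresholdAnimalModel(n_cycles=20_000, burn_in=10_000, thin=10,
                              seed=0).fit(records, ped, "bcs")
lin = pg.LinearAnimalModel(n_cycles=20_000, burn_in=10_000, thin=10,
                           seed=0).fit(records, ped, "bcs")
print(f"h2 (threshold) = {thr.h2_mean_:.2f}")
print(f"DIC threshold  = {thr.dic_:.1f}")
print(f"DIC linear     = {lin.dic_:.1f}")
bf = pg.bayes_factor(lin.loglik_draws_, thr.loglik_draws_)
print(f"BF linear/threshold = {bf.bf:.2e}  ({bf.verdict})")
print(pg.posterior_report(thr.samples_).round(3))
```

prints:

```
h2 (threshold) = 0.09
DIC threshold  = 1123.8
DIC linear     = 1204.2
BF linear/threshold = 3.79e-16  (denominator model preferred)
              mean    median  ci_lower  ci_upper    mce  geweke_z  geweke_p     n mce_stable
sigma_a2  0.067413  0.055693  0.010491  0.183842  0.001     0.096  0.923804  1000       True
sigma_e2  0.679659  0.671845  0.525278  0.858216  0.003     1.641  0.100746  1000       True
h2        0.089375  0.074598  0.014238  0.231031  0.002     0.115  0.908828  1000       True
```

The threshold model fits the 5-category body-condition score better than
the linear model on both criteria (lower DIC; BF far below 1 with the
threshold model as denominator), and the liability-scale heritability
(0.09, 95% CI 0.01–0.23) is low — the qualitative picture expected for
subjectively scored carcass traits.  A bivariate run pairing the ordinal trait with a
genetically correlated continuous anchor
(`pg.BivariateAnimalModel(...).fit(records, ped, ("mre", "hh"))`) typically
raises the categorical trait's h² by recovering genetic variance that the
single-trait analysis leaves in the residual.

The same pipeline is scriptable from the shell:

```bash
pedgibbs simulate --out sim --seed 7
pedgibbs fit --model threshold --trait bcs --ordinal bcs=5 --ordinal mre=6 \
    --pedigree sim/pedigree.txt --records sim/records.csv \
    --cycles 20000 --burn-in 10000 --thin 10 --out run
pedgibbs compare --trait bcs --ordinal bcs=5 --ordinal mre=6 \
    --pedigree sim/pedigree.txt --records sim/records.csv \
    --cycles 20000 --burn-in 10000 --thin 10 --out cmp
pedgibbs report run/chain.csv
```

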