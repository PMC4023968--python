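# nichemod

Hierarchical Bayesian unimodal species response models that explain niche
differences among species by their traits.

Community ecologists routinely ask why species occupy different parts of an
environmental gradient: is a species' thermal optimum, niche breadth, or
peak occurrence probability predictable from measurable traits such as
body size or the presence of flagella? `nichemod` answers this with the
**trait-modulated Gaussian logistic model** for presence–absence data. For
site *i* and species *j*,

```
y_ij ~ Bernoulli(p_ij)
logit p_ij = a_j − (x_i − opt_j)² / (2·tol_j²) + ε_i
```

a bell-shaped response curve with optimum `opt_j`, tolerance `tol_j`, and
maximum coefficient `a_j` (`p_max = expit(a_j)`), plus a Gaussian random
site effect `ε_i`. Each niche parameter is then regressed on K species
traits,

```
opt_j = μ_opt + Σ_k β_opt,k · z_jk + e_j,        e_j ~ N(0, σ²_opt)
```

(and likewise for `log tol_j` and `a_j`), with **spike-and-slab** priors
`β ~ (1−γ)·δ₀ + γ·DoubleExp(λ)`, `γ ~ Bernoulli(½)` performing exact
Bayesian variable selection over traits. The gradient `x` can be one
measured variable or a sparse unit-norm **latent combination**
`x_i = Σ_l c_l e_il` of all environmental variables, selected by the same
machinery. The package provides:

* `data_io` — CSV readers/writers, validation, log transforms,
  standardization, simple imputation, rare-species filtering;
* `glm_init` — per-species quadratic logistic GLM starting values with the
  closed-form niche reparametrization and absence augmentation for
  truncated curves;
* `inference` — the joint posterior and a bespoke random-walk-within-Gibbs
  sampler with exact (γ, β) conditional updates;
* `latent_env` — the latent-gradient extension with identifiability
  (unit norm + anchored sign) handled in-sampler;
* `diagnostics` — DIC (both p_D estimators), percentage of
  niche-parameter variance explained by traits, split-R̂/ESS, inclusion
  probabilities;
* `synthetic` — the generative model as a first-class simulator;
* `downstream` — response-curve prediction, optimum-sign species grouping,
  and between-group trait tests (Wilcoxon / chi-square);
* a `nichemod` command-line interface wrapping all of the above.

## Worked example

Simulate a 200-lake, 30-species community in which the first of four
traits shifts species optima (β = 1.5), fit the model with and without
traits, and ask which traits matter:

```python
import numpy as np
import nichemod as nm
from nichemod.diagnostics import (compute_dic, inclusion_probabilities,
                                  variance_explained)
from nichemod.inference import McmcOptions, fit, fit_without_traits

cfg = nm.SyntheticConfig(n=200, m=30, k_continuous=2, k_binary=2,
                         beta_opt=(1.5, 0.0, 0.0, 0.0),
                         sigma_opt=0.5, sigma_site=0.5, seed=1)
occ, env, traits, truth = nm.simulate_community(cfg)
x = env.values[:, 0]

inits = nm.initial_values(occ, x, traits)          # augmented GLM + OLS
opts = McmcOptions(n_iter=4000, n_chains=3, seed=17)
draws = fit(occ, x, traits, opts, inits)

print(inclusion_probabilities(draws).query("target == 'opt'"))
b1 = draws.stacked("beta")[:, 0, 0]
print(f"beta_opt[trait_0]: mean {b1.mean():.3f}")
ref = fit_without_traits(occ, x, McmcOptions(n_iter=4000, n_chains=3,
                                             seed=18))
ve = variance_explained(draws, ref)
print(f"optimum variance explained by traits: {ve.fraction_pct['opt']:.1f}%")
print(compute_dic(draws))
```

Output:

```
target coefficient  probability
   opt     trait_0     1.000000
   opt     trait_1     0.201000
   opt     trait_2     0.136167
   opt     trait_3     0.315667
beta_opt[trait_0]: mean 1.342
optimum variance explained by traits: 93.8%
Dbar=6363.48 Dhat=6185.62 pD=177.86/274.31 DIC=6541.34/6637.79
```

The active trait is selected in every posterior draw while the three null
traits stay mostly excluded; its slope estimate (1.34) sits close to the
generating 1.5; and the with/without-traits comparison attributes most of
the optimum variance to traits (the generating values imply
β²/(β²+σ²_opt) = 90%). The DIC line shows posterior mean deviance, deviance
at the posterior mean, both effective-parameter estimates
(classic / half-variance), and the two corresponding DIC values.

A full latent-gradient analysis of a case-study-shaped community from the
shell (the long chain is the production default for the slowly mixing
latent mode):

```
nichemod simulate --preset --seed 1 --out data/
nichemod fit --occurrence data/occurrence.csv --env data/environment.csv \
             --traits data/traits.csv --latent --iters 100000 --chains 3 \
             --seed 17 --out run1/
nichemod diagnose run1/
nichemod groups run1/ --traits data/traits.csv
```

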