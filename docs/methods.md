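# Methods

## Model

`nichemod` fits unimodal (Gaussian logistic) species response curves to a
binary sites × species table **Y**, with the niche parameters of every
species linearly modulated by species traits. For site *i* and species *j*,

    y_ij ~ Bernoulli(p_ij)
    logit p_ij = a_j − (x_i − opt_j)² / (2 tol_j²) + ε_i
    ε_i ~ N(0, σ²_site)

where `opt_j` is the niche optimum (gradient value of maximal occurrence
probability), `tol_j > 0` the tolerance (niche width, in gradient units),
`a_j` the logit of the occurrence probability at the optimum
(`p_max = expit(a)`), and `ε_i` a random site effect absorbing residual
between-site correlation. The trait submodels, for trait matrix
**Z** (m × K, standardized columns), are

    opt_j     = μ_opt + Σ_k β_opt,k z_jk + e_j,   e_j ~ N(0, σ²_opt)
    log tol_j = μ_tol + Σ_k β_tol,k z_jk + f_j,   f_j ~ N(0, σ²_tol)
    a_j       = μ_a   + Σ_k β_a,k   z_jk + g_j,   g_j ~ N(0, σ²_a)

**Tolerance scale.** The literal submodel for tolerance is linear in
`tol_j` itself, which does not keep tolerances positive and destabilizes
the sampler when a species' curve flattens. We therefore place the
submodel on `log tol_j`; the reported residual variance for the tolerance
is on that log scale. A strict linear mode (`tol_scale='identity'`) is
provided for fidelity checks; it rejects non-positive tolerances but its
intercept/variance updates ignore the resulting truncation constant, so it
is an approximation and not the default.

## Priors and variable selection

Intercepts get Uniform(−100, 100); all standard deviations get
Uniform(0, 100) (bounds configurable; everything in this package is
parameterized by variances, never precisions). Trait slopes get the
spike-and-slab mixture

    β ~ (1 − γ) δ₀ + γ DoubleExp(λ),   γ ~ Bernoulli(1/2)

with `DoubleExp(λ)` density `(λ/2)·exp(−λ|β|)` and δ₀ a point mass at
zero, so an excluded slope is exactly zero, not merely shrunk. The slab
rate λ, unspecified in the hierarchy we adopt, gets a Gamma(1, 1)
hyperprior with an exact conditional update (a fixed-λ option exists). A
comparison mode replaces the mixture by β ~ N(0, σ²_β) with σ_β uniform
per submodel.

## Sampler

The sampler is a bespoke random-walk-within-Gibbs scheme:

1. **Species parameters** (`opt`, `log tol`, `a`): vectorized random-walk
   Metropolis — one proposal per species per block, all species accepted or
   rejected independently in one matrix operation.
2. **Site effects** ε: same scheme across sites.
3. **Intercepts** μ: exact truncated-normal conditional draws.
4. **(γ, β) pairs**: exact joint conditionals. Integrating the Laplace
   slab against the Gaussian likelihood of the partial residuals gives the
   marginal inclusion odds in closed form (two `log Φ` terms); given
   inclusion, β follows a two-piece truncated normal that is sampled by
   inverse CDF. No tuning, perfect spike/slab mixing, and exact zeros in
   every excluded draw.
5. **Variances**: truncated inverse-gamma conditionals induced by the
   uniform-on-sd priors (sampled through the precision parameterization).
6. **Slab rate(s)** λ: conjugate Gamma updates over the active slopes.

Proposal scales adapt toward ~30% acceptance every 50 iterations during
burn-in only and are frozen afterwards, so kept draws form a Markov chain.
Deviance, −2 Σ log Bernoulli(y|p), is recorded at every kept draw.
Truncated normal and truncated inverse-gamma draws use `ndtri`/`gammaincinv`
inverse-CDF sampling with far-tail handling, which is both deterministic
under the seed and fast enough for the inner loop.

Defaults follow common practice for this model class: 10,000 iterations,
first half discarded as burn-in, three chains (raised to 100,000 iterations
for the latent-gradient mode, whose joint posterior mixes slowly). The
validation suite and the acceptance script use deliberately smaller problem
sizes and iteration counts, chosen so each check has enough Monte-Carlo
resolution for its stated tolerance; the sizes appear in the tests
themselves.

## Latent environmental gradient

With L measured environmental variables the site score becomes
`x_i = Σ_l c_l e_il`. Because the quadratic response is invariant to
jointly rescaling weights, optima, and tolerances, the raw scale of **c**
is unidentified; we impose unit Euclidean norm (weights are normalized
whenever scores are formed) and fix the sign by keeping the weight of an
anchor variable (default: the first; fallback: the first non-zero weight)
non-negative on every draw. Because the convention is enforced draw by
draw, chains cannot wander across the sign flip and no post-hoc alignment
is needed. Raw weights carry the same spike-and-slab mixture as the trait
slopes, with their own slab rate (the natural scales of slopes and weights
differ, so tying the two rates would couple unrelated quantities). Weight
updates are random-walk Metropolis for active weights plus reversible
add/delete moves whose proposal is the slab itself, so their acceptance
ratio reduces to a likelihood ratio. Starting weights come from the first
principal axis of the species' presence-weighted environmental centroids,
which points along the direction of maximal optimum spread.

## Initialization

Starting values are built per species by logistic regression on
(1, x, x²); when the quadratic coefficient is negative the niche follows
in closed form (`opt = −b₁/2b₂`, `tol = 1/√(−2b₂)`,
`a = b₀ − b₁²/4b₂`), and these equal the direct nonlinear ML estimates.
Species with truncated curves (optimum at or beyond the sampled range)
yield non-negative curvature; augmenting with artificial absences outside
the range (default 25 per side on grids extending the range by one width
per side) restores an interior optimum. Augmentation affects only
initialization — the posterior always uses the raw data. Species that are
degenerate even after augmentation (e.g. all-absent) get a neutral
fallback (optimum 0, tolerance 1, `a` at the logit of prevalence) and are
recorded. Submodel intercepts/slopes are initialized by OLS of the niche
estimates on the traits, residual variances from the OLS residuals, and
the site-effect variance at 0.1. Perfectly separated GLMs are refit with a
tiny ridge penalty and flagged.

## Diagnostics

**DIC** is reported in both standard estimators: `p_D = D̄ − D̂` (possibly
negative; flagged, never truncated) and `p_D = Var(D)/2` with the
within-chain sample variance (n−1 denominator) averaged over chains. `D̂`
evaluates the deviance at posterior means of the natural-scale parameters;
tolerance means are taken on the log scale and back-transformed, matching
the sampling parameterization. **Variance explained** by traits for each
niche parameter is `100·(σ²_without − σ²_with)/σ²_without` from the
posterior medians of the residual variances of matched fits with and
without traits (fits are fingerprint-checked to be on identical data).
**Convergence** reporting (split-R̂, ESS) is delegated to ArviZ.
Inclusion probabilities are posterior means of the indicators.

## Data handling

CSV tables with a header row and an id column; missing cells are empty
fields or `NA`. Skewed variables flagged in the run configuration are
transformed to natural logarithms (strictly positive values required, with
the offending cell named otherwise); all columns are then centred and
scaled to sample mean 0 and standard deviation 1 (n−1 denominator — a
convention choice). Binary traits are standardized like continuous ones,
with their kind retained for downstream tests. Missing cells are imputed
deterministically before standardization: column means for continuous
variables (geometric means for log-flagged ones, i.e. the mean on the log
scale), column modes for binary ones with ties resolved to 0. This simple
single imputation keeps the pipeline deterministic; it ignores
between-variable correlation that multiple imputation would exploit.
Species present in fewer than 5% of sites are dropped by default.

## Synthetic communities

The generator draws from exactly the model above — traits (standard normal
continuous, Bernoulli(0.3 by default) binary, standardized like real
data), niche parameters from the submodels (tolerance generated on the log
scale), Gaussian site effects, Bernoulli occurrences — through the same
response-curve evaluator the sampler uses, so the two cannot drift apart.
Gradients are standard normal by default; a uniform option exercises
truncated-curve behaviour. The case-study preset mirrors the shape of a
203-lake, 60-species phytoplankton survey (11 environmental variables, 6
traits of mixed type) with a two-group niche structure driven by a binary
trait along a sparse latent gradient, and occupancy high enough that the
rare-species filter keeps all 60 species under the default seed. Synthetic
data share none of real data's messiness — no missingness mechanism,
collinear environment blocks, phylogenetic trait structure, or spatial
autocorrelation — so passing recovery tests demonstrate correctness of the
machinery, not robustness to field data pathologies.

## Numerical choices and edge cases

* Bernoulli log-likelihoods via `y·l − log(1+eˡ)` computed with
  `logaddexp`; inclusion odds in log space with `log_ndtr`.
* The likelihood cache is refreshed from scratch every 500 iterations to
  cap incremental round-off drift; a non-finite deviance aborts the run.
* Ties in `simple_impute` binary modes go to 0; ties in group
  classification go to group 2; both documented contracts.
* Wilcoxon rank-sum tests use exhaustive enumeration for tie-free groups
  of ≤6, otherwise the tie-corrected normal approximation; chi-square
  tests default to no continuity correction (both exposed).
* `McmcOptions.fix` freezes named parameter blocks — used for reduced
  models (e.g. a flat no-gradient alternative in DIC comparisons) and for
  validation against exact micro-posteriors.

## Known limitations

* Single latent axis only; no count-data likelihoods; no spline or skewed
  response shapes.
* The strict linear-tolerance mode is approximate (see above).
* DIC on hierarchical models depends on the parameterization of the focus;
  we follow the conditional-deviance convention (species-level parameters
  in focus), and negative classic p_D values do occur and are flagged.
* With few presences per species the optimum posterior is wide and the
  latent-weight posterior mixes slowly; the 100,000-iteration default for
  latent fits is there for a reason.
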