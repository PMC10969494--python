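# Methods

## The model

`carmap` fits Bayesian hierarchical models for areal (lattice or irregular
polygon) count data of the kind produced by disease registries: one count
per areal unit, a population offset, and spatially structured covariates
that may be partially missing.

The observation model for unit *i* is

    y_i | eta_i ~ Poisson(mu_i)            or      y_i | eta_i ~ NB(r, mu_i)
    log mu_i    = beta_0 + x_i' beta + log N_i + theta_i

with `N_i` the adult population (the offset makes the regression act on
rates), `x_i` the covariate row and `theta_i` an optional spatial random
effect.  The negative binomial is parameterized by its mean and the scale
`r > 0`, so `Var(y_i) = mu_i (1 + mu_i / r)`; the factor `1 + mu_i/r`
measures overdispersion and the Poisson model is the `r -> infinity` limit.

The spatial effect follows a proper conditional autoregressive (CAR) prior,

    theta | tau, rho ~ N(0, [tau (M - rho W)]^{-1}),

where `W` is the binary contiguity matrix (1 iff two units share a border),
`M = diag(m_i)` holds the neighbour counts, `tau > 0` is the field precision
and `rho in [0, 1)` the spatial autocorrelation.  Equivalently, each unit's
conditional distribution is `theta_i | theta_{-i} ~ N(rho * mean of
neighbours, 1 / (tau m_i))`.  At `rho = 1` the intrinsic (improper) variant
is obtained; the package only constructs it on explicit request and never
fits it.

### Missing data

Missing **responses** are handled by posterior prediction: units with
missing counts contribute no likelihood factor, and each MCMC iteration
draws a predictive count for them from the outcome family at the current
parameters.

Missing **covariates** are imputed inside the model:

* **Spatial (MCAR) mode.**  The K covariate fields are modelled jointly as a
  multivariate proper-CAR Gaussian Markov random field with precision
  `Lambda (x) (I - rho_c W_s)` — a K x K between-covariate precision
  `Lambda` Kronecker-coupled to a spatial factor built on `W_s`, the
  adjacency scaled by its largest eigenvalue so `rho_c in (0, 1)` guarantees
  positive definiteness.  A single shared `rho_c` governs all fields.
  Missing cells are drawn from their exact Gaussian full conditionals,
  Metropolis-corrected by the outcome likelihood of the affected unit so the
  imputations feed back into the regression coherently.
* **Linear-regression mode** (nonspatial variants).  Each partially observed
  covariate is regressed on the fully observed ones,
  `x_mis | x_obs ~ N(X_mis b, (1/tau_c) I)`, with conjugate updates for `b`
  and `tau_c`; the adjacency structure is ignored, matching the nonspatial
  outcome model it accompanies.
* **No imputation.**  By default units with incomplete covariates are
  dropped (with the graph subset accordingly).  A strict-replication flag
  (`zero_fill_missing`) instead substitutes zeros for missing raw values —
  the documented behaviour of some GLM software when handed NAs — which is
  biased and exists only for comparison.

A design note on the precision algebra: the conditional covariance of the
missing block is `[tau_c (I_mm - rho W_mm)]^{-1}`, the standard GMRF
conditional implied by reading `tau_c (I - rho W_s)` as the joint precision.
This is the only internally consistent reading of the model, and it is
verified against brute-force dense Gaussian conditioning in the test suite.

A second design note: the offset enters the log mean exactly once
(`log mu_i = log N_i + ...`).  Writing the Poisson mean as `N_i lambda_i`
*and* putting `log N_i` inside `log lambda_i` would count the population
twice; the single-offset form matches standard disease-mapping practice.

## Inference

Inference is full-Bayes MCMC (adaptive Metropolis-within-Gibbs).  The
posterior targeted is that of the complete hierarchical model — regression
coefficients, spatial effects, hyperparameters, imputed covariate cells and
predicted missing responses jointly.  Sampler moves:

| block | update |
|---|---|
| `beta` | joint random-walk Metropolis; proposal covariance adapted from the chain history (Haario-style), scale tuned to ~23% acceptance |
| `beta`/`theta` translation | propose `beta + d`, `theta - D d` (likelihood-invariant); accepted by the CAR-prior ratio. Decorrelates coefficients of spatially smooth covariates from the spatial field |
| intercept/level swap | scalar version of the same move for `beta_0` vs. the field level |
| `theta` | colour-blocked single-site Metropolis. A greedy proper colouring of the graph makes same-colour units non-adjacent, so a whole colour class updates in one vectorised step using the exact CAR full conditional as prior factor (a lattice needs 2 colours) |
| `tau`, `tau_c` | conjugate gamma Gibbs |
| `rho`, `rho_c` | Metropolis on the logit scale; `log det(M - rho W)` is evaluated from the precomputed generalized eigenvalues of `(W, M)` (and eigenvalues of `W_s` for `rho_c`), so no factorization is needed per step |
| `r` | Metropolis on `log r` with a gamma prior on `r` |
| missing covariate cells | per-unit blocks drawn from their exact GMRF/linear-regression full conditional, Metropolis-corrected by the unit's outcome likelihood (pure Gibbs where the response is missing) |
| missing responses | direct draw from the outcome family |

All proposal scales adapt by Robbins–Monro only during burn-in and are
frozen afterwards, preserving detailed balance for the retained draws.

**Initialization.**  `beta` starts at the Poisson IRLS solution (which also
seeds the proposal covariance with the inverse Fisher information);
`theta` starts at the clipped GLM log-residuals and `r` at the residual
moment estimate.  Starting `theta` at zero instead leaves an overdispersed
spatial NB fit in a local mode where a small `r` absorbs all extra-Poisson
variation and the spatial field never grows; residual initialization removes
this trap without affecting the stationary distribution.

**Identifiability.**  The intercept trades off against the mean level of a
single CAR field draw; with `rho` near 1 the field's level is nearly flat in
the prior.  The translation/swap moves sample this ridge efficiently, and if
`rho` drifts above 0.99 the field is recentred to sum to zero with the mean
absorbed into the intercept.  Consequently the *covariate* coefficients are
well identified, while the intercept is only identified up to the level of
the particular field realization — parameter-recovery checks therefore score
coverage on the covariate coefficients.

**Priors (defaults, all configurable).**  `beta ~ N(0, 100^2)` i.i.d.;
`tau, tau_c ~ Gamma(1, 5e-5)` (shape, rate — essentially flat on the scales
that matter here); `rho, rho_c ~ Uniform(0, 1)`; `r ~ Gamma(1, 0.01)`;
covariate-field intercepts diffuse normal; `Lambda ~ Wishart(I, K + 1)`.
No claim is made that these match the priors of any particular published
analysis; posterior point estimates from moderate-sized data are insensitive
to them.

**Defaults.**  4 chains of 20,000 iterations, 10,000 burn-in, thinning 5.
Convergence is summarized by split-R-hat and effective sample size (via
`arviz`); `fit` warns when any monitored R-hat exceeds 1.05.  The test suite
and the acceptance script use shorter single chains (1,500–4,500 iterations)
on reduced lattices — problem sizes chosen so the full studies run at desk
scale; the same code paths run at any size.

## Model comparison

For each fitted model the per-draw, per-observed-unit log likelihood is
stored, from which:

* `DIC = -2 log p(y | theta_hat) + 2 p_DIC`, with
  `p_DIC = 2 [log p(y|theta_hat) - mean_s log p(y|theta_s)]` and the plug-in
  `theta_hat` taken as the posterior mean of every quantity entering the
  likelihood (coefficients, spatial effects, `r`, imputed covariates).
* `WAIC = -2 lppd + 2 p_WAIC`, `lppd = sum_i log mean_s p(y_i | theta_s)`
  (log-sum-exp stabilized), `p_WAIC = sum_i var_s log p(y_i | theta_s)`.
* `RMSE` and `RSE` between observed counts and posterior-mean fitted counts;
  `RSE = sum (y - yhat)^2 / sum (y - ybar)^2`, the relative squared error
  for which the mean-only predictor scores 1.  (RSE has no universal
  definition; this is the standard one consistent with good fits scoring
  far below 1.  Fitted values are posterior means, not predictive medians.)

DIC gaps are annotated qualitatively: more than 10 units is an *important*
difference, 3–10 *substantial*, under 3 *negligible*.

## Spatial diagnostics

Global Moran's I with binary weights,
`I = (N/S0) sum_ij w_ij z_i z_j / sum_i z_i^2`, with a one-sided Monte-Carlo
permutation p-value (observed statistic included in the reference set;
default 9,999 permutations).  Row-standardized weights are available as an
option.  Polygon contiguity supports both queen (any shared boundary point)
and rook (shared boundary of positive length) rules, queen by default —
the common disease-mapping choice and the more robust one to sliver
geometries.  Isolated units are rejected for spatial modelling (callers may
drop them), mirroring registry practice of excluding units without credible
adjacency; disconnected graphs are allowed for diagnostics but require an
explicit flag to fit (the CAR precision is then block diagonal).

## Synthetic data

The generator produces datasets with the statistical structure the model
assumes, at the scale of a state-wide zip-code registry analysis:

* 30 x 30 rook lattice (900 units, close to the ~890 of the motivating
  analysis);
* 11 covariates named for the roles in that analysis (demographics, social
  deprivation index, PM2.5, smoking/binge-drinking/obesity indices, poverty),
  drawn jointly from the multivariate CAR with shared `rho_c = 0.97`,
  exchangeable cross-covariate correlation 0.3, and `covariate_tau = 1.751`
  chosen so each field has ~unit marginal variance on the default lattice;
* regression coefficients defaulting to the reported posterior-mean
  magnitudes for those covariate roles (standardized scale);
* `theta` from the proper CAR with `rho = 0.97`, `tau = 1.066` (marginal
  variance ~0.47);
* populations `N_i ~ LogNormal(log 4000, 0.39)`, intercept `beta0 = -5.28`
  on the per-person log-rate scale;
* MCAR missingness: 7% of responses, and 0.7/0.7/0.7/1.2% of the smoking,
  binge-drinking, obesity and poverty covariates.

These defaults were calibrated once so that the generated counts reproduce
the documented summary statistics of the motivating registry data — mean
count ~33, overdispersion index ~53, Moran's I ~0.26 — and then frozen; no
generator parameter was adjusted against any model-fit or test outcome.
`scripts/acceptance.py` recomputes the descriptive panel (mean,
overdispersion index, Moran's I with permutation p-value) on a fresh draw
each run; seed-to-seed variation in these statistics is substantial (the
overdispersion index in particular has a heavy right tail).

What the generator does **not** emulate: the real covariates' marginal
distributions (SDI scores on 1–100, percentages with floors and ceilings),
non-lattice adjacency irregularity, missing-not-at-random mechanisms, and
registry artefacts such as suppressed small counts.  Passing tests therefore
demonstrate that the machinery recovers the truth *under the model's own
assumptions* at realistic size and signal strength — not that those
assumptions hold for any particular registry.

The missingness mechanism is MCAR (independent Bernoulli masks).  The
imputation model's validity under the fitted joint model requires
missing-at-random; MCAR is the simplest mechanism consistent with it and is
documented as an assumption.

## Numerical choices

* Adjacency eigenvalue scaling uses a deterministic Lanczos start vector;
  the default random start would make the last bits of `lambda_max` (and
  hence entire MCMC trajectories) depend on global RNG state.
* Log-determinants of CAR precisions come from one dense symmetric
  eigendecomposition per graph, cached on the graph object; at the default
  N = 900 this costs well under a second once.
* `car_logpdf` uses a sparse LU factorization for its log-determinant.
* All data files are written at 17-significant-digit precision and parsed
  with round-trip float handling, so a dataset survives a CSV round trip
  bit for bit.
* Chains are seeded through `numpy.random.SeedSequence.spawn`, one stream
  per chain; identical seed and configuration reproduce every draw exactly
  (bit-for-bit on a fixed single-threaded BLAS; threaded BLAS reductions can
  perturb last bits).
* Covariates are standardized (observed-cell mean/SD) before fitting by
  default; summaries report both standardized and back-transformed raw-scale
  coefficients.

## Known limitations

* MCMC, not a deterministic approximation: results carry Monte-Carlo error,
  and the reported ESS/R-hat should be checked before trusting intervals.
* The MCAR imputation assumes one shared spatial autocorrelation for all
  covariate fields; fields with very different ranges would be better served
  by per-covariate `rho_c`.
* The intrinsic CAR (`rho = 1`), the BYM additive unstructured effect and
  the Leroux convex-combination prior are not offered.
* Binary or count-valued covariates are imputed as Gaussian.
* No cross-validated criteria (LOO/PSIS); DIC and WAIC only.
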