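# carmap

Bayesian disease mapping for areal count data: Poisson and negative-binomial
spatial regression with proper conditional-autoregressive (CAR) random
effects, **simultaneous GMRF imputation of missing spatially correlated
covariates**, posterior prediction of missing responses, and
DIC/WAIC/RMSE/RSE model comparison.

The package is aimed at epidemiologists and biostatisticians analysing
registry counts aggregated to small areal units (zip codes, tracts, lattice
cells) where three complications typically coincide: counts are
overdispersed, neighbouring units are correlated, and covariates assembled
from surveys carry scattered missing values.  Rather than dropping
incomplete units or plugging in ad-hoc imputations, `carmap` treats missing
covariates as latent Gaussian Markov random fields and samples them jointly
with the regression — a single coherent posterior for everything.

## The model

For areal unit *i* with count `y_i`, population `N_i`, covariates `x_i` and
spatial effect `theta_i`:

    y_i | eta_i ~ Poisson(mu_i)   or   NB(r, mu_i),   Var = mu (1 + mu/r)
    log mu_i    = beta_0 + x_i' beta + log N_i + theta_i
    theta       ~ N(0, [tau (M - rho W)]^{-1})              (proper CAR)

`W` is the binary contiguity matrix, `M` the diagonal of neighbour counts,
`rho in [0, 1)` the spatial autocorrelation.  Missing covariates follow a
multivariate proper-CAR prior with precision `Lambda (x) (I - rho_c W_s)`
(`W_s` = adjacency scaled by its largest eigenvalue) and are imputed from
their exact Gaussian full conditionals inside the MCMC; nonspatial model
variants impute by Bayesian linear regression on the fully observed
covariates instead.  Missing responses are predicted from the posterior
predictive distribution.  See `docs/methods.md` for the complete account.

## Worked example

Generate a synthetic registry-like dataset (15 x 15 lattice, four covariates
with sub-2% missingness, 7% missing responses), inspect it, and fit the
spatial Poisson model with joint covariate imputation:

```python
from carmap import synthetic, inference, selection
from carmap.report import data_summary

ds = synthetic.make_dataset(synthetic.small_config(), seed=7)
panel = data_summary(ds.table, ds.graph, n_perm=999, seed=7)
# units=225 observed=208 mean=29.82 od=26.1 moran=0.236 (p=0.001)

spec = inference.ModelSpec(family="poisson", spatial=True, imputation="mcar")
cfg  = inference.FitConfig(n_iter=4000, n_burnin=1500, thin=2, n_chains=2, seed=1)
s    = inference.fit(ds.table, ds.graph, spec, cfg)
print(inference.posterior_summary(s).head(5).round(3))
```

```
  parameter   mean    sd   2.5%  97.5%  credible
(intercept) -5.266 0.172 -5.632 -4.898      True
        sdi  0.265 0.059  0.144  0.382      True
       pm25  0.002 0.063 -0.118  0.126     False
    smoking  0.088 0.052 -0.017  0.191     False
    poverty -0.179 0.054 -0.277 -0.073      True
```

The data were generated with true coefficients (0.20, −0.09, 0.14, −0.08):
every truth lies inside its 95% credible interval, and a coefficient is
flagged `credible` when its interval excludes zero.  Model-fit criteria for
the comparison table come from `selection.evaluate(s)`:

```
DIC=1388.97  WAIC=1351.64  RMSE=1.78  RSE=0.0041
```

(RSE far below 1 means the fitted counts explain almost all of the
variation a mean-only predictor would leave.)  `selection.compare_models`
ranks several fitted variants by DIC and labels the gaps (>10 important,
3–10 substantial, <3 negligible).

## Command line

The same pipeline is scriptable:

```bash
carmap simulate --seed 1 --nrows 30 --ncols 30 --out study/
carmap validate study/area_table.csv study/adjacency.tsv
carmap fit study/area_table.csv study/adjacency.tsv --family poisson --imputation mcar
carmap report config.yaml     # fit all configured variants, write all tables
```

`report` reads a YAML run configuration (data paths, column roles, model
variants, chain settings) and writes the data-summary panel, per-variant
posterior-summary/fitted-count/convergence tables, and the cross-variant
comparison table, each stamped with the seed and a configuration hash.
Adjacency sources may be two-column edge lists or GeoJSON polygons (queen or
rook contiguity).

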