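# pinemort

Analysis pipeline for bark-beetle-induced ponderosa pine mortality from
individual-tree survey data.

During and after the 2012–2016 California hot drought, the western pine
beetle (*Dendroctonus brevicomis*) killed ponderosa pine (*Pinus
ponderosa*) at rates that depend jointly on broad-scale moisture stress
and on local forest structure. `pinemort` is for ecologists working with
drone- or field-derived stem maps who want to go from per-tree tables to a
hierarchical model of host mortality: it validates tree detection against
ground plots, classifies crowns from five-band reflectance, calibrates
photogrammetric heights, aggregates trees to 20 × 20-m cells, and fits a
zero-inflated binomial model with a per-site spatial Gaussian process. A
synthetic-data generator reproduces the statistical structure of every
stage so the whole chain is testable with known ground truth and no
downloads.

## The model

For cell *i* in site *j*, with *n*ᵢ host trials (live ponderosa + dead
trees) and *y*ᵢⱼ dead trees:

```
y_ij ~ 0                 with probability p
       Binom(n_i, π_i)   with probability 1 − p

logit(π_i) = β0 + β1·X_cwd,j + β2·X_propHost,i + β3·X_pipoHeight,i
           + β4·X_density,i + β5·X_ba,i
           + β6..β12 · (two-way interactions)
           + β13·X_cwd·X_propHost·X_pipoHeight
           + GP_j(x_i, y_i)
```

Covariates are centered and scaled; GP_j is an exact (dense-covariance)
exponentiated-quadratic Gaussian process over raw cell-centroid
coordinates with per-site amplitude and length-scale. Fitting is adaptive
Hamiltonian Monte Carlo with analytic gradients; convergence gates are
Rhat < 1.1 and bulk/tail ESS > 100 × chains. See `docs/methods.md` for
priors, parameterization and design choices.

## Worked example

```python
import numpy as np
from pinemort.model import fit_model, summarize_effects
from pinemort.synthetic import SyntheticConfig, generate_landscape

cfg = SyntheticConfig(n_sites=8, cells_per_site=60, grid_side_cells=9, seed=42)
landscape = generate_landscape(cfg)              # known true coefficients
fit = fit_model(landscape.model_table(), chains=2, warmup=500, draws=500, seed=7)
effects = summarize_effects(fit)
effects["true"] = np.asarray(cfg.beta)
print(effects.round(2).to_string(index=False))
```

prints (selected rows; `examples/05_fit_mortality_model.py` runs the full
script in a couple of minutes):

```
             parameter  median  ci66_lo  ci66_hi  ci95_lo  ci95_hi  sign_certain  true
          b0_intercept   -1.00    -1.08    -0.92    -1.17    -0.83          True -1.00
              b1_z_cwd    0.81     0.72     0.90     0.62     1.01          True  0.85
        b2_z_prop_host    0.64     0.59     0.69     0.54     0.75          True  0.68
      b3_z_host_height    0.23     0.13     0.32     0.05     0.41          True  0.25
b6_z_cwd:z_host_height    0.45     0.35     0.54     0.25     0.65          True  0.54
```

`median` is the posterior median effect on the log-odds of host mortality
per standard deviation of the covariate; `sign_certain` marks effects
whose 95% credible interval excludes zero — at this reduced size the
strong effects (CWD, host proportion, CWD × host height) separate cleanly
from zero. The `examples/` directory holds one short script per stage:
landscape simulation, detection benchmarking with the 5%-of-best selection
rule, crown classification, height/allometry calibration plus gridding,
and the model fit with its posterior predictive check.

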