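# Methods

## The scientific problem

Western pine beetle (*Dendroctonus brevicomis*, WPB) killed ponderosa pine
(*Pinus ponderosa*) across the Sierra Nevada during and after the 2012–2016
hot drought. Mortality rates respond both to broad-scale moisture stress
(site-level climatic water deficit, CWD) and to local forest structure and
composition (host proportion, host size, stem density, basal area), with
cross-scale interactions between the two. `pinemort` implements the
analysis chain that takes individual-tree tables (as produced by a
drone-photogrammetry workflow) through per-plot validation, spectral
classification, height/allometry calibration and 20-m gridding, to a
hierarchical model of per-cell host mortality — plus a synthetic-data
generator so that every stage can be exercised with known ground truth and
no external data.

## The mortality model

For cell *i* in site *j*, with `n_i` host trials (live ponderosa + dead
trees, dead trees assumed ponderosa) and `y_ij` dead trees:

    y_ij ~ 0                with probability p
           Binom(n_i, pi_i) with probability 1 - p

    logit(pi_i) = b0
        + b1 X_cwd,j + b2 X_propHost,i + b3 X_pipoHeight,i
        + b4 X_density,i + b5 X_ba,i
        + b6 X_cwd X_height + b7 X_cwd X_propHost
        + b8 X_cwd X_density + b9 X_cwd X_ba
        + b10 X_propHost X_height + b11 X_propHost X_density
        + b12 X_height X_ba
        + b13 X_cwd X_propHost X_height
        + GP_j(x_i, y_i)

All base covariates are centered and scaled (CWD over sites, the four
cell-level covariates pooled over eligible cells); interaction columns are
products of standardized columns and are not re-centered. `GP_j` is a
zero-mean exact Gaussian process per site over the raw (unscaled) cell
centroid coordinates with an exponentiated-quadratic kernel
`sd_j^2 exp(-d^2 / (2 ls_j^2))` and diagonal jitter `1e-8 sd_j^2`; the
covariance is dense (no low-rank approximation). The zero-inflation
probability `p` is a single global scalar, matching the mixture as written;
the GP is isotropic with one length-scale per site (hyperparameters are
per-site; sites are exchangeable only through their priors).

Cells with zero host trees are excluded from the model table: the mean
host height covariate is undefined there. This exclusion (and the
dead-trees-count-as-hosts convention for `n_i`, the host proportion and
the mean host height) is controllable via flags in `pinemort.gridding`.

## Priors

The upstream fitting machinery this model descends from uses weakly
regularizing defaults that are not printed anywhere; the priors here are
explicit stand-ins with the same character:

* intercept `b0 ~ Student-t(3, 0, 2.5)`;
* slopes `b1..b13 ~ Normal(0, 5)` — a proper, very weak prior. At the
  study's cell counts the likelihood dominates: on a ~500-cell landscape
  the MAP moves by well under 1e-3 relative to the flat-prior maximum
  (this is exactly the GLM-limit check in the test suite), so slope-prior
  sensitivity is negligible at the sizes we fit; `flat_priors=True`
  removes the beta priors entirely for anyone who wants the comparison;
* `p ~ Uniform(0, 1)` (sampled as logit p with its Jacobian);
* `gp_sd_j ~ half-Student-t(3, 0, 2.5)` (log-odds units);
* `gp_lengthscale_j ~ Inverse-Gamma(5, 4 ls0_j)` with `ls0_j` half the
  median inter-cell distance of site *j* — prior mean `ls0_j`, sharp left
  cutoff that keeps the length-scale away from the sub-cell regime where
  the correlation matrix degenerates to the identity and the latent field
  is unidentifiable from iid noise.

## Sampling

No gradient-based probabilistic-programming framework is assumed: the
posterior gradient is coded analytically and sampled with an adaptive
Hamiltonian Monte Carlo chain (leapfrog integrator; dual-averaging step
size targeting 0.85 acceptance; diagonal mass matrix re-estimated twice
during warmup; leapfrog count jittered uniformly in `[L/2, L]`, default
L = 32). The GP is whitened — the sampler works on `z ~ N(0, I)` with
`GP = sd * chol(R + 1e-8 I) z` — which removes the worst of the
funnel between `sd_j` and the latent field. The length-scale gradient uses
the forward-mode derivative of the Cholesky factor
(`dL = L Phi(L^-1 dR L^-T)`). Gradient correctness is enforced by a
finite-difference test, and the joint density by a naive non-log-space
oracle.

Convergence gates follow the study protocol: rank-normalized split-Rhat
below 1.1 and bulk/tail effective sample sizes above 100 x chains for
every monitored parameter (computed with arviz). A failed gate flags the
result `converged=False` but still returns it. MAP estimates use L-BFGS on
the same gradient.

Default problem sizes: the full design is 32 sites x 200 subsampled cells
with 4 chains x 5000 iterations (2000 warmup); the package's tests and
recovery studies run a desk-scale 8 sites x 60 cells with 2 chains x
(500 + 500), which keeps a five-seed replication within minutes on one
core while leaving the strong effects (|b| >= 0.25) clearly identified.

## The synthetic generator

`generate_landscape` is the generative inverse of the model. Defaults are
the study conditions where stated and field-plausible stand-ins elsewhere:

* 32 sites, ~225 cells each (20 x 20 m, square site blocks), CWD z-scores
  uniform on [-1.5, 1.5] — spanning a hot/dry-to-cool/wet gradient; no
  site-level CWD table is published, so the range is configurable;
* host proportion ~ Beta(2, 2); total density ~ NegBin(mean 20,
  dispersion 5) trees/cell; mean host height ~ Lognormal(ln 18 m, 0.3) —
  bracketing the field-plot means (~19 trees and 18 m mean height per
  0.04-ha plot);
* cell basal area = density x per-tree basal area at the cell's mean
  height (DBH = 2.5 cm/m x height) x a Lognormal(0, 0.25) factor. The
  multiplicative factor represents within-cell height spread: without it
  basal area would be an exact function of density and height and the
  three coefficients would be structurally confounded, which real stem
  maps are not;
* effect sizes default to the reported posterior medians (b1 = 0.85,
  b2 = 0.68, b3 = 0.25, b6 = 0.54, b8 = -0.19, b13 = 0.14, the rest
  small), b0 = -1.0 so the marginal mortality sits near the observed
  26.3%; zero inflation p = 0.08, GP amplitude 0.5 log-odds with a 40-m
  length-scale — none of these three are printed, they are the package's
  calibrated defaults;
* the GP field is drawn exactly (dense kernel + Cholesky, jitter
  escalating x10 from 1e-8 to at most 1e-4 before failing with the site
  named); all generators are pure functions of (config, seed), with
  per-site substreams spawned deterministically from the root seed.

What the generator does *not* emulate: photogrammetric height error and
its spatial structure, detection/segmentation failures feeding the cell
counts, species misclassification (all labels are exact), beetle
population dynamics, and anisotropic or non-stationary spatial
correlation. Passing recovery tests therefore demonstrate correctness of
the inference machinery under the model's own assumptions — not robustness
to the real data's failure modes.

Stem maps are homogeneous Poisson; canopy height models composite
paraboloid crowns by maximum (the stem pixel is set to the exact tree
height); crown spectra are drawn around a green-vegetation template for
live crowns and a dry/gray template for dead ones (strong NIR loss, red
gain), with small species offsets and clipping to [0, 1].

## Detection benchmarking

Detection quality is scored at the plot-summary level, never by
tree-to-tree matching: seven structure metrics (total count, count > 15 m
strict, mean/25th/75th height with linear-interpolation percentiles, mean
first- and second-neighbour distance, 2-D, no edge correction) are
compared between air and ground as Pearson r, RMSE, and median(air -
ground) so positive = overestimate. The selection rule marks, per metric,
candidates within 5% of the best correlation (multiplicative, undefined
when the best r <= 0) or within 5% of the lowest RMSE, and tallies
metrics; a metric counts once if either criterion is met (the
both-criteria reading is available by flag — the two agree on dominance
cases). Tally ties break by mean correlation, then input order. The
bundled detector is a fixed-window strict local-maxima finder with
row-major tie-breaking; the detection algorithms it stands in for are out
of scope.

## Spectral features and classification

Ten features per crown: five band means (blue, green, red, red-edge, NIR)
over pixels whose centers fall inside the crown polygon, plus NDVI, NDRE,
RGI, CI_rededge, CI_green computed *from the band means* (the
per-pixel-then-average alternative is behind a flag; which of the two the
original workflow used is not stated). Zero denominators yield missing
values, never infinities; crowns capturing no pixel centers are flagged.
The cross-validation harness is stratified k-fold (stratification
guarantees class presence in every fold; plain k-fold is not exposed) with
a pluggable classifier — L2 logistic regression by default; the boosted
logistic regression / regularized discriminant analysis used upstream meet
the same fit/predict contract via their scikit-learn analogues
(`GradientBoostingClassifier`, `QuadraticDiscriminantAnalysis`).

## Calibration

Height calibration is OLS of field height on drone height, separate for
live and dead trees, fit only on pairs with drone height > 20 m but
applied to all trees (corrected heights floored at 0). A linear form is
the minimal model consistent with the reported mean shifts (+2.8 m dead,
-0.9 m live); whether the original fit shared a slope across statuses is
unknown — separate slopes per status are fit here. Allometries are
per-species OLS of DBH on height over field trees with DBH > 6.35 cm
(minimum 3 trees, otherwise skipped with a warning); dead trees take the
host-species allometry. Basal area is the geometric `pi (DBH/2)^2`. CWD
z-scores standardize a site's CWD (mm) against a reference sample's mean
and sample (n-1) sd — in the study, 179 herbarium records spanning the
host's climatic range; the reference is an input file, not packaged.

## Numerical choices

* ZIB log-pmf: log-sum-exp on the y = 0 branch; binomial coefficients
  precomputed once per model table.
* Covariance factorization: baseline jitter 1e-8 on the correlation
  diagonal; escalation x10 up to 1e-4, then failure naming the site.
* Percentiles/quantiles: linear interpolation between order statistics
  (numpy default) everywhere — structure metrics and credible intervals.
* Half-open grid cells `[x0, x0 + 20)`; a tree exactly on the boundary
  belongs to the upper cell. Plot clipping is boundary-inclusive.
* Degenerate inputs are flagged, not silently zeroed: metrics below their
  minimum tree counts are NaN; zero-variance covariates fail
  standardization by name; singular OLS fits raise.

## Known limitations

* The sampler is plain HMC, not NUTS: trajectory lengths are jittered
  rather than adapted, so tail ESS on the GP hyperparameters can sit
  below the 100 x chains gate at desk scale; the gate is reported
  honestly and the fixed-effect inferences are stable across seeds.
* No edge correction in neighbour distances and no detection/segmentation
  error model; Table-level reproduction of the original field benchmark
  numbers requires the deposited survey data, which this package treats
  as an external input.
* `select_best` with a single candidate returns a tally equal to the
  number of defined metrics by construction — the rule is only
  informative with several candidates.
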