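# Methods

`psimap` implements a full place-susceptibility index (PSI) construction
pipeline for household-survey data of the PHIA type, together with a
synthetic-country generator that provides ground truth for every stage. This
note records the models, the defaults and why they were chosen, what the
synthetic data does and does not emulate, and the numerical choices that a
maintainer would otherwise have to reverse-engineer.

## Pipeline overview

1. **Survey preparation** (`surveyprep`). Cluster-level weighted proportions
   and weighted medians of candidate indicators, then a fixed reduction
   sequence: zero-variance filter → positive-correlation pruning →
   Kaiser-Meyer-Olkin adequacy → principal-axis factor analysis with Varimax
   rotation → one representative (highest |loading|) indicator per factor.
2. **Geostatistical surfaces** (`spatialfield`). For each representative, a
   Bayesian beta regression with logit link and a Matérn latent field, fitted
   by a Laplace approximation, with forward covariate selection on WAIC/DIC
   and posterior mean / 2.5% / 97.5% prediction surfaces.
3. **Scoring** (`psi_scoring`). Zonal medians and maxima per district (the
   scoring unit, "LGA") and province ("State"); directional place
   susceptibility scores (PSS); composite PSI as the unweighted sum; Jenks
   natural-breaks classification into five named classes.
4. **Validation** (`validation`). Spearman correlation of province-median PSI
   against province-level health and life-expectancy development indices;
   negative correlation is the expected ("aligned") direction.

## The spatial model

Per cluster $i$ at location $s_i$ with squeezed response $y_i \in (0,1)$:

$$y_i \sim \mathrm{Beta}(\mu_i \phi,\ (1-\mu_i)\phi), \qquad
\operatorname{logit}(\mu_i) = \beta_0 + x_i^\top \beta + u(s_i),$$

where $u$ is a Matérn field with smoothness $\alpha = 2$ (so $\nu = 1$ in two
dimensions), represented on a triangulated mesh through the SPDE finite-element
precision $Q = \tau^2(\kappa^4 C + 2\kappa^2 G + G C^{-1} G)$ with mass-lumped
$C$. Conventions, stated explicitly because they drift between ecosystems:

* range $\rho = \sqrt{8\nu}/\kappa$, so the correlation at distance $\rho$ is
  $\sqrt{8}\,K_1(\sqrt 8) \approx 0.14$;
* marginal variance $\sigma^2 = 1/(4\pi\kappa^2\tau^2)$;
* identifiability: a soft mass-weighted sum-to-zero constraint (a rank-one
  penalty added to $Q$) pins the field's spatial mean at zero, so the
  intercept carries the level. The synthetic truth fields are centred to zero
  domain mean for the same reason — without a convention the "true" intercept
  is not a well-defined quantity.

### Inference

The engine is a self-contained latent-Gaussian approximation in dense linear
algebra (meshes here stay below a few hundred vertices):

* Given hyperparameters $\theta = (\log\rho, \log\sigma, \log\phi)$, the joint
  latent vector (field values + coefficients) is optimised by Fisher-scoring
  Newton steps with step halving; the conditional posterior is the Gaussian at
  the mode with the expected-information Hessian.
* The hyperparameter posterior (Laplace marginal likelihood × priors) is
  maximised by Nelder-Mead, then evaluated on a small curvature-scaled axis
  grid around the mode (seven points for three hyperparameters); the weighted
  Gaussian mixture over these configurations yields the fixed-effect
  summaries, field summaries and posterior draws.
* Priors (all configurable in `Priors`): penalised-complexity-style range
  prior with median $\rho_0 = 0.3\times$ domain diameter; exponential on
  $\sigma$ with $P(\sigma > 1) = 0.1$; Gamma(1, 0.1) on $\phi$; N(0, 10²) on
  coefficients.

### Information criteria and diagnostics

DIC, WAIC and leave-one-out PIT values are computed by 25-node Gauss-Hermite
quadrature over each observation's Gaussian posterior of the linear predictor
(mixed over the hyperparameter grid), not from posterior draws. This matters:
draw-based WAIC carries Monte-Carlo noise of a few units, which is the same
order as the decision threshold in forward selection; quadrature makes model
comparison deterministic. PIT uses an importance-sampling one-leave-out
correction; posterior predictive intervals come from sampled replicates.

### Forward selection

Greedy: starting from the intercept-only model, each round refits every
remaining candidate and accepts the best one only if it lowers WAIC by more
than 6 **and** lowers DIC. The WAIC bar of 6 (not 2) is deliberate: each round
examines several spatially smooth candidates against a realized smooth field,
and chance field–covariate alignment alone produces WAIC improvements of 2–5
in roughly half of null replicates at these study sizes. A bar of 6 acts as a
multiplicity correction; genuinely active covariates at the effect sizes of
interest improve WAIC by hundreds. Both thresholds are arguments of
`forward_select`.

### Boundary squeezing and median-type responses

Cluster proportions hitting 0 or 1 are squeezed as
$y' = (y(n-1) + 0.5)/n$ with $n$ the number of contributing respondents in
the cluster (the aggregation step records these counts). Unbounded
(weighted-median count) components are min–max scaled into $(0,1)$ before
squeezing and beta fitting, and the three prediction surfaces are
back-transformed to the original scale before zonal statistics.

## Scoring

With per-district (LGA) medians $m_i$ of the posterior-mean surface and the
cell-level median $M_p$ of the district's province (State):

* **HSLS** (high value confers low susceptibility, e.g. car ownership):
  $X_i = M_{p(i)} - m_i$, $Y_i = X_i + \max_j X_j$, $\mathrm{PSS}_i = Y_i /
  \max_j Y_j$. Negative $Y$ (possible when $\min X < -\max X$) is clamped to
  zero with a logged count; $\max Y = 0$ marks the component degenerate and
  scores all zeros.
* **HSHS** (high value confers high susceptibility, e.g. chronic sickness):
  $X_i = m_i / M_{p(i)}$, $\mathrm{PSS}_i = X_i / \max_j X_j$; districts under
  a zero state median are flagged missing.

State-level maxima are computed and stored alongside, but only medians enter
the formulas. PSI is the unweighted sum of PSS (weighting is a config hook);
the lower/upper surfaces are pushed through the same formulas to give
credible PSI bounds. Classification is an exact Fisher dynamic-programming
optimum for the k=5 natural-breaks partition, labelled Low … Very High, with
"Unclassified" reserved for districts missing any component.

A structural property worth knowing: both PSS formulas are *state-relative*,
so the province median of the scores is nearly constant across provinces
regardless of how provinces differ in level. District-level ordering is
preserved (the end-to-end experiment checks rank correlation with truth), but
province-aggregated PSI carries little between-province signal on a
statistically stationary country — which is why the convergent-validity sign
is tested under perfect recovery (PSI set to true susceptibility), and why
the estimated-PSI alignment on synthetic countries is reported rather than
asserted. The same mechanism is a plausible reading of why validation against
development indices can come out misaligned in real applications.

## The synthetic country

`synthdata` generates, deterministically per seed:

* a nested Voronoi hierarchy (provinces partition a rectangular country,
  districts partition provinces; ≥2 districts per province);
* eleven geocovariate rasters named after the remote-sensing/
  infrastructure covariates used in this literature (EVI, NDVI, LST, SLOPE,
  ELEV, POPPP, ACCESS, DMROADS, DMROADSINT, DMWATER, NLIGHTS): smoothed
  Gaussian fields rescaled into plausible physical ranges, with true
  Euclidean distance transforms to random road/water features and their
  intersections;
* per-component truth: a circulant-embedding Matérn (ν=1) field plus a linear
  predictor in standardized covariates, giving a true probability surface;
* survey tables: clusters placed uniformly, each with a configurable number
  of households; every household lists 1+Poisson(3.5) roster members (mean
  household size 4.5) and interviewed adults in the individual table; binary
  indicators drawn Bernoulli per row of their source table, count indicators
  as 1+Poisson(6p); three log-normal(0, 0.3) weights named as in PHIA
  releases; cluster centroids geomasked by uniform-disc jitter clamped inside
  the district (default 2 km);
* province development indices: a decreasing affine transform of
  province-mean true susceptibility plus Gaussian noise, clamped to [0,1].

What it does **not** emulate: real questionnaire content, informative
sampling (weights are independent of outcomes), non-stationary covariate
effects, urban/rural masking tiers, or any biomarker content. Passing tests
therefore demonstrate that the estimators and formulas are correct under a
well-specified, stationary design of realistic size — not that the index is
valid for any particular country.

## Study sizes and defaults

Experiments run on a 150 × 150 km country with 3 provinces × 4 districts,
1.5 km covariate cells, 300 clusters × 25 households, truth range 30 km and
field sd 0.7; meshes use an 8 km vertex cutoff and 20/50 km interior/exterior
max edges (≈250 vertices). These sizes keep a full fit under ~2 s while
leaving ≥5 mesh vertices per correlation range. The parameter-recovery
experiment runs without geomasking jitter, because jitter is covariate
measurement error (≈7% attenuation at 2 km jitter against 10 km covariate
smoothness) and would test the masking artefact rather than the estimator;
geomasking is exercised by the geometry tests and the end-to-end run. The
prediction grid aggregates covariates by a configurable block factor
(default 10 in configs mirroring full-resolution practice; 2 in the demo,
where cells are already coarse).

## Numerical choices and degenerate inputs

* Weighted median: lower convention (smallest value reaching half the total
  weight), applied identically at every aggregation level; plain medians of
  even-length sets average the middle two.
* Correlation pruning: only positive r ≥ 0.7 triggers elimination; the member
  of the worst pair with the larger mean |r| to the remaining variables is
  dropped (ties go to the lexicographically later name).
* KMO: exactly orthogonal inputs hit 0/0 and return 0.5 with a log message;
  singular correlation matrices raise, naming the columns.
* Principal-axis factoring: SMC start, communality-change tolerance 1e-3
  (500 iterations); Heywood communalities clamp to 0.995, and a clamped
  solution that cannot settle below tolerance is accepted with a warning
  rather than aborting. Factor count by the Kaiser rule on the reduced
  correlation matrix, floored at one; representative ties resolve by higher
  communality, then name.
* Mesh: greedy cutoff thinning (near-coincident locations collapse to one
  vertex), regular in-fill at max-edge/√2 spacing with a deterministic
  micro-jitter against co-circular degeneracy, and a coarser exterior band
   1.5 × the exterior max edge wide.
* Circulant embedding clips slightly negative torus eigenvalues at zero (the
  standard fix near non-embeddable ranges).
* Zonal statistics assign each cell centre to exactly one district (first in
  id order on shared boundaries); districts with no covered cell are flagged
  missing and propagate to "Unclassified".
* Spearman uses average ranks for ties and returns missing (with a warning)
  for constant vectors; no significance tests are attached, matching how such
  validation coefficients are reported.

## Known limitations

* The hyperparameter posterior is explored on an axis grid only; strongly
  correlated hyperparameter posteriors would be summarised too tightly.
  Field uncertainty is summarised from the mixture draws.
* Dense linear algebra caps practical mesh sizes at a few thousand vertices.
* The beta likelihood treats cluster proportions as continuous; for small
  clusters the discrete binomial character of the data attenuates
  coefficients slightly (visible below ~25 respondents per cluster).
* Geomasking-induced covariate measurement error is not corrected, matching
  standard practice with masked survey coordinates.
* Classes are per-country; no pooled cross-country classification.
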