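# Methods

This note documents the statistical model, the sampler, the synthetic-data
generator, and the numerical and design choices behind `icarreg`.

## Model

County outcome rates (percent obese among persons, males, or females) are
modelled with a Gaussian linear regression in hierarchically centred form,

    y_i ~ N( X_i β + s_i + Σ_k γ_k[cell_k(i)] , σ²_u ),

with three variance components:

- **σ²_u** — IID residual variance;
- **s** — an intrinsic CAR (ICAR) field over the county contiguity graph:
  each s_i is conditionally normal around the mean of its neighbours with
  variance σ²_s / L_i, equivalently the improper joint kernel
  exp(−(1/2σ²_s) Σ_{i~j}(s_i − s_j)²). The kernel is invariant to adding a
  constant, so s is identified by a sum-to-zero constraint (the model has
  a separate intercept);
- **γ_k** — six first-order interaction blocks between the four
  geographic categorisations (urbanicity × division, urbanicity ×
  ethnicity, urbanicity × poverty, division × ethnicity, division ×
  poverty, ethnicity × poverty), each an exchangeable Gaussian random
  effect with block variance σ²_k. Cells are defined on factor-level
  pairs *observed in the data*; unobserved cells would touch neither the
  likelihood nor the summaries, so they are omitted rather than carried
  as prior-only draws (the only consequence is that the block-variance
  update counts observed cells only).

Fixed effects: an intercept; dummy codes for the four categorisations
with the reference levels most-metropolitan urbanicity class, New
England, majority White non-Hispanic, and poverty quintile 1 omitted
(levels in sorted order, factors in declaration order, so summary rows
match the conventional table layout); and the seven environmental
indicators, each rescaled to [0, 1] by (x − min)/range so coefficient
magnitudes are comparable across indicators. "Regression 1" uses the
categorisations and interactions only; "Regression 2" adds the seven
indicators.

### Priors

The analysis tradition this model comes from uses vague priors without
reporting them; we make them explicit and configurable (`McmcConfig`):

| parameter | prior | default rationale |
|---|---|---|
| β (each) | N(0, 1e6) | effectively flat on the percent scale |
| 1/σ²_u, 1/σ²_s, 1/σ²_k | Gamma(0.5, 0.0005) | a common disease-mapping default; proper but weak |

Because the priors and initial values of the original analysis are
unreported, coefficient-level numerical agreement with any published fit
is not an attainable target; all validation is against synthetic data
with known truth.

## Gibbs sampler

All full conditionals are conjugate, so the sampler is a blocked Gibbs
scheme:

1. **β** — multivariate Gaussian with precision X'X/σ²_u + I/10⁶, drawn
   by Cholesky factorisation (p ≈ 31, trivial per iteration).
2. **s** — single-site ICAR-times-likelihood updates: precision
   L_i/σ²_s + 1/σ²_u, mean the precision-weighted combination of the
   neighbour average and the county residual. Nodes are grouped by a
   greedy graph colouring; within a colour class no two nodes are
   adjacent, so the class is updated in one vectorised draw (a rook
   lattice needs two classes). After every sweep s is recentred to mean
   zero over non-island nodes — the standard identification device for
   the improper prior; the intercept absorbs the shift.
3. **γ_k** — per-cell Gaussian shrinkage: precision n_c/σ²_u + 1/σ²_k.
4. **variances** — conjugate Gamma updates on the precisions. The ICAR
   update uses rank = (number of non-island nodes) − (number of connected
   components) as its degrees of freedom. Draws are floored at 1e-12
   (occurrences logged); non-finite draws abort with diagnostics.

**Islands** (nodes with no neighbours): s_i is pinned to 0 and excluded
from the recentring and the rank count. This mirrors common practice with
the classical CAR implementation; the original analysis is silent on the
point, so this is a documented package choice, not a reproduction.

**Chains and initialisation.** Two chains by default (more allowed), with
independent sub-seeds spawned from the master seed. Chain c starts β at
the OLS estimate offset by ±2(⌊c/2⌋+1) standard errors and the variances
at 0.5× or 2× the OLS residual variance — overdispersed relative to the
posterior. Burn-in is the first half of the run; no thinning. Convergence
is monitored by the split-chain potential scale reduction factor (PSRF)
with a warning flag at 1.1; the threshold is a convention, not part of
the estimator.

## Summary statistics

- **Λ = var(s)/(var(s) + σ²_u)**: var(s) is the empirical variance of the
  spatial field across counties *at each retained draw*, and Λ is formed
  per draw, then summarised by posterior mean and equal-tailed 95%
  interval. The per-draw construction (rather than a plug-in of posterior
  means) propagates posterior uncertainty into Λ.
- **% explained = 100·(1 − (var(s) + σ²_u)/var(y))** per draw, with
  var(y) the empirical outcome variance. This uses the model-based
  residual variation var(s) + σ²_u; a realised-residual alternative
  (var(y − Xβ − s)) would require the design matrix inside the metric and
  is intentionally not the default.
- **PSRF**: each chain is split in half; PSRF = sqrt(((T−1)/T·W + B/T)/W)
  over the 2C half-sequences. On identical stationary chains this equals
  1 only asymptotically — splitting leaves an O(T^−1/2) between-half
  term — which is why the identity tests use long chains and a small
  tolerance rather than exact equality.

## Indicator construction

- **Unit rescaling**: (x − min)/range over the analysis cohort; errors on
  constant input.
- **Concentration score**: leading principal component of five
  standardised settlement/commuting indices (car commuting, public
  transport commuting, walking/cycling commuting, post-1950 housing,
  population density). PCA is on the correlation matrix because the
  units are incommensurable. The eigenvector sign is fixed so the car-
  commuting loading is negative — car-dependent, dispersed counties score
  most negative — and scores are standardised to unit sample variance.
  A degenerate leading-eigenvalue gap raises an error reporting the
  spectrum.
- **Food environment index**: the published index states only its two
  components (limited access to healthy foods, food insecurity), equal
  weighting, and a 0–10 range with 10 best. We reconstruct it as: min–max
  each component over the cohort to a [0,10] badness scale, average,
  reverse. Whether the published normalisation is cohort min–max,
  z-scores, or something else is unknown; pipelines holding a precomputed
  index column simply pass it through.
- **Quintiles**: empirical 20/40/60/80 percentiles by default, with the
  four cutpoints reported; externally fixed breaks (e.g. published
  poverty cutpoints 11.8/14.7/18/22.1%) accepted for reproducing a
  published layout. Intervals are lower-closed (a value equal to a
  cutpoint goes to the higher quintile). Heavy ties that empty a quintile
  raise an error.

## Descriptive tables

Cross-tabulated cell statistics are **unweighted means of county rates**;
whether published versions of such tables weight by population is
generally unstated, so unweighted is the default and a population-weight
column is an optional argument. Margins are count-weighted (they equal
the direct means over the margin's counties), so the grand mean
reconstructs the direct mean over all counties to machine precision.
Counties with missing outcomes are dropped per table with a logged count;
empty cells are reported as missing, never zero.

## Synthetic-county generator

The generator emulates the statistical structure the analysis assumes,
not any real geography:

- **Graph**: a rook lattice by default (queen optional). Real county
  contiguity has irregular degree; the lattice keeps degrees 2–4, which
  is the right order.
- **Indicators**: one latent unit-variance Gaussian column per variable,
  each a mixture w·(standardised ICAR draw) + sqrt(1−w²)·white noise
  (w = 0.6 by default, giving poverty Moran's I ≈ 0.2; w is a config
  knob because the real clustering strength is documented only
  qualitatively). Columns are coloured by the Cholesky factor of a
  target correlation matrix whose poverty–inactivity (0.48) and exercise-
  access–poverty (−0.38) entries are the documented US county values and
  whose remaining entries are plausible smaller linkages; the matrix is
  eigenvalue-clipped to the nearest correlation matrix if needed. Latent
  columns are mapped affinely to realistic scales (poverty centred near
  16.5% with sd 6.2 so its empirical quintile cutpoints land near the
  published ones; inactivity 25 ± 5%, and so on) and clipped to valid
  ranges — clipping is rare by construction, so the affine maps preserve
  the target correlations.
- **Categorical factors**: poverty quintiles are cut from the latent
  poverty column, so poverty–environment confounding is reproducible;
  urbanicity, division, and ethnicity are drawn independently from
  frequency tables roughly proportional to US county counts. Every level
  is forced to appear at least once so reference-coded designs are well
  defined even on small lattices. The true joint distribution of the four
  factors (e.g. division × urbanicity dependence) is not reproduced.
- **Spatial effects**: exact draws from the sum-to-zero ICAR via the
  graph-Laplacian eigenbasis (zero eigenvalue removed), covariance
  σ²_s·L⁺. Eigendecompositions are cached per graph structure.
- **Outcomes**: y = Xβ_true + s_true + u. Default β_true values are at
  the order of magnitude of published indicator-regression fits
  (inactivity ≈ 15 and concentration ≈ −16 per unit-scaled covariate,
  small urbanicity effects, moderate ethnicity/division effects) so that
  synthetic runs exercise realistic signal-to-noise; they are scenario
  defaults, not claims about the real coefficients. Default variances:
  σ²_s = 4, σ²_u = 1. Male and female outcome columns scale the
  non-intercept effects by 0.9 and 1.15 with independent noise, mirroring
  the weaker male and stronger female environmental gradients seen in
  county data.
- Every dataset carries a `SimTruth` (β_true, s_true, variances,
  λ_true = var(s_true)/(var(s_true)+σ²_u)); fitting code never reads it.

The **mediated-confounding scenario** (`mediated_confounding_config`)
sets all direct categorical effects to zero, drives outcomes purely
through strongly clustered (w = 0.85), poverty-correlated indicators, and
keeps σ²_s small (0.5). A categories-only regression then attributes
signal to poverty quintiles and the spatial residual; adding the
indicators raises % explained, shrinks the poverty coefficients toward
zero, and lowers Λ — the qualitative mediation signature the two-
regression comparison is designed to expose.

**What passing synthetic tests does not show**: the generator has
Gaussian marginals, a regular lattice, independent factor assignment, and
no survey estimation error in the outcome rates, so recovery results here
do not certify behaviour under BRFSS-style small-area noise, irregular
contiguity, or non-Gaussian indicator distributions.

## Problem sizes and tolerances in the test suite

Validation runs are sized for a single CPU: exhaustive ICAR checks use
all 142 connected graphs on 2–6 nodes with 1e5–3e5 independent Gibbs
draws each (final states of parallel chains, so the mean check's 1e-2
tolerance sits at ≥4 Monte-Carlo standard errors; the draw count is
raised for the few graphs whose largest marginal sd exceeds 0.9);
parameter recovery uses a 30×30 lattice with 2 chains × 4000 iterations
over 5 seeds; the mediation contrast a 20×20 lattice with 2 × 1500 over
5 seeds; generator correlation checks a 50×50 lattice. Monte-Carlo
comparisons use error bounds derived from per-chain or per-draw spread
(e.g. chi-square-scale joint bounds for the conjugate-posterior check)
rather than fixed magic numbers wherever possible.

## Known limitations

- Gaussian likelihood on bounded percentage outcomes (no logit/Binomial
  option); adequate for rates far from 0/100.
- Single spatial prior (ICAR); no proper-CAR, BYM2, or Leroux variants,
  and no model-comparison criteria (DIC/WAIC).
- Single-site spatial updates mix slowly if σ²_s/σ²_u is extreme;
  the PSRF flag is the guard.
- The FEI reconstruction and the interaction-cell convention are
  documented package choices where the source analyses are silent.
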