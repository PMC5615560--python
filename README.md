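# icarreg

Bayesian county-level ecological regression of obesity rates on the
obesogenic environment, with spatially correlated residuals.

## The problem

Obesity rates vary widely between US counties — by urban–rural status,
census division, area poverty, and majority ethnic group — and they are
strongly spatially clustered. How much of that geographic variation can be
accounted for by *measurable* features of the environment: physical
inactivity, access to exercise opportunities, the food environment, and
car-dependent settlement patterns?

`icarreg` implements the full analysis for that question as a reusable
package, aimed at spatial epidemiologists and health geographers. Because
the real inputs (county obesity estimates, health rankings, food
environment tables) are compiled from several sources and are not bundled,
the package ships a synthetic-county generator that reproduces their
statistical structure — including the documented county-level correlations
between poverty and inactivity (0.48) and between exercise access and
poverty (−0.38) — so the entire pipeline runs end-to-end with no
downloads, and every estimator can be validated against known generating
truth.

## The model

For county *i* with outcome rate *y<sub>i</sub>* (%), covariate row
*X<sub>i</sub>*, and neighbours *j ~ i* on a contiguity graph:

```
y_i = X_i β + s_i + u_i,          u_i ~ N(0, σ²_u)
s_i | s_{-i} ~ N( mean of s over neighbours of i , σ²_s / L_i )
```

where *L<sub>i</sub>* is the neighbour count. The field *s* follows the
intrinsic conditional autoregressive (ICAR) prior — joint kernel
`exp(−(1/2σ²_s) Σ_{i~j} (s_i − s_j)²)` — identified by a sum-to-zero
constraint. Fixed effects cover dummy-coded geographic categorisations
(references: most-metropolitan urbanicity class, New England, majority
White non-Hispanic, lowest poverty quintile) and seven environmental
indicators rescaled to [0, 1] via `(x − min)/range`. The six pairwise
interactions between the four categorisations enter as exchangeable
Gaussian random effects with their own variances.

Fitting is by a from-scratch blocked Gibbs sampler (two chains of 10,000
iterations by default, first half discarded, no thinning), with vague
priors: β ~ N(0, 10⁶), precisions ~ Gamma(0.5, 0.0005). Each fit reports
posterior means and equal-tailed 95% credible intervals, plus two summary
statistics:

- **Λ = var(s) / (var(s) + σ²_u)** — the spatially structured share of
  residual variation (1 = fully clustered), computed per retained draw;
- **% variation explained = 100·(1 − (var(s) + σ²_u)/var(y))**;

and split-chain Brooks–Gelman–Rubin (BGR) potential scale reduction
factors, flagged at 1.1.

The package also constructs the indicators themselves: the **concentration
score** (leading principal component of five standardised
settlement/commuting indices, signed so car-dependent sprawl scores
negative), the 0–10 **food environment index** (equal-weight combination
of limited healthy-food access and food insecurity, 10 = best), and
quintile assignment with empirical or fixed cutpoints; plus the
descriptive geography: cross-tabulated mean rates by category pairs,
top-vs-bottom gradient ratios, and per-quintile outcome profiles.

## Worked example

```python
import icarreg as ir
from icarreg.model import McmcConfig

cfg = ir.SimConfig(rows=20, cols=20, seed=7)       # 400 synthetic counties
data, graph, truth = ir.generate_dataset(cfg)
mc = McmcConfig(n_chains=2, n_iter=2000, seed=7, progress_every=0)
res = ir.run_regression2(data, graph, mc, with_interactions=False)
print(res.summary.loc[["Intercept", "inactivity", "concentration_score",
                       "fei", "poverty_quintile:5"]].round(2))
```

prints

```
                      mean   2.5%  97.5%
Intercept            26.39  24.11  28.71
inactivity           14.80  13.63  16.08
concentration_score -15.65 -16.88 -14.47
fei                  -2.69  -3.96  -1.53
poverty_quintile:5    0.81   0.18   1.46
```

The generating slopes (15 for inactivity on the unit scale, −16 for the
concentration score) sit inside their intervals. The variance-partition
metrics for the same fit:

```
% variation explained: 85.3 (83.4, 87.1)
spatial fraction Lambda: 0.616 (0.464, 0.768)
converged (all BGR < 1.1): True
```

against a generating `lambda_true` of 0.722. A slope of 14.8 on the
unit-scaled inactivity covariate means a ~15-point swing in the obesity
rate between the least and most inactive counties, holding the rest fixed.

The same pipeline is scriptable from the shell:

```sh
icarreg simulate --rows 20 --cols 20 --seed 7 --outdir run/
icarreg descriptives run/counties.csv --outdir run/
icarreg fit reg1 run/counties.csv run/adjacency.gal --seed 7 --outdir run/
icarreg fit reg2 run/counties.csv run/adjacency.gal --seed 7 --outdir run/
icarreg report run/
```

## Adjacency file formats

GAL spatial weights (header = node count; per node a `id count` line then
a line of neighbour ids) and plain whitespace edge lists. A 4-node path
`a–b–c–d` in both dialects:

```
4               # GAL                 a b     # edge list
a 1                                   b c
b                                     c d
b 2
a c
c 2
b d
d 1
c
```

One-directional records are symmetrised on read with a warning; self-loops
are rejected. `icarreg.build_grid_adjacency(rows, cols, scheme)` builds
rook or queen lattices for synthetic work.

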