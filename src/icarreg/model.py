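"""Bayesian linear regression with ICAR spatial residuals, by Gibbs sampling.

The model, in hierarchically centred form:

    y_i ~ N(X_i beta + s_i + sum_k gamma_k[cell_k(i)], sigma2_u)

with ``s`` an intrinsic-CAR field over the county adjacency graph
(conditional variance ``sigma2_s / L_i``, sum-to-zero identification) and
each first-order interaction block ``gamma_k`` exchangeable Gaussian with
its own variance.  Fixed effects ``beta`` cover dummy-coded geographic
categorisations (reference levels omitted) and unit-scaled environmental
indicators.

Priors: beta ~ N(0, 1e6) elementwise; all precisions (1/sigma2_u,
1/sigma2_s, interaction precisions) ~ Gamma(0.5, 0.0005) — vague defaults
common in disease mapping, every hyperparameter exposed in `McmcConfig`.

Inference runs two (or more) chains from overdispersed starts; retained
draws are the post-burn-in halves, summarised as posterior means with
equal-tailed 95% credible intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.sparse.csgraph import connected_components

from .indicators import scale_unit
from .spatial import AdjacencyGraph

logger = logging.getLogger(__name__)

__all__ = [
    "FactorSpec",
    "ModelSpec",
    "McmcConfig",
    "InteractionBlock",
    "DesignMatrix",
    "PosteriorSamples",
    "build_design",
    "fit_gibbs",
    "posterior_summary",
]


@dataclass(frozen=True)
class FactorSpec:
    """A categorical factor with a declared reference level."""

    name: str
    reference: str | int


@dataclass(frozen=True)
class ModelSpec:
    """Declaration of the regression: outcome, factors, covariates, interactions."""

    outcome: str
    factors: tuple[FactorSpec, ...] = ()
    covariates: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    include_spatial: bool = True

    def __post_init__(self) -> None:
        names = {f.name for f in self.factors}
        for a, b in self.interactions:
            if a not in names or b not in names:
                raise ValueError(
                    f"interaction ({a!r}, {b!r}) references an undeclared factor"
                )


@dataclass(frozen=True)
class McmcConfig:
    """MCMC protocol: two chains, burn-in = first half, no thinning."""

    n_chains: int = 2
    n_iter: int = 10_000
    burn_in: int | None = None
    seed: int = 0
    prior_beta_var: float = 1e6
    prior_prec_shape: float = 0.5
    prior_prec_rate: float = 0.0005
    fix_sigma2_u: float | None = None
    fix_sigma2_s: float | None = None
    variance_floor: float = 1e-12
    progress_every: int = 500

    @property
    def burn(self) -> int:
        b = self.n_iter // 2 if self.burn_in is None else self.burn_in
        if not 0 <= b < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        return b


@dataclass(frozen=True)
class InteractionBlock:
    """Incidence of counties on observed cells of a factor-pair interaction."""

    name: str
    codes: np.ndarray        # (n,) int, cell index per county
    n_cells: int
    cell_labels: tuple[str, ...]
    cell_counts: np.ndarray  # (n_cells,) counties per cell


@dataclass(frozen=True)
class DesignMatrix:
    """Encoded fixed effects plus interaction incidence maps."""

    X: np.ndarray
    columns: tuple[str, ...]
    interactions: tuple[InteractionBlock, ...]
    include_spatial: bool

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def build_design(
    data: pd.DataFrame, spec: ModelSpec, check_rank: bool = True
) -> DesignMatrix:
    """Encode the model: intercept, dummy-coded factors, unit-scaled covariates.

    Factor levels appear in sorted order with the declared reference
    omitted, factors in declaration order, covariates after — matching the
    row order of the reported coefficient tables.  ``check_rank=False``
    skips the collinearity check (useful when the design is only consumed
    to form a linear predictor, e.g. in simulation, where near-saturated
    tiny cohorts can be rank deficient without harm).
    """
    used = [spec.outcome] + [f.name for f in spec.factors] + list(spec.covariates)
    for col in used:
        if col not in data.columns:
            raise KeyError(f"column {col!r} not in data")
        if data[col].isna().any():
            raise ValueError(f"column {col!r} has missing values")

    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]
    for f in spec.factors:
        levels = sorted(data[f.name].unique())
        if f.reference not in levels:
            raise ValueError(
                f"reference level {f.reference!r} absent from factor {f.name!r}"
            )
        for lev in levels:
            if lev == f.reference:
                continue
            cols.append((data[f.name] == lev).to_numpy(dtype=float))
            names.append(f"{f.name}:{lev}")
    for cov in spec.covariates:
        cols.append(scale_unit(data[cov].to_numpy(dtype=float)))
        names.append(cov)

    X = np.column_stack(cols)
    if check_rank:
        # full-column-rank check with pivoted QR; name the dependent columns
        _, r, piv = sla.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        rank = int((diag > tol).sum())
        if rank < X.shape[1]:
            dependent = [names[j] for j in piv[rank:]]
            raise ValueError(
                f"design matrix is rank deficient; collinear columns: {dependent}"
            )

    blocks = []
    for a, b in spec.interactions:
        pairs = list(zip(data[a], data[b]))
        codes, uniques = pd.factorize(pd.Series(pairs), sort=True)
        labels = tuple(f"{a}={pa}|{b}={pb}" for pa, pb in uniques)
        counts = np.bincount(codes, minlength=len(uniques))
        blocks.append(
            InteractionBlock(
                name=f"{a}*{b}",
                codes=codes.astype(int),
                n_cells=len(uniques),
                cell_labels=labels,
                cell_counts=counts,
            )
        )

    return DesignMatrix(
        X=X,
        columns=tuple(names),
        interactions=tuple(blocks),
        include_spatial=spec.include_spatial,
    )


@dataclass
class PosteriorSamples:
    """Post-burn-in draws, shaped (n_chains, n_kept, ...)."""

    beta: np.ndarray                 # (C, T, p)
    beta_names: tuple[str, ...]
    s: np.ndarray                    # (C, T, n); zeros when spatial disabled
    sigma2_u: np.ndarray             # (C, T)
    sigma2_s: np.ndarray | None      # (C, T) or None
    interaction_variances: dict[str, np.ndarray]   # name -> (C, T)
    interaction_effects: dict[str, np.ndarray]     # name -> (C, T, m)
    include_spatial: bool

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_kept(self) -> int:
        return self.beta.shape[1]

    def pooled(self, arr: np.ndarray) -> np.ndarray:
        """Flatten the chain axis: (C, T, ...) -> (C*T, ...)."""
        return arr.reshape(-1, *arr.shape[2:])


class _SpatialState:
    """Precomputed graph quantities for the s-field Gibbs updates."""

    def __init__(self, graph: AdjacencyGraph):
        self.A = graph.adjacency_matrix()
        self.deg = graph.degrees().astype(float)
        self.islands = self.deg == 0
        self.active = ~self.islands
        self.colours = [
            idx[~self.islands[idx]] for idx in graph.colouring()
        ]
        self.colours = [idx for idx in self.colours if idx.size]
        sub = self.A[self.active][:, self.active]
        if self.active.sum() > 0:
            ncomp, _ = connected_components(sub, directed=False)
        else:
            ncomp = 0
        # rank of the pairwise-difference kernel: one sum-to-zero constraint
        # per connected component of non-island counties
        self.rank = int(self.active.sum() - ncomp)
        self.L = graph.laplacian()


def _ols_start(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - X.shape[1], 1)
    s2 = float(resid @ resid) / dof
    XtX = X.T @ X
    try:
        cov = s2 * np.linalg.inv(XtX + 1e-10 * np.eye(X.shape[1]))
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.sqrt(s2))
    return beta, se, s2


def fit_gibbs(
    y: np.ndarray,
    design: DesignMatrix,
    graph: AdjacencyGraph | None,
    config: McmcConfig,
) -> PosteriorSamples:
    """Run the blocked Gibbs sampler and return post-burn-in draws.

    Chains start overdispersed around the OLS fit (beta offset by +/- 2 SE
    per chain, variances at 0.5x / 2x the OLS residual variance) with
    independent sub-seeds spawned from ``config.seed``.
    """
    y = np.asarray(y, dtype=float)
    n, p = design.X.shape
    if y.shape != (n,):
        raise ValueError(f"y has shape {y.shape}, design has {n} rows")
    if design.include_spatial:
        if graph is None:
            raise ValueError("spatial model requires an adjacency graph")
        if graph.n != n:
            raise ValueError(
                f"graph has {graph.n} nodes but design has {n} rows (misaligned inputs)"
            )
        spat = _SpatialState(graph)
    else:
        spat = None

    burn = config.burn
    n_kept = config.n_iter - burn
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    beta_hat, se, s2_hat = _ols_start(y, design.X)

    out_beta = np.empty((config.n_chains, n_kept, p))
    out_s = np.zeros((config.n_chains, n_kept, n))
    out_s2u = np.empty((config.n_chains, n_kept))
    out_s2s = np.empty((config.n_chains, n_kept)) if spat else None
    out_ivar = {b.name: np.empty((config.n_chains, n_kept)) for b in design.interactions}
    out_ieff = {
        b.name: np.empty((config.n_chains, n_kept, b.n_cells))
        for b in design.interactions
    }

    offsets = [(-1) ** c * (c // 2 + 1) for c in range(config.n_chains)]
    var_factors = [0.5 if c % 2 == 0 else 2.0 for c in range(config.n_chains)]

    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        init_beta = beta_hat + 2.0 * offsets[c] * se
        init_var = max(var_factors[c] * s2_hat, config.variance_floor)
        _run_chain(
            y, design, spat, config, rng, init_beta, init_var, c,
            out_beta[c], out_s[c], out_s2u[c],
            None if out_s2s is None else out_s2s[c],
            {k: v[c] for k, v in out_ivar.items()},
            {k: v[c] for k, v in out_ieff.items()},
        )

    return PosteriorSamples(
        beta=out_beta,
        beta_names=design.columns,
        s=out_s,
        sigma2_u=out_s2u,
        sigma2_s=out_s2s,
        interaction_variances=out_ivar,
        interaction_effects=out_ieff,
        include_spatial=design.include_spatial,
    )


def _run_chain(
    y, design, spat, config, rng, init_beta, init_var, chain_id,
    out_beta, out_s, out_s2u, out_s2s, out_ivar, out_ieff,
):
    n, p = design.X.shape
    X = design.X
    XtX = X.T @ X
    prior_prec = 1.0 / config.prior_beta_var
    a0, b0 = config.prior_prec_shape, config.prior_prec_rate
    floor = config.variance_floor

    beta = init_beta.copy()
    sigma2_u = config.fix_sigma2_u if config.fix_sigma2_u is not None else init_var
    sigma2_s = config.fix_sigma2_s if config.fix_sigma2_s is not None else init_var
    s = np.zeros(n)
    gammas = [np.zeros(b.n_cells) for b in design.interactions]
    ivars = [init_var for _ in design.interactions]
    int_contrib = np.zeros(n)

    Xbeta = X @ beta
    burn = config.burn

    for it in range(config.n_iter):
        # --- beta | rest: Gaussian conjugate update
        r = y - s - int_contrib
        prec = XtX / sigma2_u + prior_prec * np.eye(p)
        chol = sla.cho_factor(prec, lower=True)
        mean = sla.cho_solve(chol, X.T @ r / sigma2_u)
        z = rng.standard_normal(p)
        beta = mean + sla.solve_triangular(chol[0], z, lower=True, trans="T")
        Xbeta = X @ beta

        # --- spatial field: ICAR conditional x likelihood, by colour class
        if spat is not None:
            e = y - Xbeta - int_contrib
            for idx in spat.colours:
                nbsum = spat.A[idx] @ s
                prec_s = spat.deg[idx] / sigma2_s + 1.0 / sigma2_u
                mu = (nbsum / sigma2_s + e[idx] / sigma2_u) / prec_s
                s[idx] = mu + rng.standard_normal(idx.size) / np.sqrt(prec_s)
            if spat.active.any():
                s[spat.active] -= s[spat.active].mean()
            s[spat.islands] = 0.0

        # --- interaction blocks: exchangeable-cell shrinkage
        for k, block in enumerate(design.interactions):
            contrib_k = gammas[k][block.codes]
            u = y - Xbeta - s - (int_contrib - contrib_k)
            cellsum = np.bincount(block.codes, weights=u, minlength=block.n_cells)
            prec_g = block.cell_counts / sigma2_u + 1.0 / ivars[k]
            mu_g = cellsum / sigma2_u / prec_g
            gammas[k] = mu_g + rng.standard_normal(block.n_cells) / np.sqrt(prec_g)
            int_contrib += gammas[k][block.codes] - contrib_k

        # --- variances: conjugate Gamma updates on precisions
        resid = y - Xbeta - s - int_contrib
        if config.fix_sigma2_u is None:
            rate = b0 + 0.5 * float(resid @ resid)
            prec_u = rng.gamma(a0 + 0.5 * n, 1.0 / rate)
            sigma2_u = max(1.0 / prec_u, floor)
        if spat is not None and config.fix_sigma2_s is None:
            q = float(s @ (spat.L @ s))
            rate = b0 + 0.5 * q
            prec_sp = rng.gamma(a0 + 0.5 * spat.rank, 1.0 / rate)
            sigma2_s = max(1.0 / prec_sp, floor)
        for k, block in enumerate(design.interactions):
            rate = b0 + 0.5 * float(gammas[k] @ gammas[k])
            prec_k = rng.gamma(a0 + 0.5 * block.n_cells, 1.0 / rate)
            ivars[k] = max(1.0 / prec_k, floor)

        if not (np.isfinite(sigma2_u) and np.isfinite(sigma2_s)):
            raise RuntimeError(
                f"divergent variance draw at iteration {it} (chain {chain_id}): "
                f"sigma2_u={sigma2_u}, sigma2_s={sigma2_s}"
            )
        if sigma2_u <= floor or (spat is not None and sigma2_s <= floor):
            logger.warning(
                "variance floored at iteration %d (chain %d)", it, chain_id
            )

        if config.progress_every and (it + 1) % config.progress_every == 0:
            logger.info(
                "chain %d iteration %d/%d", chain_id, it + 1, config.n_iter
            )

        if it >= burn:
            t = it - burn
            out_beta[t] = beta
            out_s[t] = s
            out_s2u[t] = sigma2_u
            if out_s2s is not None:
                out_s2s[t] = sigma2_s
            for k, block in enumerate(design.interactions):
                out_ivar[block.name][t] = ivars[k]
                out_ieff[block.name][t] = gammas[k]


def posterior_summary(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior mean and equal-tailed 95% interval per parameter.

    Rows: fixed effects in design order, then variance components and the
    interaction-block variances, pooling post-burn-in draws across chains.
    """
    total = samples.n_chains * samples.n_kept
    if total < 100:
        raise ValueError("need at least 100 retained draws to summarise")

    rows, names = [], []

    def add(name: str, draws: np.ndarray) -> None:
        names.append(name)
        rows.append(
            [float(draws.mean()), *np.quantile(draws, [0.025, 0.975]).tolist()]
        )

    pooled_beta = samples.pooled(samples.beta)
    for j, nm in enumerate(samples.beta_names):
        add(nm, pooled_beta[:, j])
    add("sigma2_u", samples.pooled(samples.sigma2_u))
    if samples.sigma2_s is not None:
        add("sigma2_s", samples.pooled(samples.sigma2_s))
    for nm, draws in samples.interaction_variances.items():
        add(f"var({nm})", samples.pooled(draws))

    return pd.DataFrame(rows, index=names, columns=["mean", "2.5%", "97.5%"])
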