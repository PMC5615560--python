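"""Synthetic county generator with the statistical structure the model assumes.

Emulates the shape of the real inputs — a national county table with
outcome obesity rates, four geographic categorisations, and seven
environmental indicators on a contiguity graph — without any real data:

* lattice geography standing in for county contiguity (rook by default);
* a latent Gaussian field per indicator with mild spatial autocorrelation,
  cross-correlated so that poverty-inactivity correlation is 0.48 and
  exercise-access-poverty correlation is -0.38 (the documented US county
  values), then mapped to plausible indicator scales and clipped to valid
  ranges;
* poverty quintiles cut from the latent poverty field, so poverty-
  environment confounding is reproducible; the other three categorical
  factors drawn independently from plausible frequency tables;
* spatial effects drawn properly from the sum-to-zero ICAR distribution
  (graph-Laplacian eigenbasis, zero eigenvalue removed);
* outcomes from the linear model y = X beta_true + s_true + u.

Every generated dataset carries a `SimTruth` with the generating
parameters for parameter-recovery testing; fitting code never reads it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .indicators import quintile_assign
from .model import DesignMatrix, FactorSpec, ModelSpec, build_design
from .spatial import AdjacencyGraph, build_grid_adjacency, write_adjacency

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_indicators",
    "simulate_spatial_effects",
    "simulate_outcome",
    "generate_dataset",
    "write_dataset",
    "INDICATOR_COLUMNS",
    "GEO_FACTORS",
]

INDICATOR_COLUMNS = (
    "inactivity",
    "exercise_access",
    "fastfood_grocery_ratio",
    "groceries_per_head",
    "fei",
    "pct_restaurants_fastfood",
    "concentration_score",
)
GEO_FACTORS = ("urbanicity", "division", "ethnicity", "poverty_quintile")

_DIVISIONS = (
    "New England",
    "Middle Atlantic",
    "East North Central",
    "West North Central",
    "South Atlantic",
    "East South Central",
    "West South Central",
    "Mountain",
    "Pacific",
)
_ETHNICITIES = ("White N-H", "Black N-H", "Hispanic", "Other")

# latent-variable order for the cross-correlation matrix
_LATENT = ("poverty",) + INDICATOR_COLUMNS

# marginal maps: latent z (unit variance) -> indicator scale, with clip range
_MARGINALS: dict[str, tuple[float, float, float, float]] = {
    # name: (mean, sd, clip_lo, clip_hi)
    "poverty": (16.5, 6.2, 1.0, 60.0),
    "inactivity": (25.0, 5.0, 1.0, 60.0),
    "exercise_access": (55.0, 22.0, 0.0, 100.0),
    "fastfood_grocery_ratio": (1.6, 0.9, 0.0, 8.0),
    "groceries_per_head": (0.25, 0.10, 0.0, 2.0),
    "fei": (7.0, 1.1, 0.0, 10.0),
    "pct_restaurants_fastfood": (45.0, 10.0, 0.0, 100.0),
    "concentration_score": (0.0, 1.0, -5.0, 5.0),
}


def _default_beta_true() -> dict[str, float]:
    """Fixed-effect truths at the order of magnitude of the reported fits.

    Covariates enter the design unit-scaled, so a slope of 15 on inactivity
    means a 15-point outcome swing across the observed indicator range.
    """
    beta = {
        "Intercept": 25.0,
        "inactivity": 15.0,
        "exercise_access": -1.0,
        "fastfood_grocery_ratio": 1.6,
        "groceries_per_head": -1.6,
        "fei": -2.3,
        "pct_restaurants_fastfood": 1.2,
        "concentration_score": -16.0,
        "ethnicity:Black N-H": 2.2,
        "ethnicity:Hispanic": 0.3,
        "ethnicity:Other": 3.4,
        "division:Mountain": -3.4,
        "division:Pacific": -3.1,
        "division:East South Central": 0.5,
        "poverty_quintile:2": 0.1,
        "poverty_quintile:3": 0.45,
        "poverty_quintile:4": 0.55,
        "poverty_quintile:5": 1.05,
    }
    for u in range(2, 10):
        beta[f"urbanicity:{u}"] = 0.3
    return beta


def _default_category_probs() -> dict[str, tuple[float, ...]]:
    return {
        "urbanicity": (0.05, 0.10, 0.11, 0.06, 0.03, 0.18, 0.10, 0.17, 0.20),
        # roughly proportional to county counts per census division
        "division": (0.022, 0.048, 0.140, 0.199, 0.189, 0.117, 0.151, 0.091, 0.043),
        "ethnicity": (0.82, 0.06, 0.05, 0.07),
    }


def _default_correlations() -> np.ndarray:
    """Cross-correlation targets for (poverty, seven indicators).

    The poverty-inactivity (0.48) and exercise-access-poverty (-0.38)
    entries are the documented US county values; the rest are plausible
    obesogenic-environment linkages of smaller magnitude.
    """
    k = len(_LATENT)
    R = np.eye(k)

    def set_(a: str, b: str, r: float) -> None:
        i, j = _LATENT.index(a), _LATENT.index(b)
        R[i, j] = R[j, i] = r

    set_("poverty", "inactivity", 0.48)
    set_("poverty", "exercise_access", -0.38)
    set_("poverty", "fastfood_grocery_ratio", 0.25)
    set_("poverty", "groceries_per_head", -0.10)
    set_("poverty", "fei", -0.55)
    set_("poverty", "pct_restaurants_fastfood", 0.10)
    set_("poverty", "concentration_score", -0.20)
    set_("inactivity", "exercise_access", -0.35)
    set_("inactivity", "fei", -0.35)
    set_("inactivity", "concentration_score", -0.30)
    set_("exercise_access", "concentration_score", 0.30)
    set_("fei", "fastfood_grocery_ratio", -0.20)
    return R


@dataclass(frozen=True)
class SimConfig:
    """Generating conditions for one synthetic county dataset."""

    rows: int = 30
    cols: int = 30
    seed: int = 0
    scheme: str = "rook"
    sigma2_s_true: float = 4.0
    sigma2_u_true: float = 1.0
    rho_poverty_inactivity: float = 0.48
    rho_access_poverty: float = -0.38
    indicator_spatial_weight: float = 0.6
    beta_true: dict[str, float] = field(default_factory=_default_beta_true)
    category_probabilities: dict[str, tuple[float, ...]] = field(
        default_factory=_default_category_probs
    )

    def __post_init__(self) -> None:
        for r in (self.rho_poverty_inactivity, self.rho_access_poverty):
            if not -1.0 < r < 1.0:
                raise ValueError("correlations must lie in (-1, 1)")
        if self.sigma2_s_true <= 0 or self.sigma2_u_true < 0:
            raise ValueError("variances must be positive")
        for name, probs in self.category_probabilities.items():
            if abs(sum(probs) - 1.0) > 1e-8:
                raise ValueError(f"probabilities for {name!r} must sum to 1")

    def correlation_matrix(self) -> np.ndarray:
        R = _default_correlations()
        i, j = _LATENT.index("poverty"), _LATENT.index("inactivity")
        R[i, j] = R[j, i] = self.rho_poverty_inactivity
        i, j = _LATENT.index("poverty"), _LATENT.index("exercise_access")
        R[i, j] = R[j, i] = self.rho_access_poverty
        return R


@dataclass
class SimTruth:
    """Generating parameters retained for recovery tests; never read by fits."""

    beta_true: dict[str, float]
    beta_vector: np.ndarray
    s_true: np.ndarray
    sigma2_s_true: float
    sigma2_u_true: float
    lambda_true: float

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["beta_vector"] = self.beta_vector.tolist()
        d["s_true"] = self.s_true.tolist()
        Path(path).write_text(json.dumps(d, indent=2))


# cache of Laplacian eigendecompositions, keyed by graph structure so
# repeated same-shape lattices share one (possibly expensive) eigh call
_EIG_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _laplacian_eig(graph: AdjacencyGraph) -> tuple[np.ndarray, np.ndarray]:
    edges = tuple(
        (i, j) for i in graph.node_ids for j in sorted(graph.neighbours[i]) if i < j
    )
    key = (graph.node_ids, hash(edges))
    if key not in _EIG_CACHE:
        L = graph.laplacian().toarray()
        evals, evecs = sla.eigh(L)
        if len(_EIG_CACHE) > 8:
            _EIG_CACHE.clear()
        _EIG_CACHE[key] = (evals, evecs)
    return _EIG_CACHE[key]


def simulate_spatial_effects(
    graph: AdjacencyGraph, sigma2_s: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Exact draw from the sum-to-zero ICAR distribution.

    Uses the graph-Laplacian eigenbasis: each non-null eigendirection gets
    an independent N(0, sigma2_s / eigenvalue) coefficient, so the draw has
    covariance sigma2_s * pinv(L) and sums to zero.
    """
    if not graph.is_connected():
        raise ValueError("ICAR draws require a connected graph")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    evals, evecs = _laplacian_eig(graph)
    tol = evals.max() * graph.n * np.finfo(float).eps
    keep = evals > tol
    z = rng.standard_normal(int(keep.sum()))
    s = evecs[:, keep] @ (z * np.sqrt(sigma2_s / evals[keep]))
    return s - s.mean()


def _nearest_psd_correlation(R: np.ndarray, min_eig: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues and restore the unit diagonal."""
    evals, evecs = np.linalg.eigh(R)
    if evals.min() >= min_eig:
        return R
    evals = np.clip(evals, min_eig, None)
    A = evecs @ np.diag(evals) @ evecs.T
    d = np.sqrt(np.diag(A))
    out = A / np.outer(d, d)
    evals2 = np.linalg.eigvalsh(out)
    if evals2.min() <= 0:
        raise ValueError(
            "correlation matrix infeasible after repair; eigenvalues: "
            + np.array2string(evals2, precision=6)
        )
    return out


def simulate_indicators(
    config: SimConfig, graph: AdjacencyGraph, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Spatially autocorrelated, cross-correlated indicators plus poverty.

    Each latent column is a mixture ``w * icar_field + sqrt(1-w^2) * noise``
    of a standardised ICAR draw and white noise, giving mild spatial
    clustering; the columns are then coloured by the Cholesky factor of the
    target correlation matrix and mapped affinely to indicator scales
    (clipped to their valid ranges).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = graph.n
    k = len(_LATENT)
    w = config.indicator_spatial_weight
    if not 0.0 <= w < 1.0:
        raise ValueError("indicator_spatial_weight must lie in [0, 1)")

    G = np.empty((n, k))
    for j in range(k):
        phi = simulate_spatial_effects(graph, 1.0, rng)
        phi = phi / phi.std(ddof=1)
        G[:, j] = w * phi + np.sqrt(1.0 - w * w) * rng.standard_normal(n)

    R = _nearest_psd_correlation(config.correlation_matrix())
    Z = G @ np.linalg.cholesky(R).T

    out = pd.DataFrame({"county_id": list(graph.node_ids)})
    for j, name in enumerate(_LATENT):
        mu, sd, lo, hi = _MARGINALS[name]
        out[name] = np.clip(mu + sd * Z[:, j], lo, hi)
    return out


def simulate_outcome(
    design: DesignMatrix,
    s_true: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, SimTruth]:
    """Draw the outcome y = X beta_true + s_true + u and record the truth."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = design.n
    if s_true.shape != (n,):
        raise ValueError(
            f"s_true has shape {s_true.shape} but the design has {n} rows"
        )
    beta_vec = np.array(
        [config.beta_true.get(name, 0.0) for name in design.columns]
    )
    u = rng.standard_normal(n) * np.sqrt(config.sigma2_u_true)
    y = design.X @ beta_vec + s_true + u
    var_s = float(np.var(s_true, ddof=1))
    truth = SimTruth(
        beta_true=dict(config.beta_true),
        beta_vector=beta_vec,
        s_true=s_true.copy(),
        sigma2_s_true=config.sigma2_s_true,
        sigma2_u_true=config.sigma2_u_true,
        lambda_true=var_s / (var_s + config.sigma2_u_true),
    )
    return y, truth


def mediated_confounding_config(
    rows: int = 20, cols: int = 20, seed: int = 0
) -> SimConfig:
    """Scenario where the environment mediates the poverty gradient.

    Outcomes are driven purely by the (spatially clustered,
    poverty-correlated) indicators — no direct categorical effects — so a
    categories-only regression attributes signal to poverty quintiles and
    to the spatial residual, while the indicator regression absorbs both:
    explained variation rises, poverty coefficients shrink, and the spatial
    fraction of the residual falls.
    """
    beta = {
        "Intercept": 25.0,
        "inactivity": 15.0,
        "exercise_access": -1.0,
        "fastfood_grocery_ratio": 1.6,
        "groceries_per_head": -1.6,
        "fei": -2.3,
        "pct_restaurants_fastfood": 1.2,
        "concentration_score": -16.0,
    }
    return SimConfig(
        rows=rows,
        cols=cols,
        seed=seed,
        sigma2_s_true=0.5,
        sigma2_u_true=1.0,
        indicator_spatial_weight=0.85,
        beta_true=beta,
    )


def default_model_spec(
    outcome: str = "obesity_persons", with_indicators: bool = True,
    with_interactions: bool = True,
) -> ModelSpec:
    """The standard model declaration over the generated columns."""
    factors = (
        FactorSpec("urbanicity", "1"),
        FactorSpec("division", "New England"),
        FactorSpec("ethnicity", "White N-H"),
        FactorSpec("poverty_quintile", "1"),
    )
    interactions: tuple[tuple[str, str], ...] = ()
    if with_interactions:
        names = [f.name for f in factors]
        interactions = tuple(
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
        )
    return ModelSpec(
        outcome=outcome,
        factors=factors,
        covariates=INDICATOR_COLUMNS if with_indicators else (),
        interactions=interactions,
        include_spatial=True,
    )


def generate_dataset(
    config: SimConfig,
) -> tuple[pd.DataFrame, AdjacencyGraph, SimTruth]:
    """Generate a full county table: indicators, factors, outcome, truth.

    A pure function of the config (all randomness flows from config.seed).
    The outcome column is ``obesity_persons``; ``obesity_males`` and
    ``obesity_females`` are scaled variants (0.9x / 1.15x the covariate
    effects) with independent IID noise, mirroring the weaker male and
    stronger female environmental gradients in county data.
    """
    rng = np.random.default_rng(config.seed)
    graph = build_grid_adjacency(config.rows, config.cols, config.scheme)
    data = simulate_indicators(config, graph, rng)

    probs = config.category_probabilities
    n = graph.n

    def draw_factor(levels: tuple[str, ...], p: tuple[float, ...]) -> list[str]:
        # guarantee every level (incl. reference categories) is observed so
        # the dummy coding is well defined even on small lattices
        codes = rng.choice(len(levels), size=n, p=p)
        for _ in range(10):
            missing = [k for k in range(len(levels)) if k not in codes]
            if not missing:
                break
            slots = rng.choice(n, size=len(missing), replace=False)
            codes[slots] = missing
        return [levels[k] for k in codes]

    data["urbanicity"] = draw_factor(tuple(str(u) for u in range(1, 10)),
                                     probs["urbanicity"])
    data["division"] = draw_factor(_DIVISIONS, probs["division"])
    data["ethnicity"] = draw_factor(_ETHNICITIES, probs["ethnicity"])
    data["poverty_quintile"] = [
        str(q) for q in quintile_assign(data["poverty"].to_numpy()).labels
    ]

    spec = default_model_spec(with_interactions=False)
    # outcome column not yet present; build design from predictors only.
    # rank is not checked here: the design is only used to form X beta_true
    design = build_design(data.assign(obesity_persons=0.0), spec, check_rank=False)
    s_true = simulate_spatial_effects(graph, config.sigma2_s_true, rng)
    y, truth = simulate_outcome(design, s_true, config, rng)
    data["obesity_persons"] = y

    for name, scale in (("obesity_males", 0.9), ("obesity_females", 1.15)):
        beta_scaled = truth.beta_vector.copy()
        beta_scaled[1:] *= scale  # intercept kept
        u = rng.standard_normal(n) * np.sqrt(config.sigma2_u_true)
        data[name] = design.X @ beta_scaled + s_true + u

    return data, graph, truth


def write_dataset(
    data: pd.DataFrame,
    graph: AdjacencyGraph,
    truth: SimTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write county CSV, GAL adjacency, and the SimTruth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counties": outdir / "counties.csv",
        "adjacency": outdir / "adjacency.gal",
        "truth": outdir / "sim_truth.json",
    }
    data.to_csv(paths["counties"], index=False)
    write_adjacency(graph, paths["adjacency"], dialect="gal")
    truth.to_json(paths["truth"])
    return paths
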