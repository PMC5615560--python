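"""Construction of the seven obesogenic-environment indicators.

Covers the analysis-ready transforms: min-max rescaling of regression
covariates to [0, 1], the settlement/commuting "concentration score" (the
leading principal component of five standardised settlement indices,
signed so car-dependent sprawl scores negative), the 0-10 food environment
index that equally weights limited healthy-food access and food insecurity,
and quintile assignment with either empirical or externally fixed breaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "scale_unit",
    "concentration_score",
    "food_environment_index",
    "quintile_assign",
    "QuintileResult",
]


def scale_unit(x: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]: ``(x - min(x)) / range(x)``."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("scale_unit needs a 1-d vector of length >= 2")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("cannot rescale a constant vector (zero range)")
    return (x - lo) / (hi - lo)


def concentration_score(
    car_commute: np.ndarray,
    public_transport_commute: np.ndarray,
    walk_cycle_commute: np.ndarray,
    post1950_housing: np.ndarray,
    pop_density: np.ndarray,
) -> np.ndarray:
    """Leading principal component of five settlement/commuting indices.

    Columns are standardised (PCA on the correlation matrix, since the
    indices have incommensurable units).  The component sign is fixed so
    the loading on car commuting is negative: dispersed, car-dependent
    counties receive the most negative scores.  Returned scores have unit
    sample variance.
    """
    cols = [car_commute, public_transport_commute, walk_cycle_commute,
            post1950_housing, pop_density]
    X = np.column_stack([np.asarray(c, dtype=float) for c in cols])
    n = X.shape[0]
    if n < 6:
        raise ValueError("concentration_score needs at least 6 counties")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"input column {bad} has zero variance")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    # eigh returns ascending order; leading component is the last
    if evals[-1] - evals[-2] < 1e-10:
        raise ValueError(
            "degenerate leading eigenvalue; spectrum: "
            + np.array2string(evals[::-1], precision=6)
        )
    v = evecs[:, -1]
    if v[0] > 0:  # sign convention: negative loading on car commuting
        v = -v
    scores = Z @ v
    return scores / scores.std(ddof=1)


def food_environment_index(
    limited_access: np.ndarray, food_insecurity: np.ndarray
) -> np.ndarray:
    """0-10 food environment index from its two components.

    Each component (a percentage: limited access to healthy foods, food
    insecurity) is min-max mapped over the cohort to a [0, 10] badness
    scale, the two are averaged with equal weight, and the result is
    reversed so 10 marks the best environments and 0 the worst.  This is a
    reconstruction of the published index's stated recipe (equal weighting,
    0-10 range); pipelines holding a precomputed index can pass it through
    instead.
    """
    a = np.asarray(limited_access, dtype=float)
    b = np.asarray(food_insecurity, dtype=float)
    for name, v in (("limited_access", a), ("food_insecurity", b)):
        if np.any((v < 0) | (v > 100)):
            raise ValueError(f"{name} must lie in [0, 100]")
    bad = (scale_unit(a) + scale_unit(b)) / 2.0
    return 10.0 * (1.0 - bad)


@dataclass(frozen=True)
class QuintileResult:
    """Quintile labels (1 = lowest values) and the four interior cutpoints."""

    labels: np.ndarray
    cutpoints: tuple[float, float, float, float]


def quintile_assign(
    x: np.ndarray, breaks: tuple[float, float, float, float] | None = None
) -> QuintileResult:
    """Assign counties to quintiles of ``x``.

    By default the four cutpoints are the empirical 20/40/60/80th
    percentiles of the supplied cohort; fixed external breaks (e.g. the
    published poverty cutpoints 11.8/14.7/18/22.1) may be supplied to
    reproduce a published layout.  Intervals are lower-closed: a value
    equal to a cutpoint falls in the higher quintile.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("quintile_assign needs at least 5 values")
    if breaks is None:
        cuts = np.quantile(x, [0.2, 0.4, 0.6, 0.8])
    else:
        cuts = np.asarray(breaks, dtype=float)
        if cuts.shape != (4,) or np.any(np.diff(cuts) <= 0):
            raise ValueError("breaks must be 4 strictly increasing cutpoints")
    labels = 1 + np.searchsorted(cuts, x, side="right")
    if breaks is None:
        counts = np.bincount(labels, minlength=6)[1:]
        if np.any(counts == 0):
            raise ValueError(
                "heavy ties leave an empty quintile; tied cutpoints: "
                + np.array2string(cuts, precision=6)
            )
    return QuintileResult(labels=labels, cutpoints=tuple(float(c) for c in cuts))
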