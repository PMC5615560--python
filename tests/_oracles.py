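"""Independent oracles used by the test suite.

Each routine derives its answer from first principles (enumeration,
quadrature, closed forms) without touching the implementation paths it is
used to check.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as sla


def queen_edge_count(rows: int, cols: int) -> int:
    """Brute-force enumeration of queen-contiguity edges on a lattice."""
    cells = [(r, c) for r in range(rows) for c in range(cols)]
    edges = set()
    for r, c in cells:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) == (0, 0):
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    edges.add(frozenset({(r, c), (rr, cc)}))
    return len(edges)


def pairwise_diff_quadratic(s: np.ndarray, edges: list[tuple[int, int]]) -> float:
    """sum over undirected edges of (s_i - s_j)^2, by direct enumeration."""
    return float(sum((s[i] - s[j]) ** 2 for i, j in edges))


def sum_zero_basis(n: int) -> np.ndarray:
    """Orthonormal basis of the sum-to-zero subspace, shape (n, n-1)."""
    return sla.null_space(np.ones((1, n)))


def icar_constrained_moments(
    edges: list[tuple[int, int]], n: int, sigma2_s: float, grid: int = 4001
) -> np.ndarray:
    """Covariance of the sum-to-zero ICAR by numerical normalisation.

    Writes the pairwise-difference density on the sum-to-zero subspace,
    rotates to the eigenbasis of the restricted quadratic form (where the
    density factorises into independent 1-d kernels), and computes each
    direction's variance by numerically normalising its 1-d density on a
    wide grid.  Returns the n x n covariance of the constrained field.
    """
    L = np.zeros((n, n))
    for i, j in edges:
        L[i, i] += 1
        L[j, j] += 1
        L[i, j] -= 1
        L[j, i] -= 1
    V = sum_zero_basis(n)
    Q = V.T @ L @ V
    d, U = np.linalg.eigh(Q)
    if d.min() <= 1e-10:
        raise ValueError("graph must be connected for a proper constrained density")
    var = np.empty(len(d))
    for k, dk in enumerate(d):
        sd = np.sqrt(sigma2_s / dk)
        t = np.linspace(-10 * sd, 10 * sd, grid)
        w = np.exp(-dk * t**2 / (2 * sigma2_s))
        var[k] = np.trapezoid(t**2 * w, t) / np.trapezoid(w, t)
    cov_z = U @ np.diag(var) @ U.T
    return V @ cov_z @ V.T


def icar_constrained_moments_grid3(
    edges: list[tuple[int, int]], sigma2_s: float, half_width: float = 8.0,
    grid: int = 41,
) -> np.ndarray:
    """Full 3-d grid quadrature of the constrained density for 4-node graphs.

    A slower, even more direct cross-check of `icar_constrained_moments`:
    tabulates exp(-q(s)/(2 sigma2_s)) on a cube in sum-to-zero coordinates
    and forms covariance moments by direct summation.
    """
    n = 4
    V = sum_zero_basis(n)
    axis = np.linspace(-half_width, half_width, grid)
    Z = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 3)
    S = Z @ V.T
    q = np.zeros(len(S))
    for i, j in edges:
        q += (S[:, i] - S[:, j]) ** 2
    w = np.exp(-q / (2 * sigma2_s))
    w /= w.sum()
    cov_z = (Z * w[:, None]).T @ Z
    return V @ cov_z @ V.T


def icar_conditional_numeric(
    s: np.ndarray, i: int, edges: list[tuple[int, int]], sigma2_s: float,
    grid: int = 40001,
) -> tuple[float, float]:
    """Conditional mean/variance of s_i by 1-d numerical normalisation.

    Integrates the pairwise-difference kernel over s_i with all other
    components held fixed.
    """
    nbrs = [j for a, j in edges if a == i] + [a for a, j in edges if j == i]
    centre = np.mean([s[j] for j in nbrs])
    sd = np.sqrt(sigma2_s / len(nbrs))
    t = np.linspace(centre - 12 * sd, centre + 12 * sd, grid)
    q = np.zeros_like(t)
    for j in nbrs:
        q += (t - s[j]) ** 2
    w = np.exp(-(q - q.min()) / (2 * sigma2_s))
    norm = np.trapezoid(w, t)
    mean = np.trapezoid(t * w, t) / norm
    var = np.trapezoid((t - mean) ** 2 * w, t) / norm
    return float(mean), float(var)


def conjugate_beta_posterior(
    y: np.ndarray, X: np.ndarray, sigma2: float, prior_var: float
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form Gaussian posterior of beta with known noise variance."""
    p = X.shape[1]
    prec = X.T @ X / sigma2 + np.eye(p) / prior_var
    cov = np.linalg.inv(prec)
    mean = cov @ (X.T @ y / sigma2)
    return mean, cov


def psrf_reference(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor, written independently.

    Follows the textbook recipe step by step on explicitly split sequences.
    """
    halves = []
    for ch in chains:
        t = len(ch)
        halves.append(np.asarray(ch[: t // 2], dtype=float))
        halves.append(np.asarray(ch[t - t // 2 :], dtype=float))
    m = len(halves)
    t = len(halves[0])
    means = np.array([h.mean() for h in halves])
    variances = np.array([h.var(ddof=1) for h in halves])
    w = variances.mean()
    b = t * means.var(ddof=1)
    var_hat = (t - 1) / t * w + b / t
    return float(np.sqrt(var_hat / w))
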