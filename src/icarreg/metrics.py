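"""Variance-partition and convergence summaries for the fitted model.

Two bespoke statistics summarise each fit:

* the spatial fraction ``Lambda = var(s) / (var(s) + sigma2_u)`` — the share
  of residual variation attributable to the spatially clustered component
  (1 = fully clustered);
* percent variation explained, ``100 * (1 - total residual variation /
  total variation)``, where total residual variation is ``var(s) + sigma2_u``
  per draw and total variation is the empirical variance of the outcome.

Both are computed per retained draw — ``var(s)`` is the empirical variance
of the spatial field across counties at that draw — and summarised by
posterior mean and equal-tailed 95% interval, preserving posterior
uncertainty.  Convergence is assessed by the split-chain potential scale
reduction factor (Brooks-Gelman-Rubin), flagged at 1.1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .model import PosteriorSamples

__all__ = [
    "MetricReport",
    "lambda_stat",
    "pct_variation_explained",
    "bgr_diagnostic",
    "metric_report",
]

BGR_FLAG_THRESHOLD = 1.1


@dataclass(frozen=True)
class MetricReport:
    """Posterior summaries of Lambda and % explained, plus BGR diagnostics."""

    lambda_mean: float
    lambda_interval: tuple[float, float]
    pct_explained_mean: float
    pct_explained_interval: tuple[float, float]
    bgr: dict[str, float]
    converged: bool

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _summ(draws: np.ndarray) -> tuple[float, tuple[float, float]]:
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return float(draws.mean()), (float(lo), float(hi))


def lambda_stat(samples: PosteriorSamples) -> np.ndarray:
    """Per-draw spatial fraction Lambda = var(s)/(var(s) + sigma2_u)."""
    s = samples.pooled(samples.s)
    s2u = samples.pooled(samples.sigma2_u)
    var_s = s.var(axis=1, ddof=1)
    denom = var_s + s2u
    if np.any(denom <= 0):
        raise ValueError("var(s) + sigma2_u is zero at some draw")
    return var_s / denom


def pct_variation_explained(y: np.ndarray, samples: PosteriorSamples) -> np.ndarray:
    """Per-draw percent of outcome variation explained by the model.

    Total residual variation per draw is ``var(s) + sigma2_u``; an
    alternative using realised residuals is out of scope of this statistic
    and would require the design matrix.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != samples.s.shape[2]:
        raise ValueError("y is not aligned with the sampled spatial field")
    total = y.var(ddof=1)
    if total == 0:
        raise ValueError("outcome has zero variance")
    s = samples.pooled(samples.s)
    s2u = samples.pooled(samples.sigma2_u)
    resid = s.var(axis=1, ddof=1) + s2u
    return 100.0 * (1.0 - resid / total)


def bgr_diagnostic(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``chains`` has shape (n_chains, n_draws).  Each chain is split in half,
    and the PSRF is ``sqrt(((T-1)/T * W + B/T) / W)`` with ``W`` the mean
    within-sequence variance and ``B/T`` the between-sequence variance of
    sequence means.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    c, t = chains.shape
    if t < 10:
        raise ValueError("need >= 10 draws per chain")
    half = t // 2
    seqs = np.concatenate([chains[:, :half], chains[:, t - half :]], axis=0)
    m, tt = seqs.shape
    w = seqs.var(axis=1, ddof=1).mean()
    if w == 0:
        raise ValueError("zero within-chain variance in all chains")
    b_over_t = seqs.mean(axis=1).var(ddof=1)
    var_plus = (tt - 1) / tt * w + b_over_t
    return float(np.sqrt(var_plus / w))


def metric_report(y: np.ndarray, samples: PosteriorSamples) -> MetricReport:
    """Assemble Lambda, % explained, and per-parameter BGR for one fit."""
    lam_mean, lam_iv = _summ(lambda_stat(samples))
    pct_mean, pct_iv = _summ(pct_variation_explained(y, samples))
    bgr: dict[str, float] = {}
    for j, nm in enumerate(samples.beta_names):
        bgr[nm] = bgr_diagnostic(samples.beta[:, :, j])
    bgr["sigma2_u"] = bgr_diagnostic(samples.sigma2_u)
    if samples.sigma2_s is not None:
        bgr["sigma2_s"] = bgr_diagnostic(samples.sigma2_s)
    converged = all(v < BGR_FLAG_THRESHOLD for v in bgr.values())
    return MetricReport(
        lambda_mean=lam_mean,
        lambda_interval=lam_iv,
        pct_explained_mean=pct_mean,
        pct_explained_interval=pct_iv,
        bgr=bgr,
        converged=converged,
    )
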