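"""Design encoding and the Gibbs sampler's statistical correctness."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import icarreg as ir
from icarreg.model import FactorSpec, McmcConfig, ModelSpec

from _oracles import conjugate_beta_posterior


class TestBuildDesign:
    def test_two_level_factor(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "f": ["A", "B", "A"]})
        spec = ModelSpec(outcome="y", factors=(FactorSpec("f", "A"),))
        d = ir.build_design(df, spec)
        assert d.columns == ("Intercept", "f:B")
        assert np.allclose(d.X, [[1, 0], [1, 1], [1, 0]])

    def test_covariate_unit_scaled(self):
        df = pd.DataFrame({"y": [0.0, 0.0, 0.0], "x": [2.0, 4.0, 6.0]})
        d = ir.build_design(df, ModelSpec(outcome="y", covariates=("x",)))
        assert np.allclose(d.X[:, 1], [0, 0.5, 1])

    def test_full_spec_column_count(self, rng):
        """4 factors (9+9+4+5 levels) and 7 covariates give
        p = 1 + 8 + 8 + 3 + 4 + 7 = 31 fixed-effect columns."""
        cfg = ir.SimConfig(rows=12, cols=12, seed=0)
        data, graph, _ = ir.generate_dataset(cfg)
        d = ir.build_design(data, ir.default_model_spec(with_interactions=True))
        assert d.p == 31
        assert len(d.interactions) == 6

    def test_missing_reference_level_named(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "f": ["A", "B"]})
        spec = ModelSpec(outcome="y", factors=(FactorSpec("f", "Z"),))
        with pytest.raises(ValueError, match="'Z'"):
            ir.build_design(df, spec)

    def test_collinear_columns_named(self):
        df = pd.DataFrame(
            {"y": np.zeros(6), "x1": np.arange(6.0), "x2": 2 * np.arange(6.0)}
        )
        spec = ModelSpec(outcome="y", covariates=("x1", "x2"))
        with pytest.raises(ValueError, match="collinear"):
            ir.build_design(df, spec)

    def test_interaction_requires_declared_factor(self):
        with pytest.raises(ValueError, match="undeclared"):
            ModelSpec(
                outcome="y",
                factors=(FactorSpec("f", "A"),),
                interactions=(("f", "g"),),
            )


def small_fixed_noise_fit(n=60, p=3, seed=4, n_iter=1200):
    """IID-only model with known noise variance: every beta draw comes from
    the exact conjugate posterior."""
    r = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n)] + [r.normal(size=n) for _ in range(p - 1)])
    beta_true = np.array([1.0, -2.0, 0.5])
    sigma2 = 1.3
    y = X @ beta_true + r.normal(0, np.sqrt(sigma2), n)
    df = pd.DataFrame({"y": y, **{f"x{j}": X[:, j] for j in range(1, p)}})
    spec = ModelSpec(
        outcome="y", covariates=tuple(f"x{j}" for j in range(1, p)),
        include_spatial=False,
    )
    # covariates get unit-scaled by the design; use the design's X for the oracle
    design = ir.build_design(df, spec)
    cfg = McmcConfig(n_chains=2, n_iter=n_iter, seed=seed, fix_sigma2_u=sigma2,
                     progress_every=0)
    samples = ir.fit_gibbs(y, design, None, cfg)
    return y, design, sigma2, cfg, samples


class TestGibbsConjugateOracle:
    def test_beta_matches_closed_form_posterior(self):
        y, design, sigma2, cfg, samples = small_fixed_noise_fit()
        m, cov = conjugate_beta_posterior(y, design.X, sigma2, cfg.prior_beta_var)
        draws = samples.pooled(samples.beta)
        t = draws.shape[0]
        se = np.sqrt(np.diag(cov) / t)
        z = (draws.mean(axis=0) - m) / se
        # joint Monte-Carlo-error check across coefficients
        assert np.abs(z).max() < 4.0
        assert float(z @ z) < len(m) + 3 * np.sqrt(2 * len(m))
        assert np.allclose(draws.std(axis=0, ddof=1), np.sqrt(np.diag(cov)),
                           rtol=0.1)


@pytest.fixture(scope="module")
def small_spatial_problem():
    cfg = ir.SimConfig(rows=8, cols=8, seed=9, sigma2_s_true=2.0)
    data, graph, truth = ir.generate_dataset(cfg)
    data = ir.align_to_graph(data, graph)
    spec = ModelSpec(
        outcome="obesity_persons",
        factors=(FactorSpec("ethnicity", "White N-H"),),
        covariates=("inactivity", "concentration_score"),
        include_spatial=True,
    )
    design = ir.build_design(data, spec)
    y = data["obesity_persons"].to_numpy()
    return y, data, design, graph, spec


class TestGibbsInvariances:
    def test_location_equivariance(self, small_spatial_problem):
        """Shifting y by a constant shifts only the intercept posterior."""
        y, data, design, graph, spec = small_spatial_problem
        cfg = McmcConfig(n_chains=2, n_iter=1500, seed=2, progress_every=0)
        m1 = ir.posterior_summary(ir.fit_gibbs(y, design, graph, cfg))
        m2 = ir.posterior_summary(ir.fit_gibbs(y + 10.0, design, graph, cfg))
        diff = m2["mean"] - m1["mean"]
        assert diff["Intercept"] == pytest.approx(10.0, abs=0.5)
        others = diff.drop(["Intercept", "sigma2_u", "sigma2_s"])
        assert np.abs(others.to_numpy()).max() < 0.5

    def test_permutation_equivariance(self, small_spatial_problem):
        """Relabelling counties together with their graph nodes leaves
        posterior summaries unchanged up to Monte-Carlo error."""
        y, data, design, graph, spec = small_spatial_problem
        cfg = McmcConfig(n_chains=2, n_iter=1500, seed=3, progress_every=0)
        s1 = ir.posterior_summary(ir.fit_gibbs(y, design, graph, cfg))

        perm = np.random.default_rng(0).permutation(graph.n)
        ids = [graph.node_ids[k] for k in perm]
        g2 = ir.AdjacencyGraph.from_neighbours(
            {i: graph.neighbours[i] for i in ids}, ids
        )
        data2 = ir.align_to_graph(data, g2)
        design2 = ir.build_design(data2, spec)
        y2 = data2["obesity_persons"].to_numpy()
        s2 = ir.posterior_summary(ir.fit_gibbs(y2, design2, g2, cfg))
        betas = [n for n in s1.index if not n.startswith("sigma2")]
        assert np.allclose(
            s1.loc[betas, "mean"], s2.loc[betas, "mean"], atol=0.4
        )

    def test_spatial_variance_pinned_to_zero_reduces_to_iid(
        self, small_spatial_problem
    ):
        """With sigma2_s fixed near zero the spatial field collapses and
        beta summaries agree with the IID-model code path."""
        y, data, design, graph, spec = small_spatial_problem
        cfg = McmcConfig(n_chains=2, n_iter=1500, seed=5, fix_sigma2_s=1e-10,
                         progress_every=0)
        s_spatial = ir.posterior_summary(ir.fit_gibbs(y, design, graph, cfg))

        spec_iid = ModelSpec(
            outcome=spec.outcome, factors=spec.factors,
            covariates=spec.covariates, include_spatial=False,
        )
        design_iid = ir.build_design(data, spec_iid)
        cfg_iid = McmcConfig(n_chains=2, n_iter=1500, seed=5, progress_every=0)
        s_iid = ir.posterior_summary(ir.fit_gibbs(y, design_iid, None, cfg_iid))
        betas = [n for n in s_iid.index if n != "sigma2_u"]
        assert np.allclose(
            s_spatial.loc[betas, "mean"], s_iid.loc[betas, "mean"], atol=0.3
        )

    def test_chain_seed_independence(self, small_spatial_problem):
        """Summaries from different master seeds agree within Monte-Carlo
        error, estimated from the spread of per-chain means."""
        y, data, design, graph, spec = small_spatial_problem
        means, ses = [], []
        for seed in (11, 12):
            cfg = McmcConfig(n_chains=4, n_iter=2000, seed=seed, progress_every=0)
            samples = ir.fit_gibbs(y, design, graph, cfg)
            chain_means = samples.beta.mean(axis=1)  # (C, p)
            means.append(chain_means.mean(axis=0))
            ses.append(chain_means.std(axis=0, ddof=1) / np.sqrt(cfg.n_chains))
        tol = 3.0 * np.sqrt(ses[0] ** 2 + ses[1] ** 2) + 1e-3
        assert (np.abs(means[0] - means[1]) < tol).all()

    def test_null_slopes_covered(self):
        """With beta = 0 and no spatial signal, slope intervals cover zero
        nearly always."""
        hits, total = 0, 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 120
            df = pd.DataFrame(
                {"y": r.normal(size=n), "x1": r.normal(size=n), "x2": r.normal(size=n)}
            )
            spec = ModelSpec(outcome="y", covariates=("x1", "x2"),
                             include_spatial=False)
            design = ir.build_design(df, spec)
            cfg = McmcConfig(n_chains=2, n_iter=800, seed=seed, progress_every=0)
            summ = ir.posterior_summary(ir.fit_gibbs(df["y"].to_numpy(), design, None, cfg))
            for name in ("x1", "x2"):
                total += 1
                if summ.loc[name, "2.5%"] <= 0 <= summ.loc[name, "97.5%"]:
                    hits += 1
        # nominal 95% coverage; allow binomial fluctuation down to 90%
        assert hits >= int(0.9 * total)


class TestPosteriorSummary:
    def _samples(self, draws):
        draws = np.asarray(draws, dtype=float)[None, :, None]
        return ir.PosteriorSamples(
            beta=draws, beta_names=("b",),
            s=np.zeros((1, draws.shape[1], 2)),
            sigma2_u=np.ones((1, draws.shape[1])),
            sigma2_s=None, interaction_variances={}, interaction_effects={},
            include_spatial=False,
        )

    def test_constant_draws(self):
        summ = ir.posterior_summary(self._samples(np.full(200, 3.3)))
        assert np.allclose(summ.loc["b"].to_numpy(), 3.3)

    def test_standard_normal_draws_interval(self, rng):
        draws = rng.standard_normal(200_000)
        summ = ir.posterior_summary(self._samples(draws))
        assert summ.loc["b", "2.5%"] == pytest.approx(-1.96, abs=0.03)
        assert summ.loc["b", "97.5%"] == pytest.approx(1.96, abs=0.03)

    def test_matches_sorted_quantile_oracle(self, rng):
        draws = rng.gamma(2.0, 1.0, 5001)
        summ = ir.posterior_summary(self._samples(draws))
        srt = np.sort(draws)

        def manual_quantile(q):
            pos = q * (len(srt) - 1)
            k, frac = int(pos), pos - int(pos)
            return srt[k] + frac * (srt[min(k + 1, len(srt) - 1)] - srt[k])

        lo, hi = manual_quantile(0.025), manual_quantile(0.975)
        assert summ.loc["b", "2.5%"] == pytest.approx(lo)
        assert summ.loc["b", "97.5%"] == pytest.approx(hi)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            ir.posterior_summary(self._samples(np.ones(50)))
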