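"""Meta-analysis: effect computation, MCMC-versus-grid agreement, shrinkage
algebra and new-study prediction."""

import logging

import numpy as np
import pandas as pd
import pytest

import litbayes as lb
from litbayes.meta import MetaPosterior, conditional_posterior_mean


def _studies(rows):
    return lb.StudyTable(pd.DataFrame(rows))


class TestComputeEffects:
    def test_printed_formula_hand_example(self):
        """50/100 vs 25/100: Y = ln 2, sigma^2 = 1/50 - 1/100 + 1/25 - 1/100."""
        t = _studies({"label": ["a"], "d1": [50], "n1": [100],
                      "d0": [25], "n0": [100]})
        eff = lb.compute_effects(t)
        assert eff.y[0] == pytest.approx(np.log(2.0), abs=1e-12)
        assert eff.se[0] ** 2 == pytest.approx(0.04, abs=1e-12)

    def test_identical_arms_zero_effect(self):
        t = _studies({"label": ["a"], "d1": [30], "n1": [80],
                      "d0": [30], "n0": [80]})
        assert lb.compute_effects(t).y[0] == 0.0

    def test_zero_cell_continuity_correction(self, caplog):
        t = _studies({"label": ["z"], "d1": [10], "n1": [20],
                      "d0": [0], "n0": [20]})
        with caplog.at_level(logging.WARNING, logger="litbayes.meta"):
            eff = lb.compute_effects(t)
        assert np.isfinite(eff.y[0]) and np.isfinite(eff.se[0])
        assert eff.continuity_corrected[0]
        assert any("continuity" in r.message for r in caplog.records)
        with pytest.raises(ValueError, match="degenerate"):
            lb.compute_effects(t, continuity="none")

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            _studies({"label": ["a"], "d1": [30], "n1": [20],
                      "d0": [5], "n0": [20]})
        with pytest.raises(ValueError, match="negative"):
            _studies({"label": ["a"], "d1": [-1], "n1": [20],
                      "d0": [5], "n0": [20]})
        with pytest.raises(ValueError, match=">= 1"):
            _studies({"label": ["a"], "d1": [0], "n1": [0],
                      "d0": [5], "n0": [20]})


class TestGridOracle:
    def test_grid_density_normalized(self, toy_effects):
        g = lb.marginal_grid_oracle(toy_effects, np.linspace(-1, 2, 200),
                                    np.linspace(0, 2.5, 160))
        total = np.trapezoid(np.trapezoid(g.density, g.tau_grid, axis=1), g.mu_grid)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_tau_mode_zero_for_homogeneous_effects(self):
        eff = lb.EffectEstimates(labels=list("abcd"), y=[0.4] * 4,
                                 se=[0.2] * 4, continuity_corrected=[False] * 4)
        g = lb.marginal_grid_oracle(eff, np.linspace(-0.6, 1.4, 200),
                                    np.linspace(0, 2.0, 150))
        x, dens = g._marginal(1)
        assert np.argmax(dens) == 0

    def test_edge_mass_demands_wider_grid(self, toy_effects):
        with pytest.raises(ValueError, match="widen"):
            lb.marginal_grid_oracle(toy_effects, np.linspace(0.4, 0.45, 30),
                                    np.linspace(0, 2.5, 100))


class TestFitHierarchical:
    def test_mcmc_matches_grid_oracle_on_toy_table(self, toy_effects):
        """Agreement under a tau prior bounded at 2.5 (both routes use it);
        the near-zero-tau toy has a heavy tau tail under the default prior,
        whose SD needs a larger draw budget than a unit test warrants."""
        post = lb.fit_hierarchical(toy_effects, chains=4, iterations=5000,
                                   warmup=1000, seed=1, tau_max=2.5)
        g = lb.marginal_grid_oracle(toy_effects, np.linspace(-5.0, 6.0, 1000),
                                    np.linspace(0, 2.5, 500), tau_max=2.5)
        mu_m, mu_s = g.mu_mean_sd
        tau_m, tau_s = g.tau_mean_sd
        assert abs(post.mu_flat.mean() - mu_m) < 0.02
        assert abs(post.mu_flat.std(ddof=1) - mu_s) < 0.02
        assert abs(post.tau_flat.mean() - tau_m) < 0.02
        assert abs(post.tau_flat.std(ddof=1) - tau_s) < 0.02

    def test_fixed_effect_limit_matches_weighted_mean(self, toy_effects):
        """tau fixed at 0: mu posterior is the inverse-variance pooled
        Normal(sum(wY)/sum(w), 1/sum(w))."""
        post = lb.fit_hierarchical(toy_effects, chains=2, iterations=1500,
                                   warmup=500, seed=2, fix_tau=0.0)
        w = 1.0 / toy_effects.se**2
        mean = np.sum(w * toy_effects.y) / np.sum(w)
        sd = 1.0 / np.sqrt(np.sum(w))
        mu = post.mu_flat
        assert mu.mean() == pytest.approx(mean, abs=3 * sd / np.sqrt(200))
        assert mu.std(ddof=1) == pytest.approx(sd, rel=0.1)
        assert np.all(post.tau_flat == 0.0)

    def test_precise_study_escapes_shrinkage(self):
        """A study with tiny sigma keeps theta at its own Y."""
        eff = lb.EffectEstimates(labels=["precise", "vague1", "vague2"],
                                 y=[1.0, -0.5, 0.2], se=[0.01, 2.0, 2.0],
                                 continuity_corrected=[False] * 3)
        post = lb.fit_hierarchical(eff, chains=2, iterations=1500,
                                   warmup=500, seed=3)
        theta = post.theta_flat[:, 0]
        assert abs(np.median(theta) - 1.0) < 0.02

    def test_deterministic_given_seed(self, toy_effects):
        p1 = lb.fit_hierarchical(toy_effects, chains=2, iterations=600,
                                 warmup=300, seed=4)
        p2 = lb.fit_hierarchical(toy_effects, chains=2, iterations=600,
                                 warmup=300, seed=4)
        assert np.array_equal(p1.mu, p2.mu)
        assert np.array_equal(p1.tau, p2.tau)
        assert np.array_equal(p1.eta, p2.eta)

    def test_needs_two_studies(self):
        eff = lb.EffectEstimates(labels=["a"], y=[0.1], se=[0.2],
                                 continuity_corrected=[False])
        with pytest.raises(ValueError, match="2 studies"):
            lb.fit_hierarchical(eff)

    def test_rescaled_counts_tighten_without_recentring(self):
        """Scaling every study's counts by 10 shrinks each sigma_J; at any
        fixed heterogeneity the mu posterior must tighten and not recenter.
        (Unconditionally the comparison is confounded: smaller sigma shifts
        the tau posterior upward, so the fixed-tau fit isolates the pooling
        algebra.)"""
        cfg = lb.default_meta_template(seed=6)
        table, _ = lb.generate_meta_studies(cfg)
        big = lb.StudyTable(table.data.assign(
            d1=table.data.d1 * 10, n1=table.data.n1 * 10,
            d0=table.data.d0 * 10, n0=table.data.n0 * 10))
        kw = dict(chains=2, iterations=3000, warmup=1000, fix_tau=0.3)
        p_small = lb.fit_hierarchical(lb.compute_effects(table), seed=7, **kw)
        p_big = lb.fit_hierarchical(lb.compute_effects(big), seed=8, **kw)
        sd_s = p_small.mu_flat.std(ddof=1)
        sd_b = p_big.mu_flat.std(ddof=1)
        assert sd_b < sd_s
        # centers agree within the posterior scale of the looser fit
        assert abs(p_small.mu_flat.mean() - p_big.mu_flat.mean()) < 2 * sd_s


class TestShrinkageAlgebra:
    def test_less_precise_studies_shrink_more(self):
        y = np.full(4, 1.0)
        se = np.array([0.1, 0.3, 0.6, 1.2])
        cond = conditional_posterior_mean(y, se, mu=0.2, tau=0.4)
        dist = np.abs(cond - y)
        assert np.all(np.diff(dist) >= 0)

    def test_zero_se_limit_returns_observed(self):
        cond = conditional_posterior_mean([0.8], [1e-9], mu=0.0, tau=0.3)
        assert cond[0] == pytest.approx(0.8, abs=1e-12)

    def test_zero_tau_limit_pools_completely(self):
        cond = conditional_posterior_mean([0.8, -0.2], [0.3, 0.1], mu=0.25, tau=0.0)
        assert np.allclose(cond, 0.25)

    def test_forest_frame_contents(self, toy_effects):
        post = lb.fit_hierarchical(toy_effects, chains=2, iterations=1200,
                                   warmup=400, seed=9)
        forest = lb.shrinkage_summaries(post, toy_effects, force=True)
        assert list(forest["label"]) == toy_effects.labels
        assert np.allclose(forest["exp_y"], np.exp(toy_effects.y))
        assert (forest["shrunk_2.5"] <= forest["exp_theta_median"]).all()
        assert (forest["exp_theta_median"] <= forest["shrunk_97.5"]).all()


class TestPredictNewStudy:
    def test_zero_tau_prediction_equals_mu_interval(self, toy_effects):
        post = lb.fit_hierarchical(toy_effects, chains=2, iterations=1500,
                                   warmup=500, seed=10, fix_tau=0.0)
        _, (lo, hi) = lb.predict_new_study(post, seed=0, force=True)
        exp_mu = np.exp(post.mu_flat)
        assert lo == pytest.approx(np.percentile(exp_mu, 2.5), rel=0.02)
        assert hi == pytest.approx(np.percentile(exp_mu, 97.5), rel=0.02)

    def test_prediction_contains_mu_interval(self, toy_effects):
        post = lb.fit_hierarchical(toy_effects, chains=2, iterations=1500,
                                   warmup=500, seed=11)
        _, (lo, hi) = lb.predict_new_study(post, seed=1, force=True)
        exp_mu = np.exp(post.mu_flat)
        assert lo <= np.percentile(exp_mu, 2.5)
        assert hi >= np.percentile(exp_mu, 97.5)

    def test_large_j_matches_analytic_interval(self):
        """With 200 simulated studies, the prediction interval approaches
        exp(mu_hat +/- 1.96 sqrt(tau^2 + sd_mu^2))."""
        J = 200
        sizes = tuple((300, 300) for _ in range(J))
        cfg = lb.MetaSimConfig(n_studies=J, mu_true=0.4, tau_true=0.3,
                               study_sizes=sizes, baseline_risks=(0.3,) * J,
                               seed=12)
        table, _ = lb.generate_meta_studies(cfg)
        post = lb.fit_hierarchical(lb.compute_effects(table), chains=2,
                                   iterations=1500, warmup=500, seed=13)
        _, (lo, hi) = lb.predict_new_study(post, seed=2, force=True)
        mu_hat = post.mu_flat.mean()
        spread = np.sqrt(np.median(post.tau_flat) ** 2 + post.mu_flat.var(ddof=1))
        assert lo == pytest.approx(np.exp(mu_hat - 1.96 * spread), rel=0.1)
        assert hi == pytest.approx(np.exp(mu_hat + 1.96 * spread), rel=0.1)


def test_summaries_withheld_on_diagnostic_failure():
    post = MetaPosterior(labels=["a", "b"], mu=np.zeros((2, 10)),
                         tau=np.ones((2, 10)) * 0.1,
                         eta=np.zeros((2, 10, 2)), seed=0,
                         diagnostics_ok=False)
    with pytest.raises(RuntimeError, match="withheld"):
        post.summaries()
    assert "exp_mu_mean" in post.summaries(force=True)
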