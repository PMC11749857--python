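"""Logistic-regression engine: design construction, posterior correctness
against quadrature oracles, and the model-checking utilities."""

import logging

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import litbayes as lb
from litbayes.glm import DesignMatrix, PosteriorDraws
from litbayes.tables import FactorSpec, PatientTable


def _table(columns: dict, y, specs):
    return PatientTable(data=pd.DataFrame({"live_birth": y, **columns}),
                        specs=specs)


class TestBuildDesign:
    def test_three_levels_give_two_indicators(self):
        spec = FactorSpec("f", ("m", "a", "b"))
        t = _table({"f": ["m", "a", "b", "a"]}, [0, 1, 0, 1], [spec])
        d = lb.build_design(t, ["f"])
        assert d.p == 3  # intercept + (k-1)
        assert d.column_labels == [("intercept", ""), ("f", "a"), ("f", "b")]

    def test_reference_only_patient_row(self):
        spec = FactorSpec("f", ("m", "a", "b"))
        t = _table({"f": ["m", "a", "b"]}, [0, 1, 0], [spec])
        d = lb.build_design(t, ["f"])
        assert np.array_equal(d.X[0], [1.0, 0.0, 0.0])

    def test_paper_sized_level_sets_column_count(self):
        # factors with (3, 6, 5, 3) levels -> 1 + 2+5+4+2 = 14 columns
        rng = np.random.default_rng(0)
        specs, cols = [], {}
        for name, k in (("f1", 3), ("f2", 6), ("f3", 5), ("f4", 3)):
            levels = tuple(f"l{i}" for i in range(k))
            specs.append(FactorSpec(name, levels))
            cols[name] = rng.choice(levels, size=60)
        t = _table(cols, rng.integers(0, 2, 60), specs)
        d = lb.build_design(t, ["f1", "f2", "f3", "f4"])
        assert d.p == 14

    def test_single_observed_level_rejected_by_name(self):
        spec = FactorSpec("lonely", ("m", "a"))
        t = _table({"lonely": ["m", "m", "m"]}, [0, 1, 0], [spec])
        with pytest.raises(ValueError, match="lonely"):
            lb.build_design(t, ["lonely"])


class TestSamplePosterior:
    def test_intercept_only_recovers_success_rate(self):
        y = np.array([1] * 50 + [0] * 50)
        d = DesignMatrix(X=np.ones((100, 1)), column_labels=[("intercept", "")],
                         factors=[], factor_levels={})
        fit = lb.sample_posterior(d, y, lb.PriorSpec(intercept_scale=10.0),
                                  chains=4, iterations=1500, warmup=500, seed=2)
        p = expit(fit.flat[:, 0])
        mcse = p.std(ddof=1) / np.sqrt(lb.ess(fit).iloc[0])
        assert abs(p.mean() - 0.5) < 3 * (mcse + p.std(ddof=1) / np.sqrt(100))

    def test_two_coefficient_posterior_matches_grid_quadrature(self):
        """Posterior mean and SD agree with dense 2-d quadrature within 0.02."""
        rng = np.random.default_rng(7)
        n = 200
        x = rng.integers(0, 2, n)
        X = np.column_stack([np.ones(n), x.astype(float)])
        y = (rng.random(n) < expit(X @ [-0.3, 0.8])).astype(float)
        d = DesignMatrix(X=X, column_labels=[("intercept", ""), ("f", "b")],
                         factors=["f"], factor_levels={"f": ("a", "b")})
        fit = lb.sample_posterior(d, y, chains=4, iterations=2000, warmup=1000, seed=5)

        # independent oracle: quadrature over the 2-d posterior via the
        # sufficient statistics of the two x-groups
        n1, s1 = int((x == 1).sum()), float(y[x == 1].sum())
        n0, s0 = int((x == 0).sum()), float(y[x == 0].sum())
        b0 = np.linspace(-2.5, 2.5, 400)
        b1 = np.linspace(-2.5, 3.5, 400)
        B0, B1 = np.meshgrid(b0, b1, indexing="ij")
        ll = (s0 * B0 - n0 * np.logaddexp(0, B0)
              + s1 * (B0 + B1) - n1 * np.logaddexp(0, B0 + B1))
        logpost = ll - 0.5 * (B0 / 2.5) ** 2 - 0.5 * B1**2
        dens = np.exp(logpost - logpost.max())
        dens /= np.trapezoid(np.trapezoid(dens, b1, axis=1), b0)
        for j, B in enumerate((B0, B1)):
            m = np.trapezoid(np.trapezoid(dens * B, b1, axis=1), b0)
            v = np.trapezoid(np.trapezoid(dens * (B - m) ** 2, b1, axis=1), b0)
            assert abs(fit.flat[:, j].mean() - m) < 0.02
            assert abs(fit.flat[:, j].std(ddof=1) - np.sqrt(v)) < 0.02

    def test_same_seed_identical_draws(self):
        y = np.array([1, 0, 1, 1, 0, 0, 1, 0] * 10)
        X = np.column_stack([np.ones(80), np.tile([0.0, 1.0], 40)])
        d = DesignMatrix(X=X, column_labels=[("intercept", ""), ("f", "b")],
                         factors=["f"], factor_levels={"f": ("a", "b")})
        f1 = lb.sample_posterior(d, y, chains=2, iterations=400, warmup=200, seed=9)
        f2 = lb.sample_posterior(d, y, chains=2, iterations=400, warmup=200, seed=9)
        assert np.array_equal(f1.draws, f2.draws)

    def test_non_finite_design_column_named(self):
        X = np.column_stack([np.ones(10), np.full(10, np.nan)])
        d = DesignMatrix(X=X, column_labels=[("intercept", ""), ("f", "b")],
                         factors=["f"], factor_levels={"f": ("a", "b")})
        with pytest.raises(ValueError, match=r"f\[b\]"):
            lb.sample_posterior(d, np.zeros(10), chains=2, iterations=100, warmup=50)

    def test_separation_warned_not_fatal(self, caplog):
        y = np.array([1] * 20 + [0] * 20)
        X = np.column_stack([np.ones(40), (y == 1).astype(float)])
        d = DesignMatrix(X=X, column_labels=[("intercept", ""), ("f", "b")],
                         factors=["f"], factor_levels={"f": ("a", "b")})
        with caplog.at_level(logging.WARNING, logger="litbayes.glm"):
            fit = lb.sample_posterior(d, y, chains=2, iterations=300, warmup=150, seed=0)
        assert any("separates" in r.message for r in caplog.records)
        assert np.isfinite(fit.draws).all()

    def test_level_relabelling_equivariance(self):
        """Swapping two non-reference level labels permutes the coefficients,
        leaving the matched posteriors equal up to Monte Carlo error."""
        rng = np.random.default_rng(12)
        n = 600
        levels = ("m", "a", "b")
        vals = rng.choice(levels, size=n, p=(0.2, 0.4, 0.4))
        eff = {"m": 0.0, "a": 0.6, "b": -0.4}
        y = (rng.random(n) < expit(np.array([eff[v] for v in vals]))).astype(int)

        t1 = _table({"f": vals}, y, [FactorSpec("f", ("m", "a", "b"))])
        swap = {"a": "b", "b": "a", "m": "m"}
        t2 = _table({"f": [swap[v] for v in vals]}, y,
                    [FactorSpec("f", ("m", "a", "b"))])
        f1 = lb.sample_posterior(lb.build_design(t1, ["f"]), y,
                                 chains=2, iterations=1200, warmup=400, seed=3)
        f2 = lb.sample_posterior(lb.build_design(t2, ["f"]), y,
                                 chains=2, iterations=1200, warmup=400, seed=3)
        # f1's "a" coefficient is f2's "b" coefficient
        for lev1, lev2 in (("a", "b"), ("b", "a")):
            d1 = f1.parameter(f"f[{lev1}]")
            d2 = f2.parameter(f"f[{lev2}]")
            tol = 3 * (d1.std(ddof=1) + d2.std(ddof=1)) / np.sqrt(400)
            assert abs(d1.mean() - d2.mean()) < tol


class TestModelChecking:
    def test_bayes_r2_intercept_only_near_zero(self):
        d = DesignMatrix(X=np.ones((50, 1)), column_labels=[("intercept", "")],
                         factors=[], factor_levels={})
        draws = PosteriorDraws(names=["intercept"],
                               draws=np.zeros((2, 100, 1)), warmup=0, seed=0)
        r2, med = lb.bayes_r2(draws, d)
        assert med == 0.0 and np.all(r2 == 0.0)

    def test_bayes_r2_strong_predictor_exceeds_threshold(self):
        rng = np.random.default_rng(4)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        X = np.column_stack([np.ones(n), x])
        y = (rng.random(n) < expit(-2.0 + 4.0 * x)).astype(float)
        d = DesignMatrix(X=X, column_labels=[("intercept", ""), ("f", "b")],
                         factors=["f"], factor_levels={"f": ("a", "b")})
        fit = lb.sample_posterior(d, y, chains=2, iterations=800, warmup=400, seed=1)
        r2, med = lb.bayes_r2(fit, d)
        assert med > 0.3
        assert np.all((r2 >= 0.0) & (r2 < 1.0))

    def test_ppc_calibrated_under_the_true_model(self):
        """Fitting data simulated from the model itself yields tail
        probabilities that are rarely extreme."""
        rng = np.random.default_rng(21)
        n = 300
        inside = 0
        reps = 20
        for r in range(reps):
            x = rng.integers(0, 2, n).astype(float)
            X = np.column_stack([np.ones(n), x])
            y = (rng.random(n) < expit(0.2 + 0.5 * x)).astype(float)
            d = DesignMatrix(X=X, column_labels=[("intercept", ""), ("f", "b")],
                             factors=["f"], factor_levels={"f": ("a", "b")})
            fit = lb.sample_posterior(d, y, chains=2, iterations=500,
                                      warmup=250, seed=100 + r)
            ppc = lb.posterior_predictive_check(fit, d, y, n_rep=200, seed=r)
            inside += 0.05 < ppc.p_value < 0.95
        assert inside >= 0.9 * reps

    def test_ppc_detects_gross_misfit(self):
        y = np.array([0.0, 1.0] * 100)
        d = DesignMatrix(X=np.ones((200, 1)), column_labels=[("intercept", "")],
                         factors=[], factor_levels={})
        # posterior forced to logit p = -10: replicates are nearly all zeros
        draws = PosteriorDraws(names=["intercept"],
                               draws=np.full((2, 200, 1), -10.0), warmup=0, seed=0)
        ppc = lb.posterior_predictive_check(draws, d, y, n_rep=300, seed=5)
        assert ppc.p_value < 0.01

    def test_ppc_replicate_mean_tracks_observed_for_good_fit(self, cohort_fit):
        table, design, fit = cohort_fit
        ppc = lb.posterior_predictive_check(fit, design, table.outcome, seed=0)
        mc = ppc.replicated.std(ddof=1) / np.sqrt(ppc.replicated.size)
        sampling = np.sqrt(ppc.observed * (1 - ppc.observed) / table.n)
        assert abs(ppc.replicated.mean() - ppc.observed) < 3 * (mc + sampling)


def test_posterior_concentrates_on_truth():
    """Pooled across replicates, ~95% credible intervals cover the generating
    coefficients at calibrated rates (>= 90% per-coefficient pooled)."""
    covered = total = 0
    for r in range(8):
        cfg = lb.default_cohort_template(n_patients=3000, seed=700 + r)
        table = lb.generate_patient_table(cfg)
        design = lb.build_design(table, table.factor_names)
        fit = lb.sample_posterior(design, table.outcome, chains=2,
                                  iterations=700, warmup=350, seed=r)
        truth = table.truth["effects"]
        summ = fit.summary()
        for fac, lev in design.column_labels[1:]:
            lo, hi = summ.loc[f"{fac}[{lev}]", ["q2.5", "q97.5"]]
            covered += lo <= truth[fac][lev] <= hi
            total += 1
    assert covered / total >= 0.90


def test_default_cohort_fit_passes_diagnostics(cohort_fit):
    _, _, fit = cohort_fit
    diag = lb.check_convergence(fit)
    assert (diag["rhat"] < 1.01).all()
    assert (diag["ess"] > 400).all()
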