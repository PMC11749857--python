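"""Hierarchical Bayesian random-effects meta-analysis of log relative risks.

Per study J with treatment counts d1/n1 and control counts d0/n0 the observed
effect is the log relative risk

    Y_J = ln(d1/n1) - ln(d0/n0),      sigma_J^2 = 1/d1 - 1/n1 + 1/d0 - 1/n0,

(the delta-method variance, treated as known).  The hierarchical model is

    Y_J ~ Normal(theta_J, sigma_J^2),   theta_J ~ Normal(mu, tau^2),

with a flat prior on mu and a uniform prior on tau over [0, tau_max].
Sampling exploits the conjugate normal-normal structure: NUTS draws (mu, tau)
from the analytic theta-marginal, and each theta_J is then drawn exactly from
its conditional, so the reported draws satisfy the non-centered identity
theta_J = mu + tau * eta_J with eta_J | mu, tau standard-normal a priori.  The
module provides the MCMC fit, an exhaustive grid oracle over (mu, tau) using
the analytic marginal Y_J | mu, tau ~ Normal(mu, sigma_J^2 + tau^2),
per-study shrinkage summaries (forest-plot content), and the new-study
prediction interval exp(mu + tau * z).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .samplers import SamplerStats, nuts_sample

__all__ = [
    "StudyTable",
    "EffectEstimates",
    "MetaPosterior",
    "GridPosterior",
    "compute_effects",
    "fit_hierarchical",
    "marginal_grid_oracle",
    "shrinkage_summaries",
    "conditional_posterior_mean",
    "predict_new_study",
]

logger = logging.getLogger(__name__)

DEFAULT_TAU_MAX = 10.0
TAU_SENSITIVITY_BOUND = 5.0

_STUDY_COLUMNS = ["label", "d1", "n1", "d0", "n0"]


@dataclass
class StudyTable:
    """Per-study 2x2 live-birth counts: treatment d1/n1, control d0/n0."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data.copy()
        missing = [c for c in _STUDY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"study table missing columns {missing}")
        if "outcome_type" not in df.columns:
            df["outcome_type"] = "live_birth"
        for c in ("d1", "n1", "d0", "n0"):
            df[c] = df[c].astype(int)
        for _, row in df.iterrows():
            lab = row["label"]
            for d, n in (("d1", "n1"), ("d0", "n0")):
                if row[n] < 1:
                    raise ValueError(f"study {lab!r}: arm size {n} must be >= 1")
                if row[d] < 0:
                    raise ValueError(f"study {lab!r}: negative count {d}")
                if row[d] > row[n]:
                    raise ValueError(f"study {lab!r}: {d} exceeds {n}")
        self.data = df.reset_index(drop=True)

    @property
    def n_studies(self) -> int:
        return len(self.data)

    @property
    def labels(self) -> list[str]:
        return self.data["label"].astype(str).tolist()

    @property
    def total_enrolment(self) -> int:
        return int((self.data["n1"] + self.data["n0"]).sum())


@dataclass
class EffectEstimates:
    """Per-study log relative risks with known standard errors."""

    labels: list[str]
    y: np.ndarray
    se: np.ndarray
    continuity_corrected: np.ndarray  # bool per study

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.continuity_corrected = np.asarray(self.continuity_corrected, dtype=bool)
        if not (len(self.labels) == self.y.size == self.se.size):
            raise ValueError("inconsistent lengths")
        if not np.all(np.isfinite(self.y)) or not np.all(np.isfinite(self.se)):
            raise ValueError("non-finite effect estimates")
        if np.any(self.se <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def n_studies(self) -> int:
        return self.y.size


def compute_effects(table: StudyTable, continuity: str = "haldane") -> EffectEstimates:
    """Log relative risks and delta-method standard errors from 2x2 counts.

    Any study with a zero or arm-filling cell (d = 0 or d = n in either arm)
    gets 0.5 added to all four of its cells before the ratio is formed
    (``continuity="haldane"``); the correction is logged and recorded.  With
    ``continuity="none"`` such a study raises instead.
    """
    df = table.data
    d1 = df["d1"].to_numpy(float)
    n1 = df["n1"].to_numpy(float)
    d0 = df["d0"].to_numpy(float)
    n0 = df["n0"].to_numpy(float)
    degenerate = (d1 == 0) | (d0 == 0) | (d1 == n1) | (d0 == n0)
    if degenerate.any():
        if continuity == "none":
            raise ValueError(
                f"degenerate cells in studies {list(np.flatnonzero(degenerate))} "
                "and continuity correction disabled"
            )
        labels = [table.labels[j] for j in np.flatnonzero(degenerate)]
        logger.warning("continuity correction (+0.5 to all cells) applied to %s", labels)
        d1 = np.where(degenerate, d1 + 0.5, d1)
        n1 = np.where(degenerate, n1 + 1.0, n1)
        d0 = np.where(degenerate, d0 + 0.5, d0)
        n0 = np.where(degenerate, n0 + 1.0, n0)
    y = np.log(d1 / n1) - np.log(d0 / n0)
    var = 1.0 / d1 - 1.0 / n1 + 1.0 / d0 - 1.0 / n0
    return EffectEstimates(
        labels=table.labels, y=y, se=np.sqrt(var), continuity_corrected=degenerate
    )


@dataclass
class MetaPosterior:
    """Joint posterior draws of (mu, tau, theta_1..J) with diagnostics.

    ``theta = mu + tau * eta`` holds draw-wise by construction.  Summaries are
    withheld (raise) when the convergence diagnostics failed, unless forced.
    """

    labels: list[str]
    mu: np.ndarray      # (chains, draws)
    tau: np.ndarray     # (chains, draws)
    eta: np.ndarray     # (chains, draws, J)
    seed: int
    stats: SamplerStats | None = None
    diagnostics: pd.DataFrame | None = None
    diagnostics_ok: bool = True
    effects: EffectEstimates | None = field(default=None, repr=False)

    @property
    def theta(self) -> np.ndarray:
        return self.mu[..., None] + self.tau[..., None] * self.eta

    @property
    def mu_flat(self) -> np.ndarray:
        return self.mu.ravel()

    @property
    def tau_flat(self) -> np.ndarray:
        return self.tau.ravel()

    @property
    def theta_flat(self) -> np.ndarray:
        return self.theta.reshape(-1, self.eta.shape[2])

    def _require_converged(self, force: bool):
        if not self.diagnostics_ok and not force:
            raise RuntimeError(
                "convergence diagnostics failed; summaries withheld "
                "(pass force=True to override)"
            )

    def summaries(self, force: bool = False, seed: int = 0) -> dict:
        """Posterior summaries on the relative-risk scale: exp(mu) posterior
        mean with central 95% interval, tau median (and mean) with 95%
        interval, and the new-study 95% prediction interval for exp(theta)."""
        self._require_converged(force)
        mu, tau = self.mu_flat, self.tau_flat
        exp_mu = np.exp(mu)
        pred_draws, pred_iv = predict_new_study(self, seed=seed, force=force)
        return {
            "exp_mu_mean": float(exp_mu.mean()),
            "exp_mu_2.5": float(np.percentile(exp_mu, 2.5)),
            "exp_mu_97.5": float(np.percentile(exp_mu, 97.5)),
            "mu_mean": float(mu.mean()),
            "mu_sd": float(mu.std(ddof=1)),
            "tau_median": float(np.median(tau)),
            "tau_mean": float(tau.mean()),
            "tau_sd": float(tau.std(ddof=1)),
            "tau_2.5": float(np.percentile(tau, 2.5)),
            "tau_97.5": float(np.percentile(tau, 97.5)),
            "pred_2.5": pred_iv[0],
            "pred_97.5": pred_iv[1],
        }


def _meta_marginal_target(y, v, tau_max):
    """Log posterior and gradient of (mu, u) with theta integrated out
    analytically (Y_J | mu, tau ~ Normal(mu, sigma_J^2 + tau^2)) and
    tau = tau_max * logistic(u) carrying the uniform-prior Jacobian.

    Sampling the marginal instead of the joint (mu, tau, eta) space avoids
    the funnel geometries of both the centered and non-centered joint
    parameterizations, which otherwise bias the tau tail (non-centered NUTS
    under-visits large tau when the studies are precise: the likelihood pins
    eta on a ridge narrower than the adapted step size)."""

    def logp_and_grad(params):
        mu, u = params[0], params[1]
        sig = expit(u)
        tau = tau_max * sig
        tv = v + tau * tau
        r = y - mu
        lp = -0.5 * float(np.sum(r * r / tv)) - 0.5 * float(np.sum(np.log(tv)))
        # log-Jacobian of the logistic transform, softplus-stable
        lp += float(-np.logaddexp(0.0, u) - np.logaddexp(0.0, -u))
        g_mu = float(np.sum(r / tv))
        g_tau = float(np.sum(tau * (r * r) / (tv * tv) - tau / tv))
        dtau_du = tau_max * sig * (1.0 - sig)
        return lp, np.array([g_mu, g_tau * dtau_du + (1.0 - 2.0 * sig)])

    return logp_and_grad


def _fixed_tau_marginal_target(y, v, tau):
    tv = v + tau * tau

    def logp_and_grad(params):
        mu = params[0]
        r = y - mu
        return -0.5 * float(np.sum(r * r / tv)), np.array([float(np.sum(r / tv))])

    return logp_and_grad


def _conditional_theta_draws(y, v, mu, tau, seed):
    """Exact conjugate draws theta_J | mu, tau, Y_J ~ Normal(m_J, s_J^2) with
    m_J the precision-weighted mean and 1/s_J^2 = 1/sigma_J^2 + 1/tau^2;
    tau = 0 collapses to theta_J = mu."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x7E7A]))
    n_chains, n_draws = mu.shape
    J = y.size
    tau2 = tau[..., None] ** 2
    with np.errstate(divide="ignore"):
        w_y = 1.0 / v[None, None, :]
        w_mu = np.where(tau2 > 0, 1.0 / np.where(tau2 > 0, tau2, 1.0), np.inf)
    cond_var = 1.0 / (w_y + w_mu)
    cond_mean = (y[None, None, :] * w_y + mu[..., None] * np.where(np.isinf(w_mu), 0.0, w_mu)) * cond_var
    # tau = 0: complete pooling, theta = mu exactly
    zero = tau2 == 0
    cond_mean = np.where(zero, mu[..., None], cond_mean)
    cond_var = np.where(zero, 0.0, cond_var)
    z = rng.standard_normal((n_chains, n_draws, J))
    return cond_mean + np.sqrt(cond_var) * z


def fit_hierarchical(
    effects: EffectEstimates,
    chains: int = 4,
    iterations: int = 4000,
    warmup: int = 2000,
    seed: int = 0,
    tau_max: float = DEFAULT_TAU_MAX,
    fix_tau: float | None = None,
    target_accept: float = 0.9,
) -> MetaPosterior:
    """Sample the hierarchical model: NUTS on the analytic (mu, tau)
    marginal, exact conjugate conditional draws for each theta_J.

    ``iterations`` is the total per chain including warmup.  The prior on mu
    is flat and on tau uniform over [0, tau_max]; ``fix_tau`` runs the model
    with tau held constant (``fix_tau=0`` collapses to the fixed-effect
    model).  Convergence (split-R-hat < 1.01, ESS > 400) is checked on mu,
    tau and every theta_J; on failure the returned posterior withholds its
    summaries and the failure is logged.
    """
    from .diagnostics import check_convergence

    if effects.n_studies < 2:
        raise ValueError("need at least 2 studies")
    y, se = effects.y, effects.se
    v = se**2
    J = effects.n_studies
    w = 1.0 / v
    mu_init = float(np.sum(w * y) / np.sum(w))

    if fix_tau is not None:
        if fix_tau < 0:
            raise ValueError("fix_tau must be >= 0")
        target = _fixed_tau_marginal_target(y, v, float(fix_tau))
        draws, stats = nuts_sample(target, np.array([mu_init]), n_chains=chains,
                                   n_iter=iterations, n_warmup=warmup, seed=seed,
                                   target_accept=target_accept)
        mu = draws[:, :, 0]
        tau = np.full_like(mu, float(fix_tau))
    else:
        target = _meta_marginal_target(y, v, tau_max)
        init = np.array([mu_init, float(np.log(0.2 / (tau_max - 0.2)))])
        draws, stats = nuts_sample(target, init, n_chains=chains, n_iter=iterations,
                                   n_warmup=warmup, seed=seed,
                                   target_accept=target_accept)
        mu = draws[:, :, 0]
        tau = tau_max * expit(draws[:, :, 1])

    theta = _conditional_theta_draws(y, v, mu, tau, seed)
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = np.where(tau[..., None] > 0,
                       (theta - mu[..., None]) / np.where(tau[..., None] > 0,
                                                          tau[..., None], 1.0),
                       0.0)
    names = ["mu", "tau"] + [f"theta[{lab}]" for lab in effects.labels]
    stacked = np.concatenate([mu[..., None], tau[..., None], theta], axis=2)
    if fix_tau is not None:
        # tau is constant by construction; diagnose the sampled parameters only
        stacked = np.concatenate([mu[..., None], theta], axis=2)
        names = ["mu"] + [f"theta[{lab}]" for lab in effects.labels]
    diag = check_convergence(stacked)
    diag.index = names
    ok = bool(diag["rhat_ok"].all() and diag["ess_ok"].all())
    if not ok:
        logger.warning("meta-analysis convergence diagnostics failed:\n%s",
                       diag[~(diag["rhat_ok"] & diag["ess_ok"])])
    if fix_tau is None and np.mean(tau > TAU_SENSITIVITY_BOUND) > 1e-3:
        logger.warning(
            "posterior mass for tau above %.1f; results may be sensitive to tau_max",
            TAU_SENSITIVITY_BOUND,
        )
    return MetaPosterior(labels=effects.labels, mu=mu, tau=tau, eta=eta,
                         seed=seed, stats=stats, diagnostics=diag,
                         diagnostics_ok=ok, effects=effects)


@dataclass
class GridPosterior:
    """Quadrature posterior over (mu, tau) from the analytic marginal
    likelihood Y_J | mu, tau ~ Normal(mu, sigma_J^2 + tau^2)."""

    mu_grid: np.ndarray
    tau_grid: np.ndarray
    density: np.ndarray  # (len(mu_grid), len(tau_grid)), integrates to 1

    def _marginal(self, axis: int) -> tuple[np.ndarray, np.ndarray]:
        if axis == 0:
            x = self.mu_grid
            dens = np.trapezoid(self.density, self.tau_grid, axis=1)
        else:
            x = self.tau_grid
            dens = np.trapezoid(self.density, self.mu_grid, axis=0)
        dens = dens / np.trapezoid(dens, x)
        return x, dens

    def _moments(self, axis: int) -> tuple[float, float]:
        x, dens = self._marginal(axis)
        m = np.trapezoid(x * dens, x)
        v = np.trapezoid((x - m) ** 2 * dens, x)
        return float(m), float(np.sqrt(v))

    @property
    def mu_mean_sd(self) -> tuple[float, float]:
        return self._moments(0)

    @property
    def tau_mean_sd(self) -> tuple[float, float]:
        return self._moments(1)

    def quantile(self, axis: int, q) -> np.ndarray:
        x, dens = self._marginal(axis)
        cdf = np.concatenate([[0.0], np.cumsum(np.diff(x) * 0.5 * (dens[1:] + dens[:-1]))])
        cdf /= cdf[-1]
        return np.interp(np.atleast_1d(q), cdf, x)


def marginal_grid_oracle(
    effects: EffectEstimates,
    mu_grid: np.ndarray,
    tau_grid: np.ndarray,
    tau_max: float = DEFAULT_TAU_MAX,
    edge_tol: float = 1e-3,
) -> GridPosterior:
    """Exhaustive-grid posterior for (mu, tau), the package's independent
    check on the MCMC fit.

    Uses the analytic marginal likelihood (theta integrated out); priors match
    :func:`fit_hierarchical` (flat mu, uniform tau on [0, tau_max]).  Raises
    when normalized posterior mass touches the grid boundary (> ``edge_tol``
    of the total along any edge), which means the grids must be widened.
    """
    mu_grid = np.asarray(mu_grid, float)
    tau_grid = np.asarray(tau_grid, float)
    if np.any(tau_grid < 0) or np.any(tau_grid > tau_max):
        raise ValueError("tau grid must lie within [0, tau_max]")
    var = effects.se**2
    total_var = var[None, None, :] + (tau_grid**2)[None, :, None]
    logp = norm.logpdf(effects.y[None, None, :],
                       loc=mu_grid[:, None, None],
                       scale=np.sqrt(total_var)).sum(axis=2)
    logp -= logp.max()
    dens = np.exp(logp)
    z = np.trapezoid(np.trapezoid(dens, tau_grid, axis=1), mu_grid)
    dens = dens / z
    for edge_mass in (
        np.trapezoid(dens[0, :], tau_grid) * (mu_grid[1] - mu_grid[0]),
        np.trapezoid(dens[-1, :], tau_grid) * (mu_grid[-1] - mu_grid[-2]),
        np.trapezoid(dens[:, -1], mu_grid) * (tau_grid[-1] - tau_grid[-2]),
    ):
        if edge_mass > edge_tol:
            raise ValueError("posterior mass at grid edge; widen the grid")
    return GridPosterior(mu_grid=mu_grid, tau_grid=tau_grid, density=dens)


def conditional_posterior_mean(y, se, mu, tau) -> np.ndarray:
    """Precision-weighted conditional mean E[theta_J | mu, tau, Y_J] =
    (Y/sigma^2 + mu/tau^2) / (1/sigma^2 + 1/tau^2); the shrinkage formula.
    ``tau = 0`` gives complete pooling (mu)."""
    y = np.asarray(y, float)
    se = np.asarray(se, float)
    if tau == 0.0:
        return np.full_like(y, mu)
    w_y = 1.0 / se**2
    w_mu = 1.0 / tau**2
    return (y * w_y + mu * w_mu) / (w_y + w_mu)


def shrinkage_summaries(post: MetaPosterior, effects: EffectEstimates | None = None,
                        force: bool = False) -> pd.DataFrame:
    """Forest-plot content: per study the raw relative risk exp(Y_J) with its
    95% CI, the shrunk posterior median of exp(theta_J) with its 95% credible
    interval, and the conditional-mean diagnostic evaluated at the posterior
    medians of (mu, tau)."""
    post._require_converged(force)
    effects = effects or post.effects
    if effects is None:
        raise ValueError("effect estimates required for the raw intervals")
    theta = post.theta_flat
    mu_med = float(np.median(post.mu_flat))
    tau_med = float(np.median(post.tau_flat))
    cond = conditional_posterior_mean(effects.y, effects.se, mu_med, tau_med)
    q = np.percentile(np.exp(theta), [2.5, 50.0, 97.5], axis=0)
    return pd.DataFrame(
        {
            "label": effects.labels,
            "exp_y": np.exp(effects.y),
            "raw_2.5": np.exp(effects.y - 1.96 * effects.se),
            "raw_97.5": np.exp(effects.y + 1.96 * effects.se),
            "exp_theta_median": q[1],
            "shrunk_2.5": q[0],
            "shrunk_97.5": q[2],
            "conditional_mean": cond,
        }
    )


def predict_new_study(post: MetaPosterior, seed: int = 0,
                      force: bool = False) -> tuple[np.ndarray, tuple[float, float]]:
    """Draws and central 95% interval of exp(theta_new) for a hypothetical
    future study: theta_new = mu + tau * z with fresh z ~ N(0, 1) per draw."""
    post._require_converged(force)
    rng = np.random.default_rng(seed)
    mu, tau = post.mu_flat, post.tau_flat
    theta_new = mu + tau * rng.standard_normal(mu.size)
    lo, hi = np.percentile(np.exp(theta_new), [2.5, 97.5])
    return np.exp(theta_new), (float(lo), float(hi))
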