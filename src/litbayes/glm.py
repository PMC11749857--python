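"""Bayesian logistic regression over dummy-coded categorical factors.

The likelihood is Bernoulli with a logit link,

    ln( p / (1 - p) ) = beta0 + sum_i beta_i * 1[x_i = level],

with one indicator per non-reference level of each included factor and
independent normal priors on all coefficients (default N(0, 1) per level,
N(0, 2.5) on the intercept).  Sampling is by NUTS (see
:mod:`litbayes.samplers`); model checking utilities (Bayesian R-squared and
posterior predictive checks for a binary outcome) live here, while split-R-hat
and effective sample size are in :mod:`litbayes.diagnostics`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .samplers import SamplerStats, nuts_sample
from .tables import PatientTable

__all__ = [
    "DesignMatrix",
    "PriorSpec",
    "PosteriorDraws",
    "PPCResult",
    "build_design",
    "sample_posterior",
    "bayes_r2",
    "posterior_predictive_check",
]

logger = logging.getLogger(__name__)

INTERCEPT_LABEL = ("intercept", "")


@dataclass
class DesignMatrix:
    """Dense design: intercept column first, then one indicator per
    non-reference level of each included factor, in declaration order."""

    X: np.ndarray
    column_labels: list[tuple[str, str]]  # (factor, level); intercept first
    factors: list[str]
    factor_levels: dict[str, tuple[str, ...]]  # full level sets incl. reference

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.column_labels):
            raise ValueError("X shape does not match column labels")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def names(self) -> list[str]:
        out = []
        for fac, lev in self.column_labels:
            out.append("intercept" if (fac, lev) == INTERCEPT_LABEL else f"{fac}[{lev}]")
        return out

    def columns_for(self, factor: str) -> list[int]:
        return [j for j, (f, _) in enumerate(self.column_labels) if f == factor]


@dataclass
class PriorSpec:
    """Independent normal priors: one (location, scale) per coefficient.

    ``coef_loc``/``coef_scale`` apply to every level indicator unless
    overridden per column in ``overrides`` (keyed by ``"factor[level]"``),
    which is how literature-derived informative priors can be supplied.
    """

    coef_loc: float = 0.0
    coef_scale: float = 1.0
    intercept_loc: float = 0.0
    intercept_scale: float = 2.5
    overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.coef_scale <= 0 or self.intercept_scale <= 0:
            raise ValueError("prior scales must be positive")
        for k, (_, s) in self.overrides.items():
            if s <= 0:
                raise ValueError(f"prior scale for {k!r} must be positive")

    def location_scale(self, design: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
        loc = np.full(design.p, self.coef_loc)
        scale = np.full(design.p, self.coef_scale)
        names = design.names
        for j, name in enumerate(names):
            if name == "intercept":
                loc[j], scale[j] = self.intercept_loc, self.intercept_scale
            if name in self.overrides:
                loc[j], scale[j] = self.overrides[name]
        return loc, scale


@dataclass
class PosteriorDraws:
    """MCMC output: draws indexed (chain, iteration, parameter) plus the
    sampler metadata needed to reproduce and diagnose the run."""

    names: list[str]
    draws: np.ndarray  # (n_chains, n_post_warmup, n_params)
    warmup: int
    seed: int
    stats: SamplerStats | None = None

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.names):
            raise ValueError("draws must have shape (chains, iterations, parameters)")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    @property
    def flat(self) -> np.ndarray:
        """Draws pooled across chains, shape (n_draws, n_params)."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def parameter(self, name: str) -> np.ndarray:
        return self.flat[:, self.names.index(name)]

    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD, central quantiles, split-R-hat and ESS."""
        from .diagnostics import ess, split_rhat

        flat = self.flat
        q = np.percentile(flat, [2.5, 50.0, 97.5], axis=0)
        return pd.DataFrame(
            {
                "mean": flat.mean(axis=0),
                "sd": flat.std(axis=0, ddof=1),
                "q2.5": q[0],
                "median": q[1],
                "q97.5": q[2],
                "rhat": split_rhat(self).to_numpy(),
                "ess": ess(self).to_numpy(),
            },
            index=self.names,
        )


def build_design(table: PatientTable, included_factors: list[str]) -> DesignMatrix:
    """Dummy-code the requested factors of a patient table.

    Column order is deterministic: intercept, then for each factor in the
    order given, its non-reference levels in declared order.  A factor whose
    observed column takes a single value carries no information and is
    rejected by name.
    """
    for f in included_factors:
        table.spec(f)  # raises KeyError on unknown factor
    n = table.n
    cols = [np.ones(n)]
    labels: list[tuple[str, str]] = [INTERCEPT_LABEL]
    level_sets: dict[str, tuple[str, ...]] = {}
    for f in included_factors:
        spec = table.spec(f)
        values = table.data[f].astype(str).to_numpy()
        if len(np.unique(values)) < 2:
            raise ValueError(
                f"factor {f!r} has a single observed level and cannot be dummy-coded"
            )
        level_sets[f] = spec.levels
        for lev in spec.levels[1:]:
            cols.append((values == lev).astype(float))
            labels.append((f, lev))
    X = np.column_stack(cols)
    return DesignMatrix(X=X, column_labels=labels,
                        factors=list(included_factors), factor_levels=level_sets)


def _check_separation(X: np.ndarray, y: np.ndarray, names: list[str]) -> None:
    """Warn when a level indicator perfectly predicts the outcome; the proper
    normal prior keeps the posterior well-defined, so this is not an error."""
    for j in range(1, X.shape[1]):
        mask = X[:, j] > 0
        if mask.any():
            ys = y[mask]
            if ys.min() == ys.max():
                logger.warning(
                    "column %s separates the outcome (all y = %d at this level); "
                    "the prior regularizes the fit", names[j], int(ys[0])
                )


def _bernoulli_logit_target(X, y, loc, scale):
    inv_var = 1.0 / scale**2
    Xt = np.ascontiguousarray(X.T)

    def logp_and_grad(beta):
        eta = X @ beta
        # log-lik: y*eta - log(1 + e^eta), stable via logaddexp
        ll = float(np.dot(y, eta) - np.logaddexp(0.0, eta).sum())
        resid = y - expit(eta)
        dev = beta - loc
        lp = ll - 0.5 * float(np.dot(dev * inv_var, dev))
        grad = Xt @ resid - dev * inv_var
        return lp, grad

    return logp_and_grad


def sample_posterior(
    design: DesignMatrix,
    y: np.ndarray,
    prior: PriorSpec | None = None,
    chains: int = 4,
    iterations: int = 4000,
    warmup: int = 2000,
    seed: int = 0,
    target_accept: float = 0.8,
) -> PosteriorDraws:
    """Sample the logistic-regression posterior with NUTS.

    ``iterations`` is the total per chain including ``warmup`` (so the default
    4 chains x 4000 iterations with 2000 warmup yields 8000 posterior draws).
    Deterministic given ``seed``.
    """
    prior = prior or PriorSpec()
    y = np.asarray(y, dtype=float).ravel()
    if design.n != y.size:
        raise ValueError("design rows do not match outcome length")
    if not set(np.unique(y)).issubset({0.0, 1.0}):
        raise ValueError("outcome must be coded 0/1")
    bad = ~np.isfinite(design.X).all(axis=0)
    if bad.any():
        name = design.names[int(np.flatnonzero(bad)[0])]
        raise ValueError(f"non-finite values in design column {name!r}")
    _check_separation(design.X, y, design.names)
    loc, scale = prior.location_scale(design)

    # QR reparameterization: sample in gamma with X beta = Z gamma, where
    # Z = sqrt(n) Q has near-orthonormal unit-scale columns.  This removes
    # the strong intercept/indicator correlations of dummy coding and keeps
    # NUTS trajectories short; draws are mapped back to beta afterwards.
    n = design.n
    Q, R = np.linalg.qr(design.X)
    rdiag = np.abs(np.diag(R))
    if rdiag.min() > 1e-8 * rdiag.max():
        Z = Q * np.sqrt(n)
        A = np.sqrt(n) * np.linalg.inv(R)  # beta = A gamma
    else:
        # rank-deficient design (e.g. duplicated columns): the proper prior
        # still identifies beta, so sample in the original basis
        Z = design.X
        A = np.eye(design.p)

    target_beta = _bernoulli_logit_target(design.X, y, loc, scale)
    At = A.T

    def target(gamma):
        lp, g_beta = target_beta(A @ gamma)
        return lp, At @ g_beta

    # Fisher-information diagonal at p = 1/2 as the initial inverse mass.
    prior_prec = At @ ((1.0 / scale**2)[:, None] * A)
    info = 0.25 * np.sum(Z**2, axis=0) + np.diag(prior_prec)
    gamma0 = np.linalg.solve(A, loc)
    draws_gamma, stats = nuts_sample(
        target, init=gamma0, n_chains=chains, n_iter=iterations,
        n_warmup=warmup, seed=seed, target_accept=target_accept,
        inv_mass0=1.0 / info, jitter_init=0.2,
    )
    draws = draws_gamma @ At
    return PosteriorDraws(names=design.names, draws=draws, warmup=warmup,
                          seed=seed, stats=stats)


def bayes_r2(draws: PosteriorDraws, design: DesignMatrix) -> tuple[np.ndarray, float]:
    """Per-draw Bayesian R-squared on the probability scale.

    For each posterior draw, R2 = var(p_hat) / (var(p_hat) + mean(p_hat(1-p_hat))),
    i.e. explained variance over explained plus Bernoulli residual variance.
    Returns the vector of per-draw values and their median.
    """
    beta = draws.flat
    r2 = np.empty(beta.shape[0])
    for s in range(beta.shape[0]):
        p = expit(design.X @ beta[s])
        vfit = p.var()
        r2[s] = vfit / (vfit + np.mean(p * (1.0 - p)))
    return r2, float(np.median(r2))


@dataclass
class PPCResult:
    """Posterior predictive check for the overall success proportion, with
    per-factor-level proportions as secondary statistics."""

    observed: float
    replicated: np.ndarray
    p_value: float  # P(T_rep >= T_obs)
    level_observed: dict[str, float]
    level_p_values: dict[str, float]


def posterior_predictive_check(
    draws: PosteriorDraws,
    design: DesignMatrix,
    y: np.ndarray,
    n_rep: int = 500,
    seed: int = 0,
) -> PPCResult:
    """Simulate replicated outcomes from the posterior predictive and compare
    the observed success proportion with its replicate distribution.

    The tail probability is P(T_rep >= T_obs); values near 0 or 1 indicate
    misfit of the overall rate.  Per-level proportions are checked the same
    way for every non-reference design column.
    """
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    flat = draws.flat
    idx = np.linspace(0, flat.shape[0] - 1, min(n_rep, flat.shape[0])).astype(int)
    reps = np.empty(idx.size)
    names = design.names
    level_masks = {names[j]: design.X[:, j] > 0 for j in range(1, design.p)}
    level_reps = {k: np.empty(idx.size) for k in level_masks}
    for r, s in enumerate(idx):
        p = expit(design.X @ flat[s])
        y_rep = rng.random(p.size) < p
        reps[r] = y_rep.mean()
        for k, mask in level_masks.items():
            level_reps[k][r] = y_rep[mask].mean() if mask.any() else np.nan
    observed = float(y.mean())
    # mid-p to keep the statistic symmetric under ties
    p_val = float(np.mean(reps > observed) + 0.5 * np.mean(reps == observed))
    level_obs = {k: float(y[m].mean()) if m.any() else np.nan for k, m in level_masks.items()}
    level_p = {
        k: float(np.mean(level_reps[k] > level_obs[k]) + 0.5 * np.mean(level_reps[k] == level_obs[k]))
        for k in level_masks
    }
    return PPCResult(observed=observed, replicated=reps, p_value=p_val,
                     level_observed=level_obs, level_p_values=level_p)
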