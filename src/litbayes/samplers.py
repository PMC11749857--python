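"""No-U-Turn sampler with dual-averaging step-size and diagonal mass adaptation.

A compact, dependency-free NUTS implementation used by every model in the
package (logistic regression and the hierarchical meta-analysis).  The target
is supplied as a callable returning the joint log density and its gradient in
an unconstrained parameterization; constrained parameters (e.g. a
between-study SD with a uniform prior) are transformed by the caller, with the
Jacobian folded into the log density.

Chains are run sequentially; each chain draws from an independent
``numpy.random.Generator`` spawned deterministically from the root seed, so a
run is bit-reproducible given ``(seed, chains, iterations)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["SamplerStats", "nuts_sample"]

# Hamiltonians whose error exceeds this are treated as divergent transitions.
_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class SamplerStats:
    """Per-chain sampler metadata recorded during a NUTS run."""

    step_size: list[float] = field(default_factory=list)
    mean_accept: list[float] = field(default_factory=list)
    divergences: list[int] = field(default_factory=list)
    max_treedepth_hits: list[int] = field(default_factory=list)


def _find_reasonable_epsilon(logp_and_grad, theta, inv_mass, rng):
    """Coarse initial step size: double/halve until the one-step acceptance
    probability crosses 0.5 (Hoffman & Gelman initialization heuristic)."""
    eps = 1.0
    lp, grad = logp_and_grad(theta)
    p = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * np.sum(inv_mass * p * p)

    def one_step(eps):
        p1 = p + 0.5 * eps * grad
        theta1 = theta + eps * inv_mass * p1
        lp1, grad1 = logp_and_grad(theta1)
        p1 = p1 + 0.5 * eps * grad1
        return lp1 - 0.5 * np.sum(inv_mass * p1 * p1)

    h1 = one_step(eps)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        h1 = one_step(eps)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


def _leapfrog(logp_and_grad, theta, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    theta = theta + eps * inv_mass * p
    lp, grad = logp_and_grad(theta)
    p = p + 0.5 * eps * grad
    return theta, p, lp, grad


def _build_tree(logp_and_grad, theta, p, lp, grad, logu, v, j, eps, inv_mass, h0):
    """Recursive doubling of the NUTS trajectory (slice-sampling variant)."""
    if j == 0:
        theta1, p1, lp1, grad1 = _leapfrog(logp_and_grad, theta, p, grad, v * eps, inv_mass)
        joint = lp1 - 0.5 * np.sum(inv_mass * p1 * p1)
        if not np.isfinite(joint):
            joint = -np.inf
        n1 = int(logu <= joint)
        s1 = int(logu < joint + _DIVERGENCE_THRESHOLD)
        div = int(s1 == 0)
        alpha = min(1.0, np.exp(min(0.0, joint - h0)))
        return (theta1, p1, lp1, grad1, theta1, p1, lp1, grad1,
                theta1, lp1, grad1, n1, s1, alpha, 1, div)
    (theta_m, p_m, lp_m, grad_m, theta_p, p_p, lp_p, grad_p,
     theta_c, lp_c, grad_c, n1, s1, alpha, n_alpha, div) = _build_tree(
        logp_and_grad, theta, p, lp, grad, logu, v, j - 1, eps, inv_mass, h0)
    if s1 == 1:
        if v == -1:
            (theta_m, p_m, lp_m, grad_m, _, _, _, _,
             theta_c2, lp_c2, grad_c2, n2, s2, alpha2, n_alpha2, div2) = _build_tree(
                logp_and_grad, theta_m, p_m, lp_m, grad_m, logu, v, j - 1, eps, inv_mass, h0)
        else:
            (_, _, _, _, theta_p, p_p, lp_p, grad_p,
             theta_c2, lp_c2, grad_c2, n2, s2, alpha2, n_alpha2, div2) = _build_tree(
                logp_and_grad, theta_p, p_p, lp_p, grad_p, logu, v, j - 1, eps, inv_mass, h0)
        if n1 + n2 > 0 and _build_tree.rng.random() < n2 / (n1 + n2):
            theta_c, lp_c, grad_c = theta_c2, lp_c2, grad_c2
        alpha += alpha2
        n_alpha += n_alpha2
        div += div2
        dtheta = theta_p - theta_m
        s1 = s2 * int(np.dot(dtheta, inv_mass * p_m) >= 0) * int(np.dot(dtheta, inv_mass * p_p) >= 0)
        n1 += n2
    return (theta_m, p_m, lp_m, grad_m, theta_p, p_p, lp_p, grad_p,
            theta_c, lp_c, grad_c, n1, s1, alpha, n_alpha, div)


def _run_chain(logp_and_grad, init, n_iter, n_warmup, rng, max_treedepth, target_accept,
               inv_mass0=None):
    dim = init.size
    theta = init.astype(float).copy()
    inv_mass = np.ones(dim) if inv_mass0 is None else np.asarray(inv_mass0, float).copy()
    lp, grad = logp_and_grad(theta)
    if not np.isfinite(lp):
        raise ValueError("log density is not finite at the initial point")

    eps = _find_reasonable_epsilon(logp_and_grad, theta, inv_mass, rng)
    # Dual-averaging state (Nesterov primal averaging as in Stan).
    mu_da = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # Warmup phases: step size only / mass-matrix windows / step size only.
    phase1 = max(1, int(0.15 * n_warmup))
    phase3 = max(1, int(0.10 * n_warmup))
    window_end = n_warmup - phase3
    window_samples: list[np.ndarray] = []
    # Doubling windows for mass adaptation, Stan-style.
    window_bounds = []
    w = max(25, int(0.25 * (window_end - phase1)))
    pos = phase1 + w
    while pos < window_end:
        window_bounds.append(min(pos, window_end))
        w *= 2
        pos = pos + w
    window_bounds.append(window_end)

    draws = np.empty((n_iter - n_warmup, dim))
    divergences = 0
    depth_hits = 0
    accept_sum = 0.0
    accept_n = 0
    da_count = 0

    for it in range(n_iter):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(inv_mass * p0 * p0)
        logu = h0 + np.log(rng.random())
        theta_m = theta_p = theta
        p_m = p_p = p0
        lp_m = lp_p = lp
        grad_m = grad_p = grad
        j = 0
        n = 1
        s = 1
        alpha, n_alpha = 0.0, 1
        _build_tree.rng = rng
        while s == 1:
            v = 1 if rng.random() < 0.5 else -1
            if v == -1:
                (theta_m, p_m, lp_m, grad_m, _, _, _, _,
                 theta_c, lp_c, grad_c, n1, s1, alpha, n_alpha, div) = _build_tree(
                    logp_and_grad, theta_m, p_m, lp_m, grad_m, logu, v, j, eps, inv_mass, h0)
            else:
                (_, _, _, _, theta_p, p_p, lp_p, grad_p,
                 theta_c, lp_c, grad_c, n1, s1, alpha, n_alpha, div) = _build_tree(
                    logp_and_grad, theta_p, p_p, lp_p, grad_p, logu, v, j, eps, inv_mass, h0)
            if s1 == 1 and rng.random() < min(1.0, n1 / n):
                theta, lp, grad = theta_c, lp_c, grad_c
            n += n1
            dtheta = theta_p - theta_m
            s = s1 * int(np.dot(dtheta, inv_mass * p_m) >= 0) * int(np.dot(dtheta, inv_mass * p_p) >= 0)
            j += 1
            if div > 0 or j >= max_treedepth:
                depth_hits += int(j >= max_treedepth and it >= n_warmup)
                divergences += int(div > 0 and it >= n_warmup)
                break
        accept_prob = alpha / max(n_alpha, 1)

        if it < n_warmup:
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_prob)
            log_eps = mu_da - np.sqrt(da_count) / gamma * h_bar
            eta = da_count ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = np.exp(log_eps)
            if phase1 <= it < window_end:
                window_samples.append(theta.copy())
                if (it + 1) in window_bounds and len(window_samples) >= 10:
                    samp = np.asarray(window_samples)
                    var = samp.var(axis=0, ddof=1)
                    nw = samp.shape[0]
                    # Regularize towards unit metric as Stan does.
                    inv_mass = (nw / (nw + 5.0)) * var + (5.0 / (nw + 5.0)) * 1e-3
                    inv_mass = np.maximum(inv_mass, 1e-10)
                    window_samples = []
                    eps = _find_reasonable_epsilon(logp_and_grad, theta, inv_mass, rng)
                    mu_da = np.log(10.0 * eps)
                    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            draws[it - n_warmup] = theta
            accept_sum += accept_prob
            accept_n += 1

    return draws, {
        "step_size": float(eps),
        "mean_accept": accept_sum / max(accept_n, 1),
        "divergences": divergences,
        "max_treedepth_hits": depth_hits,
    }


def nuts_sample(
    logp_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    init: np.ndarray | Sequence[float],
    n_chains: int = 4,
    n_iter: int = 4000,
    n_warmup: int = 2000,
    seed: int = 0,
    max_treedepth: int = 10,
    target_accept: float = 0.8,
    jitter_init: float = 0.5,
    inv_mass0: np.ndarray | None = None,
) -> tuple[np.ndarray, SamplerStats]:
    """Draw from a target density with NUTS.

    Parameters
    ----------
    logp_and_grad
        Callable mapping an unconstrained parameter vector to
        ``(log_density, gradient)``.
    init
        Initialization point; each chain starts from ``init`` plus uniform
        jitter of half-width ``jitter_init`` (chain 0 starts exactly at
        ``init``) so chains are overdispersed for convergence diagnostics.
    n_iter, n_warmup
        Total iterations per chain, of which the first ``n_warmup`` adapt the
        step size and diagonal mass matrix and are discarded.
    seed
        Root seed; per-chain generators are spawned from it.
    inv_mass0
        Optional initial diagonal inverse mass (posterior variance guess,
        e.g. an inverse Fisher information diagonal); refined during warmup.

    Returns
    -------
    draws : ndarray of shape (n_chains, n_iter - n_warmup, dim)
    stats : SamplerStats
    """
    init = np.atleast_1d(np.asarray(init, dtype=float))
    if n_warmup >= n_iter:
        raise ValueError("n_warmup must be smaller than n_iter")
    if n_chains < 1:
        raise ValueError("need at least one chain")
    seqs = np.random.SeedSequence(seed).spawn(n_chains)
    all_draws = np.empty((n_chains, n_iter - n_warmup, init.size))
    stats = SamplerStats()
    for c, seq in enumerate(seqs):
        rng = np.random.default_rng(seq)
        start = init.copy()
        if c > 0 and jitter_init > 0:
            start = start + rng.uniform(-jitter_init, jitter_init, size=init.size)
        draws, st = _run_chain(
            logp_and_grad, start, n_iter, n_warmup, rng, max_treedepth, target_accept,
            inv_mass0=inv_mass0,
        )
        all_draws[c] = draws
        stats.step_size.append(st["step_size"])
        stats.mean_accept.append(st["mean_accept"])
        stats.divergences.append(st["divergences"])
        stats.max_treedepth_hits.append(st["max_treedepth_hits"])
    return all_draws, stats
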