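"""Projection predictive feature selection for the categorical logistic model.

The reference model is the full-factor Bayesian logistic fit.  A submodel's
coefficients are not re-estimated from data: for each (thinned) reference
draw s, the submodel coefficient vector minimizes the KL divergence from the
reference Bernoulli predictive to the submodel predictive.  Operationally
that is a logistic fit with the reference fitted probabilities mu_n^(s) as
soft targets, solved by damped Newton iterations.  A greedy forward search
ranks factors by the projected predictive score, and the resulting path is
scored honestly by stratified K-fold cross-validation (held-out accuracy and
ELPD per model size, mean and SD across folds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .glm import DesignMatrix, PosteriorDraws, PriorSpec, build_design, sample_posterior
from .tables import PatientTable

__all__ = ["ProjectedSubmodel", "SelectionPath", "project", "forward_search", "evaluate_path"]

logger = logging.getLogger(__name__)

_PCLIP = 1e-12


@dataclass
class ProjectedSubmodel:
    """Projection of the reference posterior onto a subset of factors."""

    included_factors: list[str]
    column_labels: list[tuple[str, str]]
    coefs: np.ndarray          # (n_proj_draws, p_sub)
    probs: np.ndarray          # (n_proj_draws, n) projected predictive probabilities
    kl: np.ndarray             # per-draw total KL from the reference predictive
    draw_indices: np.ndarray   # which reference draws were projected
    converged: np.ndarray      # per-draw Newton convergence flag

    @property
    def n_draws(self) -> int:
        return self.coefs.shape[0]


@dataclass
class SelectionPath:
    """Forward-search ranking with per-size cross-validated metrics.

    Sizes run 0..K where size 0 is the intercept-only model and size k adds
    ``ranked_factors[k-1]``.  Metric arrays are filled by
    :func:`evaluate_path`; ``search_scores`` are the in-sample projected
    predictive scores used during the greedy search.
    """

    ranked_factors: list[str]
    candidate_factors: list[str]
    search_scores: np.ndarray  # per size 0..K, in-sample projected log-score
    acc_mean: np.ndarray | None = None
    acc_sd: np.ndarray | None = None
    elpd_mean: np.ndarray | None = None
    elpd_sd: np.ndarray | None = None
    reference_accuracy: float | None = None
    reference_elpd: float | None = None
    folds: int | None = None

    def __post_init__(self):
        if len(set(self.ranked_factors)) != len(self.ranked_factors):
            raise ValueError("ranked_factors contains duplicates")

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(len(self.ranked_factors) + 1)

    def to_frame(self) -> pd.DataFrame:
        """CSV-ready table: size, factor added, accuracy and ELPD (mean, SD)."""
        k = len(self.ranked_factors)
        nan = np.full(k + 1, np.nan)
        return pd.DataFrame(
            {
                "size": self.sizes,
                "factor_added": [""] + list(self.ranked_factors),
                "acc_mean": self.acc_mean if self.acc_mean is not None else nan,
                "acc_sd": self.acc_sd if self.acc_sd is not None else nan,
                "elpd_mean": self.elpd_mean if self.elpd_mean is not None else nan,
                "elpd_sd": self.elpd_sd if self.elpd_sd is not None else nan,
            }
        )


def _submodel_columns(ref_design: DesignMatrix, sub_factors: list[str]) -> list[int]:
    cols = [0]  # intercept first
    for f in sub_factors:
        cols.extend(ref_design.columns_for(f))
    return cols


def _kl_bernoulli(mu: np.ndarray, q: np.ndarray) -> float:
    mu = np.clip(mu, _PCLIP, 1 - _PCLIP)
    q = np.clip(q, _PCLIP, 1 - _PCLIP)
    return float(np.sum(mu * np.log(mu / q) + (1 - mu) * np.log((1 - mu) / (1 - q))))


def _soft_logistic_fit(X: np.ndarray, mu: np.ndarray, tol: float = 1e-10,
                       max_iter: int = 100) -> tuple[np.ndarray, bool]:
    """Newton solve of the KL projection: minimize over b the Bernoulli KL
    from targets mu to expit(X b).  Damped (step-halving + ridge retry)."""
    p = X.shape[1]
    b = np.zeros(p)
    ridge = 0.0
    obj = _kl_bernoulli(mu, expit(X @ b))
    for _ in range(max_iter):
        q = expit(X @ b)
        grad = X.T @ (q - mu)
        w = np.clip(q * (1 - q), 1e-10, None)
        H = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            ridge = max(ridge * 10, 1e-6)
            continue
        # step-halving line search on the KL objective
        for _ in range(30):
            b_new = b - step
            obj_new = _kl_bernoulli(mu, expit(X @ b_new))
            if obj_new <= obj + 1e-14:
                break
            step *= 0.5
        moved = np.max(np.abs(b_new - b))
        b, obj = b_new, obj_new
        if moved < tol or np.max(np.abs(grad)) < tol:
            return b, True
    if ridge == 0.0:
        # retry once with damping before flagging non-convergence
        logger.warning("projection Newton did not converge; retrying with ridge damping")
        Xc = X
        b2, ok = _soft_logistic_fit_ridged(Xc, mu)
        return b2, ok
    return b, False


def _soft_logistic_fit_ridged(X, mu, lam: float = 1e-6, max_iter: int = 200):
    p = X.shape[1]
    b = np.zeros(p)
    for _ in range(max_iter):
        q = expit(X @ b)
        grad = X.T @ (q - mu) + lam * b
        w = np.clip(q * (1 - q), 1e-10, None)
        H = (X * w[:, None]).T @ X + lam * np.eye(p)
        step = np.linalg.solve(H, grad)
        b -= step
        if np.max(np.abs(step)) < 1e-9:
            return b, True
    return b, False


def _thin_indices(total: int, k: int) -> np.ndarray:
    return np.unique(np.linspace(0, total - 1, min(k, total)).astype(int))


def project(
    reference: PosteriorDraws,
    ref_design: DesignMatrix,
    sub_factors: list[str],
    n_proj_draws: int = 100,
) -> ProjectedSubmodel:
    """Project the reference posterior onto the submodel spanned by
    ``sub_factors`` (plus intercept).

    Deterministic given the reference draws: the projected draws are an
    evenly thinned subset.  For the empty factor set the KL minimizer is
    closed-form (the intercept reproducing the mean reference probability),
    recovered here by the same Newton solve.
    """
    unknown = set(sub_factors) - set(ref_design.factors)
    if unknown:
        raise ValueError(f"factors {sorted(unknown)} not in the reference design")
    flat = reference.flat
    idx = _thin_indices(flat.shape[0], n_proj_draws)
    cols = _submodel_columns(ref_design, list(sub_factors))
    X_sub = ref_design.X[:, cols]
    labels = [ref_design.column_labels[j] for j in cols]
    S = idx.size
    coefs = np.empty((S, len(cols)))
    probs = np.empty((S, ref_design.n))
    kl = np.empty(S)
    conv = np.empty(S, dtype=bool)
    Xfull = ref_design.X
    for s, i in enumerate(idx):
        mu = expit(Xfull @ flat[i])
        b, ok = _soft_logistic_fit(X_sub, mu)
        q = expit(X_sub @ b)
        coefs[s] = b
        probs[s] = q
        kl[s] = _kl_bernoulli(mu, q)
        conv[s] = ok
    if not conv.all():
        logger.warning("projection failed to converge for %d of %d draws",
                       int((~conv).sum()), S)
    return ProjectedSubmodel(
        included_factors=list(sub_factors), column_labels=labels, coefs=coefs,
        probs=probs, kl=kl, draw_indices=idx, converged=conv,
    )


def _projected_score(sub: ProjectedSubmodel, ref_probs: np.ndarray) -> float:
    """In-sample projected predictive score: the reference-expected log
    predictive density of the submodel, averaged over projected draws
    (equivalently, minus the mean KL up to the reference entropy).
    ``ref_probs`` must be thinned to the same draws as the projection."""
    if ref_probs.shape != sub.probs.shape:
        raise ValueError("reference probabilities not aligned with projected draws")
    q = np.clip(sub.probs, _PCLIP, 1 - _PCLIP)
    terms = ref_probs * np.log(q) + (1 - ref_probs) * np.log(1 - q)
    return float(terms.sum(axis=1).mean())


def forward_search(
    reference: PosteriorDraws,
    ref_design: DesignMatrix,
    candidates: list[str] | None = None,
    max_size: int | None = None,
    n_proj_draws: int = 20,
) -> SelectionPath:
    """Greedy forward selection of factors by projected predictive score.

    At each step the candidate whose projection maximizes the in-sample
    projected score (the reference-expected log predictive; maximizing it is
    minimizing the projection KL) is added.  Ties are broken by fewer levels,
    then lexicographic name.  Returns the full ranking up to ``max_size``.
    """
    candidates = list(candidates) if candidates is not None else list(ref_design.factors)
    unknown = set(candidates) - set(ref_design.factors)
    if unknown:
        raise ValueError(f"candidates {sorted(unknown)} not in the reference design")
    if max_size is None:
        max_size = len(candidates)
    if max_size > len(candidates):
        raise ValueError("max_size exceeds the number of candidates")
    flat = reference.flat
    idx = _thin_indices(flat.shape[0], n_proj_draws)
    ref_probs = expit(ref_design.X @ flat[idx].T).T  # (S, n)

    selected: list[str] = []
    scores = [None] * (max_size + 1)
    remaining = list(candidates)
    # size-0 score: intercept-only projection
    base = project(reference, ref_design, [], n_proj_draws=n_proj_draws)
    scores[0] = _projected_score(base, ref_probs)
    n_levels = {f: len(ref_design.factor_levels[f]) for f in candidates}
    for size in range(1, max_size + 1):
        best = None
        for f in sorted(remaining, key=lambda f: (n_levels[f], f)):
            sub = project(reference, ref_design, selected + [f], n_proj_draws=n_proj_draws)
            sc = _projected_score(sub, ref_probs)
            # strictly-better test keeps the (fewer levels, name) tie order
            if best is None or sc > best[1] + 1e-9:
                best = (f, sc)
        selected.append(best[0])
        remaining.remove(best[0])
        scores[size] = best[1]
    return SelectionPath(
        ranked_factors=selected,
        candidate_factors=candidates,
        search_scores=np.asarray(scores, dtype=float),
    )


def _stratified_folds(y: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified K-fold assignment; errors out if any fold
    would end up with a single outcome class."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    assignment = np.empty(y.size, dtype=int)
    for cls in (0, 1):
        members = np.flatnonzero(y == cls)
        if members.size < folds:
            raise ValueError(
                f"outcome class {cls} has {members.size} members; "
                f"cannot stratify into {folds} folds"
            )
        rng.shuffle(members)
        assignment[members] = np.arange(members.size) % folds
    return [np.flatnonzero(assignment == k) for k in range(folds)]


def evaluate_path(
    path: SelectionPath,
    table: PatientTable,
    folds: int = 5,
    seed: int = 0,
    prior: PriorSpec | None = None,
    n_proj_draws: int = 100,
    chains: int = 2,
    iterations: int = 1000,
    warmup: int = 500,
) -> SelectionPath:
    """Fill the path's per-size accuracy and ELPD by K-fold cross-validation.

    Per fold the reference model (all candidate factors) is refit on the
    training split, projected onto every path prefix, and the held-out fold is
    scored: accuracy by the p > 0.5 rule on the mean predictive probability,
    and ELPD = sum over held-out points of log mean-over-draws Bernoulli
    density.  Means and SDs across folds are stored per size, along with the
    un-projected reference model's own metrics.
    """
    y = table.outcome
    design = build_design(table, path.candidate_factors)
    fold_idx = _stratified_folds(y, folds, seed)
    K = len(path.ranked_factors)
    acc = np.empty((folds, K + 1))
    elpd = np.empty((folds, K + 1))
    ref_acc = np.empty(folds)
    ref_elpd = np.empty(folds)
    seed_seq = np.random.SeedSequence(seed).generate_state(folds)
    for k, test in enumerate(fold_idx):
        train = np.setdiff1d(np.arange(y.size), test)
        train_design = DesignMatrix(
            X=design.X[train], column_labels=design.column_labels,
            factors=design.factors, factor_levels=design.factor_levels,
        )
        fit = sample_posterior(
            train_design, y[train], prior=prior, chains=chains,
            iterations=iterations, warmup=warmup, seed=int(seed_seq[k] % (2**31 - 1)),
        )
        X_test = design.X[test]
        y_test = y[test]
        # reference model metrics on the held-out fold
        flat = fit.flat[_thin_indices(fit.flat.shape[0], n_proj_draws)]
        p_ref = expit(X_test @ flat.T)  # (n_test, S)
        acc_ref, elpd_ref = _heldout_metrics(p_ref, y_test)
        ref_acc[k], ref_elpd[k] = acc_ref, elpd_ref
        for size in range(K + 1):
            sub_factors = path.ranked_factors[:size]
            sub = project(fit, train_design, sub_factors, n_proj_draws=n_proj_draws)
            cols = _submodel_columns(design, sub_factors)
            p_sub = expit(X_test[:, cols] @ sub.coefs.T)  # (n_test, S)
            acc[k, size], elpd[k, size] = _heldout_metrics(p_sub, y_test)
    path.acc_mean = acc.mean(axis=0)
    path.acc_sd = acc.std(axis=0, ddof=1)
    path.elpd_mean = elpd.mean(axis=0)
    path.elpd_sd = elpd.std(axis=0, ddof=1)
    path.reference_accuracy = float(ref_acc.mean())
    path.reference_elpd = float(ref_elpd.mean())
    path.folds = folds
    return path


def _heldout_metrics(p: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Accuracy (mean predictive probability > 0.5) and ELPD
    (log mean-over-draws pointwise density, summed) on held-out data."""
    p_mean = p.mean(axis=1)
    accuracy = float(np.mean((p_mean > 0.5) == (y == 1)))
    pointwise = np.where(y[:, None] == 1, p, 1.0 - p)
    elpd = float(np.sum(np.log(np.clip(pointwise.mean(axis=1), _PCLIP, None))))
    return accuracy, elpd
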