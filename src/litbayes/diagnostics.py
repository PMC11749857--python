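"""MCMC convergence diagnostics: rank-normalized split-R-hat and ESS.

Thin wrappers around ArviZ's implementations, returning per-parameter values
keyed by name and refusing to propagate NaN for degenerate (constant) chains.
"""

from __future__ import annotations

import logging

import arviz as az
import numpy as np
import pandas as pd

from .glm import PosteriorDraws

__all__ = ["split_rhat", "ess", "check_convergence"]

logger = logging.getLogger(__name__)

RHAT_THRESHOLD = 1.01
ESS_THRESHOLD = 400.0


def _to_array(draws) -> tuple[np.ndarray, list[str]]:
    if isinstance(draws, PosteriorDraws):
        return draws.draws, list(draws.names)
    arr = np.asarray(draws, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError("expected draws of shape (chains, iterations[, parameters])")
    return arr, [f"p{j}" for j in range(arr.shape[2])]


def _constant_mask(arr: np.ndarray) -> np.ndarray:
    return np.ptp(arr.reshape(-1, arr.shape[2]), axis=0) == 0


def split_rhat(draws: PosteriorDraws | np.ndarray) -> pd.Series:
    """Rank-normalized split-R-hat per parameter (values near 1 indicate the
    chains agree; > 1.01 is treated as non-convergence).

    A parameter that is constant across all chains has no defined R-hat; it is
    flagged with ``inf`` and a logged warning rather than returning NaN.
    """
    arr, names = _to_array(draws)
    if arr.shape[0] < 2:
        raise ValueError("split-R-hat needs at least 2 chains")
    if arr.shape[1] < 4:
        raise ValueError("split-R-hat needs at least 4 iterations per chain")
    vals = az.rhat(az.convert_to_dataset(arr))["x"].to_numpy()
    const = _constant_mask(arr)
    if const.any():
        logger.warning(
            "constant chains for parameters %s; R-hat undefined, flagged as inf",
            [names[j] for j in np.flatnonzero(const)],
        )
        vals = np.where(const, np.inf, vals)
    return pd.Series(vals, index=names, name="rhat")


def ess(draws: PosteriorDraws | np.ndarray, method: str = "bulk") -> pd.Series:
    """Autocorrelation-based effective sample size per parameter.

    Antithetic chains may legitimately yield ESS above the nominal draw count;
    no clipping is applied.  Constant parameters are flagged with ESS 0.
    """
    arr, names = _to_array(draws)
    vals = az.ess(az.convert_to_dataset(arr), method=method)["x"].to_numpy()
    const = _constant_mask(arr)
    if const.any():
        logger.warning(
            "constant chains for parameters %s; ESS set to 0",
            [names[j] for j in np.flatnonzero(const)],
        )
        vals = np.where(const, 0.0, vals)
    return pd.Series(vals, index=names, name="ess")


def check_convergence(
    draws: PosteriorDraws | np.ndarray,
    rhat_threshold: float = RHAT_THRESHOLD,
    ess_threshold: float = ESS_THRESHOLD,
) -> pd.DataFrame:
    """R-hat and ESS side by side with pass/fail flags against the package's
    convergence thresholds (R-hat < 1.01, ESS > 400 by default)."""
    r = split_rhat(draws)
    e = ess(draws)
    out = pd.DataFrame({"rhat": r, "ess": e})
    out["rhat_ok"] = out["rhat"] < rhat_threshold
    out["ess_ok"] = out["ess"] > ess_threshold
    return out
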