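"""Direct / indirect (spillover) / total effect decomposition for spatial fits.

In an SDM the marginal effect of covariate r on the outcome vector is the
n x n matrix S_r(W) = (I - rho*W)^{-1} (I*beta_r + W*theta_r) (theta_r = 0
for an SLM).  The direct effect is the average diagonal element of S_r,
the total effect the average row sum, and the indirect (spillover) effect
their difference.  Inference simulates (beta, theta, rho) from the
asymptotic normal distribution implied by the fit's covariance matrix,
recomputes the decomposition per draw, and reports the draw standard
deviation as the standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import SpatialFitResult
from .weights import SpatialWeights


@dataclass
class EffectsTable:
    """Point effects with simulation standard errors, t and p values."""

    table: pd.DataFrame  # index covariate; direct/indirect/total + _se/_t/_p
    n_draws: int
    seed: int
    method: str = "parameter-simulation"


def _effect_params(fit: SpatialFitResult) -> tuple[np.ndarray, np.ndarray, float]:
    if fit.family not in ("SLM", "SDM"):
        raise ValueError("effect decomposition applies to SLM and SDM fits")
    beta = fit.beta.to_numpy(dtype=float)
    if fit.family == "SDM" and fit.theta is not None:
        theta = fit.theta.to_numpy(dtype=float)
    else:
        theta = np.zeros_like(beta)
    return beta, theta, float(fit.rho)


def _decompose(beta: np.ndarray, theta: np.ndarray, rho: float, wm: np.ndarray) -> np.ndarray:
    """Rows (direct, indirect, total) x covariates for given parameters."""
    n = wm.shape[0]
    a = np.eye(n) - rho * wm
    a_inv = np.linalg.inv(a)
    diag_ainv = np.trace(a_inv) / n
    diag_ainvw = np.trace(a_inv @ wm) / n
    row_ainv = a_inv.sum() / n
    row_ainvw = (a_inv @ wm).sum() / n
    direct = beta * diag_ainv + theta * diag_ainvw
    total = beta * row_ainv + theta * row_ainvw
    indirect = total - direct
    # store total as direct + indirect so the additivity identity is exact
    return np.vstack([direct, indirect, direct + indirect])


def decompose_effects(fit: SpatialFitResult, w: SpatialWeights) -> pd.DataFrame:
    """Point direct/indirect/total effects per covariate.

    Requires an interior spatial parameter; total = direct + indirect holds
    exactly by construction.
    """
    beta, theta, rho = _effect_params(fit)
    if fit.boundary:
        raise ValueError("spatial parameter at interval boundary; effects undefined")
    vals = _decompose(beta, theta, rho, w.matrix)
    return pd.DataFrame(vals.T, index=list(fit.beta.index), columns=["direct", "indirect", "total"])


def effects_inference(
    fit: SpatialFitResult,
    w: SpatialWeights,
    n_draws: int = 1000,
    seed: int = 0,
) -> EffectsTable:
    """Monte-Carlo effect inference by simulating from the fit's covariance.

    Draws (beta, theta, rho) jointly from N(estimates, vcov), rejecting
    draws whose rho leaves the admissible interval, and decomposes each
    draw.  A covariance submatrix that is not positive semidefinite is
    repaired by clipping negative eigenvalues (with a warning).
    """
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    beta, theta, rho = _effect_params(fit)
    point = decompose_effects(fit, w)
    k = len(beta)
    names = list(fit.beta.index)
    pnames = names + ([f"W.{v}" for v in names] if fit.family == "SDM" and fit.theta is not None
                      and f"W.{names[0]}" in fit.vcov.index else []) + ["rho"]
    mean = np.concatenate([beta, theta[: len(pnames) - k - 1], [rho]])
    cov = fit.vcov.loc[pnames, pnames].to_numpy()
    cov = (cov + cov.T) / 2
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval.min() < -1e-12 * max(1.0, eigval.max()):
        warnings.warn("parameter covariance not PSD; clipping negative eigenvalues", stacklevel=2)
    eigval = np.clip(eigval, 0.0, None)
    chol_like = eigvec * np.sqrt(eigval)

    lo, hi = fit.rho_interval if fit.rho_interval is not None else (-1.0, 1.0)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_draws, 3, k))
    got = 0
    has_theta = len(pnames) - 1 > k
    while got < n_draws:
        batch = mean + rng.standard_normal((max(n_draws, 256), len(mean))) @ chol_like.T
        ok = (batch[:, -1] > lo) & (batch[:, -1] < hi)
        for row in batch[ok]:
            if got >= n_draws:
                break
            b = row[:k]
            th = row[k:-1] if has_theta else np.zeros(k)
            draws[got] = _decompose(b, th, row[-1], w.matrix)
            got += 1

    se = draws.std(axis=0, ddof=1)  # (3, k)
    est = point.to_numpy().T  # (3, k) direct/indirect/total
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = est / se
    pvals = 2 * stats.norm.sf(np.abs(tvals))
    out = point.copy()
    for i, eff in enumerate(["direct", "indirect", "total"]):
        out[f"{eff}_se"] = se[i]
        out[f"{eff}_t"] = tvals[i]
        out[f"{eff}_p"] = pvals[i]
    return EffectsTable(table=out, n_draws=n_draws, seed=seed)
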