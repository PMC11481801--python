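"""Single imputation of missing outcomes by joint-Gaussian EM.

The variables (predictors + outcome) are modelled as one multivariate
normal; the EM algorithm iterates conditional-expectation E-steps and
mean/covariance M-steps until the parameter change falls below tolerance.
Missing outcome entries are then replaced by their conditional
expectations given the observed variables — deterministic single
imputation, no noise draw. Observed cells are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EMInfo:
    """Convergence diagnostics of one EM run."""

    n_iter: int
    converged: bool
    max_change: float
    n_imputed: int
    trace: list[float] = field(default_factory=list)


def _em_gaussian(M: np.ndarray, miss_col: int, tol: float, max_iter: int):
    """EM for a data matrix with missing values in one column only."""
    n, p = M.shape
    miss = np.isnan(M[:, miss_col])
    obs_idx = [j for j in range(p) if j != miss_col]

    # start from complete-data moments with missing entries mean-filled
    work = M.copy()
    col_obs = M[~miss, miss_col]
    if len(col_obs) == 0:
        raise ValueError("outcome entirely missing: EM has no anchor")
    work[miss, miss_col] = col_obs.mean()

    mu = work.mean(axis=0)
    sigma = np.cov(work, rowvar=False, bias=True)
    trace = []
    converged = False
    it = 0
    cond_var = 0.0
    for it in range(1, max_iter + 1):
        # E-step: conditional mean/variance of the missing entries
        s_oo = sigma[np.ix_(obs_idx, obs_idx)]
        s_mo = sigma[miss_col, obs_idx]
        if len(obs_idx):
            w = np.linalg.solve(s_oo, s_mo)
            cond_var = float(sigma[miss_col, miss_col] - s_mo @ w)
            pred = mu[miss_col] + (M[np.ix_(miss.nonzero()[0], obs_idx)]
                                   - mu[obs_idx]) @ w
        else:
            cond_var = float(sigma[miss_col, miss_col])
            pred = np.full(miss.sum(), mu[miss_col])
        work[miss, miss_col] = pred
        cond_var = max(cond_var, 0.0)

        # M-step: ML mean and covariance, with the conditional variance of
        # the filled entries added to the outcome's second moment
        mu_new = work.mean(axis=0)
        centred = work - mu_new
        sigma_new = centred.T @ centred / n
        sigma_new[miss_col, miss_col] += cond_var * miss.sum() / n

        change = max(np.max(np.abs(mu_new - mu)),
                     np.max(np.abs(sigma_new - sigma)))
        trace.append(float(change))
        mu, sigma = mu_new, sigma_new
        if change < tol:
            converged = True
            break
    return work[:, miss_col], miss, EMInfo(it, converged, trace[-1] if trace
                                           else 0.0, int(miss.sum()), trace)


def impute_em(data: pd.DataFrame, outcome: str, predictors,
              tol: float = 1e-6, max_iter: int = 500
              ) -> tuple[pd.DataFrame, EMInfo]:
    """Impute missing ``outcome`` values from complete ``predictors``.

    Returns a completed copy of ``data`` and an :class:`EMInfo`. Raises on
    missing predictor cells (the method assumes missingness in the outcome
    only) and reports the iteration trace on non-convergence.
    """
    predictors = list(predictors)
    if data[predictors].isna().any().any():
        raise ValueError("predictors must be complete")
    out = data.copy()
    if not out[outcome].isna().any():
        return out, EMInfo(0, True, 0.0, 0)
    cols = predictors + [outcome]
    M = out[cols].to_numpy(float)
    filled, miss, info = _em_gaussian(M, miss_col=len(cols) - 1,
                                      tol=tol, max_iter=max_iter)
    if not info.converged:
        raise RuntimeError(
            f"EM did not converge in {info.n_iter} iterations; "
            f"last parameter changes: {info.trace[-5:]}")
    values = out[outcome].to_numpy(float)
    values[miss] = filled[miss]
    out[outcome] = values
    return out, info
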