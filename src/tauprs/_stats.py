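"""Closed-form least-squares helpers.

These back the bootstrap and screening loops (mediation, leave-one-out
scans, nested-score profiles) where thousands of small OLS fits are
needed and the overhead of a full model object per fit would dominate.
The reported association fits in :mod:`tauprs.association` go through
statsmodels; the two paths agree to numerical precision and are
cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def ols(X: np.ndarray, y: np.ndarray):
    """Ordinary least squares with Wald t statistics.

    Parameters
    ----------
    X : (n, k) design matrix, intercept column included by the caller.
    y : (n,) response.

    Returns
    -------
    beta, se, tstat, p : (k,) arrays
    df_resid : int
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    df = n - rank
    if df <= 0:
        raise ValueError(f"not enough rows for OLS: n={n}, rank={rank}")
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    return beta, se, tstat, p, df


def coef_solve(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficients only, via the normal equations.

    Falls back to lstsq when the Gram matrix is singular (e.g. a
    degenerate bootstrap resample).
    """
    g = X.T @ X
    try:
        return np.linalg.solve(g, X.T @ y)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(X, y, rcond=None)[0]


def design_with_intercept(*blocks) -> np.ndarray:
    """Stack 1-D/2-D column blocks behind an intercept column.

    ``None`` blocks are skipped; everything is cast to float.
    """
    cols = []
    n = None
    for b in blocks:
        if b is None:
            continue
        arr = np.asarray(b, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        cols.append(arr)
        n = arr.shape[0]
    if n is None:
        raise ValueError("no design columns supplied")
    return np.hstack([np.ones((n, 1))] + cols)
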