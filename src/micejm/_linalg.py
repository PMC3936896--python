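"""Small dense least-squares helpers used in hot loops.

The chained-equations study refits tiny regressions (~100 x 3) tens of
thousands of times per dataset, so these avoid per-call overhead of the
full model classes; statsmodels serves as the independent cross-check in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["add_intercept", "ols_fit", "ols_coef", "inv_spd_small", "chol_small"]


def inv_spd_small(a: np.ndarray) -> np.ndarray:
    """Inverse of a small symmetric positive-definite matrix.

    Closed forms for 1x1 and 2x2 (the common cases in the samplers, where
    LAPACK call overhead dominates); LAPACK otherwise.
    """
    q = a.shape[0]
    if q == 1:
        return np.array([[1.0 / a[0, 0]]])
    if q == 2:
        det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
        return np.array([[a[1, 1], -a[0, 1]], [-a[1, 0], a[0, 0]]]) / det
    return np.linalg.inv(a)


def chol_small(a: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of a small SPD matrix (closed form for q <= 2)."""
    q = a.shape[0]
    if q == 1:
        if a[0, 0] <= 0:
            raise np.linalg.LinAlgError("matrix is not positive definite")
        return np.array([[np.sqrt(a[0, 0])]])
    if q == 2:
        a00 = a[0, 0]
        if a00 <= 0:
            raise np.linalg.LinAlgError("matrix is not positive definite")
        l00 = np.sqrt(a00)
        l10 = a[1, 0] / l00
        rest = a[1, 1] - l10 * l10
        if rest <= 0:
            raise np.linalg.LinAlgError("matrix is not positive definite")
        return np.array([[l00, 0.0], [l10, np.sqrt(rest)]])
    return np.linalg.cholesky(a)


def add_intercept(columns: np.ndarray) -> np.ndarray:
    """Prepend a column of ones to a 2-D covariate matrix."""
    n = columns.shape[0]
    return np.column_stack([np.ones(n), columns])


def ols_fit(design: np.ndarray, response: np.ndarray):
    """Least-squares fit via Cholesky on the normal equations.

    Returns ``(coefficients, residual sum of squares, XtX)``. Raises
    ``np.linalg.LinAlgError`` on a rank-deficient design.
    """
    xtx = design.T @ design
    xty = design.T @ response
    try:
        coef = np.linalg.solve(xtx, xty)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("rank-deficient design matrix") from None
    resid = response - design @ coef
    if resid.ndim == 1:
        rss = float(resid @ resid)
    else:
        rss = resid.T @ resid
    return coef, rss, xtx


def ols_coef(design: np.ndarray, response: np.ndarray, index: int) -> float:
    """Single OLS coefficient (convenience wrapper over :func:`ols_fit`)."""
    coef, _, _ = ols_fit(design, response)
    return float(coef[index])
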