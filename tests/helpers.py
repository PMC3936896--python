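"""Independent oracles shared by the tests.

Everything here is deliberately brute force and separate from the package
implementation: a random-walk Metropolis sampler targeting the written
posterior densities, and a blocked standard-error estimate for comparing
correlated oracle chains with direct draws.
"""

from __future__ import annotations

import numpy as np


def rw_metropolis(logpost, x0, step, n_steps, rng, thin=1):
    """Full-vector random-walk Metropolis; returns the thinned chain."""
    x = np.asarray(x0, dtype=float).copy()
    lp = logpost(x)
    out = np.empty((n_steps // thin, x.size))
    kept = 0
    for t in range(n_steps):
        prop = x + step * rng.standard_normal(x.size)
        lp_prop = logpost(prop)
        if np.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
        if (t + 1) % thin == 0:
            out[kept] = x
            kept += 1
    return out


def blocked_se(series, n_blocks=50):
    """Standard error of a (possibly correlated) series mean via blocking."""
    series = np.asarray(series, dtype=float)
    n = (series.size // n_blocks) * n_blocks
    means = series[:n].reshape(n_blocks, -1).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(n_blocks)


def glom_log_posterior(y, w, tau, nu, kappa):
    """Unnormalized log posterior of (mu0, mu1, Sigma) for the GLOM normal block.

    Parameter vector x = (mu0[0], mu0[1], mu1[0], mu1[1], s11, s12, s22);
    gamma integrates out separately (Beta-conjugate), so it is omitted.
    Returns -inf outside the positive-definite cone.
    """
    n = y.size

    def logpost(x):
        mu0 = x[0:2]
        mu1 = x[2:4]
        s11, s12, s22 = x[4], x[5], x[6]
        det = s11 * s22 - s12 * s12
        if s11 <= 0 or s22 <= 0 or det <= 0:
            return -np.inf
        prec = np.array([[s22, -s12], [-s12, s11]]) / det
        resid = w - mu0 - np.outer(y, mu1)
        quad = np.einsum("ij,jk,ik->", resid, prec, resid)
        return -(n / 2.0 + kappa) * np.log(det) - 0.5 * quad

    return logpost


def normal_linear_log_posterior(y, design, kappa):
    """Unnormalized log posterior of (b, omega) under prior omega^(-kappa).

    Parameter vector x = (b..., omega); -inf for omega <= 0.
    """
    n, p = design.shape

    def logpost(x):
        b, omega = x[:p], x[p]
        if omega <= 0:
            return -np.inf
        resid = y - design @ b
        return -(n / 2.0 + kappa) * np.log(omega) - 0.5 * (resid @ resid) / omega

    return logpost


def irls_logistic(y, design, tol=1e-12, max_iter=200):
    """Plain IRLS logistic regression oracle (weighted least squares form)."""
    b = np.zeros(design.shape[1])
    for _ in range(max_iter):
        eta = design @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        wt = mu * (1.0 - mu)
        z = eta + (y - mu) / wt
        wx = design * wt[:, None]
        b_new = np.linalg.solve(wx.T @ design, wx.T @ z)
        if np.abs(b_new - b).max() < tol:
            return b_new
        b = b_new
    return b
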