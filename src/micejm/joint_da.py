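"""Joint-model imputation under the general location model (GLOM).

The joint model for one binary variable Y and q continuous variables W is

    Y ~ Bernoulli(gamma),      W | Y ~ N(mu0 + mu1 * Y, Sigma),

with parameter theta = (gamma, mu0, mu1, Sigma) and prior

    p(theta) ∝ gamma^(tau-1) * (1-gamma)^(nu-1) * |Sigma|^(-kappa).

Imputation uses two-block data augmentation: alternately draw the missing
cells from p(x_mis | x_obs, theta) and theta from the complete-data
posterior. Upon convergence this yields draws of x_mis from the posterior
predictive distribution implied by the joint model, which is why this
sampler serves as the gold standard against which the chained-equations
algorithm is compared.

Complete-data posterior (derivation used by :func:`draw_theta_complete`):
gamma is conjugate Beta(tau + n1, nu + n - n1), independent of the normal
block. Writing the W-part as a multivariate regression of W (n x q) on
X = [1, Y] (n x p, p = 2) with coefficient matrix B = [mu0; mu1], the prior
|Sigma|^(-kappa) combined with the likelihood gives

    Sigma | data ~ InvWishart(df = n - p + 2*kappa - q - 1, scale = S),
    B | Sigma    ~ MatrixNormal(B_ols, (X'X)^(-1), Sigma),

where S is the residual cross-product matrix at the least-squares fit.
(The inverse-Wishart degrees of freedom follow from matching exponents of
|Sigma| after integrating B out; the test suite validates the draw against
a brute-force Metropolis sampler of the written density.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linalg import add_intercept, chol_small, inv_spd_small, ols_fit
from .dataset import Dataset

__all__ = [
    "GLOMParams",
    "GLOMPrior",
    "DAConfig",
    "draw_theta_complete",
    "draw_missing_glom",
    "run_data_augmentation",
    "pool_estimates",
    "class_log_odds",
]


@dataclass(frozen=True)
class GLOMParams:
    """gamma plus class-conditional normal parameters (mu0, mu1, Sigma)."""

    gamma: float
    mu0: np.ndarray
    mu1: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mu0", np.atleast_1d(np.asarray(self.mu0, dtype=float)))
        object.__setattr__(self, "mu1", np.atleast_1d(np.asarray(self.mu1, dtype=float)))
        object.__setattr__(self, "Sigma", np.atleast_2d(np.asarray(self.Sigma, dtype=float)))
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie strictly in (0, 1)")
        q = self.mu0.shape[0]
        if self.mu1.shape != (q,) or self.Sigma.shape != (q, q):
            raise ValueError("inconsistent GLOM parameter dimensions")
        if not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be symmetric")
        # positive definiteness via Cholesky
        np.linalg.cholesky(self.Sigma)


@dataclass(frozen=True)
class GLOMPrior:
    """Hyperparameters of gamma^(tau-1) (1-gamma)^(nu-1) |Sigma|^(-kappa)."""

    tau: float = 0.5
    nu: float = 0.5
    kappa: float = 1.5

    def __post_init__(self):
        if self.tau <= 0 or self.nu <= 0:
            raise ValueError("tau and nu must be positive")


@dataclass(frozen=True)
class DAConfig:
    """Data-augmentation schedule: m imputations, burn-in, thinning."""

    m_imputations: int = 100
    burn_in: int = 100
    thin: int = 100
    seed: int = 0

    def __post_init__(self):
        if min(self.m_imputations, self.thin) < 1 or self.burn_in < 0:
            raise ValueError("m_imputations, thin >= 1 and burn_in >= 0 required")


# ----------------------------------------------------------------------
# structure helpers


def _split_glom(data: Dataset):
    """Locate the single binary column; return (binary index, continuous indices)."""
    binary = [j for j, t in enumerate(data.column_types) if t == "binary"]
    if len(binary) != 1:
        raise ValueError("GLOM requires exactly one binary column")
    cont = [j for j in range(data.n_cols) if j != binary[0]]
    return binary[0], cont


def _invwishart_rvs(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One inverse-Wishart(df, scale) draw via the Bartlett decomposition.

    Used in the data-augmentation hot loop, where this runs ~10^4 times per
    dataset; equivalent in distribution to ``scipy.stats.invwishart.rvs``
    (the test suite checks the two agree in moments).
    """
    q = scale.shape[0]
    a = np.zeros((q, q))
    idx = np.tril_indices(q, -1)
    a[idx] = rng.standard_normal(len(idx[0]))
    a[np.diag_indices(q)] = np.sqrt(rng.chisquare(df - np.arange(q)))
    ls = chol_small(scale)
    # factor B of scale^-1: B = inv(ls).T, then inv(W) with W = (B A)(B A)^T
    if q == 2:
        ls_inv = np.array(
            [[1.0 / ls[0, 0], 0.0],
             [-ls[1, 0] / (ls[0, 0] * ls[1, 1]), 1.0 / ls[1, 1]]]
        )
    else:
        ls_inv = np.linalg.inv(ls)
    m = ls_inv.T @ a
    mi = np.linalg.inv(m)
    return mi.T @ mi


def _params_fast(gamma: float, mu0, mu1, sigma) -> GLOMParams:
    """Construct GLOMParams without re-validating (sampler-internal values)."""
    obj = object.__new__(GLOMParams)
    object.__setattr__(obj, "gamma", gamma)
    object.__setattr__(obj, "mu0", mu0)
    object.__setattr__(obj, "mu1", mu1)
    object.__setattr__(obj, "Sigma", sigma)
    return obj


def _draw_theta(y: np.ndarray, w: np.ndarray, prior: GLOMPrior, rng: np.random.Generator) -> GLOMParams:
    """Complete-data posterior draw from raw arrays (hot path)."""
    n, q = w.shape
    n1 = float(y.sum())
    if n1 == 0 or n1 == n:
        raise ValueError("degenerate posterior: only one Y class present")
    gamma = float(rng.beta(prior.tau + n1, prior.nu + n - n1))

    design = add_intercept(y)
    p = design.shape[1]
    if n < p:
        raise np.linalg.LinAlgError("fewer rows than regression parameters")
    b_hat, s, xtx = ols_fit(design, w)
    df = n - p + 2.0 * prior.kappa - q - 1.0
    if df <= q - 1:
        raise ValueError(f"posterior for Sigma is improper: df={df} <= {q - 1}")
    s = np.atleast_2d(s)
    try:
        np.linalg.cholesky(s)
    except np.linalg.LinAlgError:
        raise ValueError("degenerate Sigma posterior: residual scatter is singular") from None
    sigma = _invwishart_rvs(df, s, rng)
    # B | Sigma ~ MatrixNormal(B_ols, (X'X)^-1, Sigma)
    a = chol_small(inv_spd_small(xtx))
    l = chol_small(sigma)
    b = b_hat + a @ rng.standard_normal((p, q)) @ l.T
    return _params_fast(gamma, b[0], b[1], sigma)


def draw_theta_complete(
    data: Dataset, prior: GLOMPrior, rng: np.random.Generator
) -> GLOMParams:
    """One draw of theta from the complete-data GLOM posterior.

    ``data`` must be fully observed with both Y classes present. gamma is
    drawn from its Beta posterior; (mu0, mu1, Sigma) from the
    inverse-Wishart / matrix-normal posterior of the regression of W on
    (1, Y) — see the module docstring for the derivation.
    """
    if not data.is_complete():
        raise ValueError("draw_theta_complete requires fully completed data")
    jb, jc = _split_glom(data)
    return _draw_theta(data.values[:, jb], data.values[:, jc], prior, rng)


# ----------------------------------------------------------------------
# posterior predictive draws


def class_log_odds(theta: GLOMParams, w: np.ndarray, obs_idx=None) -> np.ndarray:
    """log pr(Y=1|w)/pr(Y=0|w) for rows of ``w`` (columns ``obs_idx`` of W).

    Computed from the two class-conditional normal densities and gamma by
    Bayes' rule; under the GLOM this is exactly an affine (logistic
    regression) function of w.
    """
    w = np.atleast_2d(np.asarray(w, dtype=float))
    if obs_idx is None:
        obs_idx = np.arange(theta.mu0.shape[0])
    obs_idx = np.asarray(obs_idx, dtype=int)
    m0 = theta.mu0[obs_idx]
    m1 = m0 + theta.mu1[obs_idx]
    sub = theta.Sigma[np.ix_(obs_idx, obs_idx)]
    prec = inv_spd_small(sub)
    d0 = w - m0
    d1 = w - m1
    quad0 = np.einsum("ij,jk,ik->i", d0, prec, d0)
    quad1 = np.einsum("ij,jk,ik->i", d1, prec, d1)
    return np.log(theta.gamma / (1.0 - theta.gamma)) + 0.5 * (quad0 - quad1)


def _conditional_normal(theta: GLOMParams, mis_idx, obs_idx):
    """Coefficients of W_mis | Y, W_obs: returns (means fn inputs) pieces."""
    mis_idx = np.asarray(mis_idx, dtype=int)
    obs_idx = np.asarray(obs_idx, dtype=int)
    s_mm = theta.Sigma[np.ix_(mis_idx, mis_idx)]
    if obs_idx.size == 0:
        return None, s_mm
    s_mo = theta.Sigma[np.ix_(mis_idx, obs_idx)]
    s_oo = theta.Sigma[np.ix_(obs_idx, obs_idx)]
    gain = s_mo @ inv_spd_small(s_oo)
    cond_cov = s_mm - gain @ s_mo.T
    return gain, cond_cov


def _pattern_groups(mask: np.ndarray, jb: int, jc: list[int]) -> list[tuple]:
    """Group incomplete rows by missingness pattern, with precomputed indexers.

    Each entry is (group rows, y_missing flag, W-local observed indices,
    W-local missing indices, observed-cell grid, missing-cell grid); the
    grids index ``values[grid]`` directly so the per-iteration fill avoids
    re-deriving fancy indices.
    """
    incomplete = ~mask.all(axis=1)
    if not incomplete.any():
        return []
    rows = np.where(incomplete)[0]
    patterns = mask[rows]
    uniq, inverse = np.unique(patterns, axis=0, return_inverse=True)
    w_cols = np.asarray(jc)
    groups = []
    for g, pat in enumerate(uniq):
        grp = rows[inverse == g]
        w_obs_local = np.where(pat[w_cols])[0]  # indices into the W vector
        w_mis_local = np.where(~pat[w_cols])[0]
        grid_obs = np.ix_(grp, w_cols[w_obs_local]) if w_obs_local.size else None
        grid_mis = np.ix_(grp, w_cols[w_mis_local]) if w_mis_local.size else None
        groups.append((grp, not pat[jb], w_obs_local, w_mis_local, grid_obs, grid_mis))
    return groups


def _fill_missing(
    values: np.ndarray,
    mask: np.ndarray,
    jb: int,
    jc: list[int],
    theta: GLOMParams,
    rng: np.random.Generator,
    out: np.ndarray,
    groups: list[tuple] | None = None,
) -> None:
    """Draw missing cells of each row into ``out`` (observed cells copied).

    Rows are grouped by missingness pattern. Within a group, a missing Y is
    drawn first from pr(Y=1 | observed W, theta); missing W components are
    then drawn from their conditional normal given Y and the observed W.
    """
    out[:] = values
    if groups is None:
        groups = _pattern_groups(mask, jb, jc)
    for grp, y_missing, w_obs_local, w_mis_local, grid_obs, grid_mis in groups:
        # --- binary variable
        if not y_missing:
            y = values[grp, jb]
        else:
            if w_obs_local.size:
                lo = class_log_odds(theta, values[grid_obs], w_obs_local)
                p1 = 1.0 / (1.0 + np.exp(-lo))
            else:
                p1 = np.full(grp.size, theta.gamma)
            y = (rng.random(grp.size) < p1).astype(float)
            out[grp, jb] = y
        # --- continuous variables
        if w_mis_local.size:
            gain, cond_cov = _conditional_normal(theta, w_mis_local, w_obs_local)
            mean_full = theta.mu0 + np.outer(y, theta.mu1)  # (rows, q)
            cond_mean = mean_full[:, w_mis_local]
            if gain is not None:
                resid = values[grid_obs] - mean_full[:, w_obs_local]
                cond_mean = cond_mean + resid @ gain.T
            chol = chol_small(cond_cov)
            z = rng.standard_normal((grp.size, w_mis_local.size))
            out[grid_mis] = cond_mean + z @ chol.T


def draw_missing_glom(
    data: Dataset, theta: GLOMParams, rng: np.random.Generator
) -> Dataset:
    """Draw every missing cell from p(x_mis | x_obs, theta); returns a completed copy."""
    jb, jc = _split_glom(data)
    out = np.empty_like(data.values)
    _fill_missing(data.values, data.mask, jb, jc, theta, rng, out)
    return data.completed(out)


# ----------------------------------------------------------------------
# the sampler


def _initial_fill(values: np.ndarray, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replace missing cells with random draws from the column's observed values."""
    out = values.copy()
    for j in range(values.shape[1]):
        obs = values[mask[:, j], j]
        mis = ~mask[:, j]
        if mis.any():
            if obs.size == 0:
                raise ValueError(f"column {j} is entirely missing; cannot initialize")
            out[mis, j] = rng.choice(obs, size=int(mis.sum()), replace=True)
    return out


def run_data_augmentation(
    data: Dataset,
    prior: GLOMPrior = GLOMPrior(),
    cfg: DAConfig = DAConfig(),
    rng: np.random.Generator | None = None,
) -> list[Dataset]:
    """Tanner–Wong data augmentation under the GLOM; returns m completed datasets.

    The chain is started by filling missing cells with random draws from
    each column's observed values. Each iteration draws the missing cells
    given the current theta and then theta from the completed data. After
    ``burn_in`` iterations one completed dataset is retained every ``thin``
    iterations (the first retained dataset sits one thinning gap after the
    burn-in), for ``burn_in + m * thin`` iterations in total.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    jb, jc = _split_glom(data)
    values, mask = data.values, data.mask
    if not mask.any(axis=0).all():
        raise ValueError("a column is entirely missing; the GLOM fit is undefined")
    work = _initial_fill(values, mask, rng)
    completed: list[Dataset] = []
    if data.is_complete():
        # nothing to impute: the posterior predictive is a point mass at the data
        return [data.copy() for _ in range(cfg.m_imputations)]
    total = cfg.burn_in + cfg.m_imputations * cfg.thin
    buf = np.empty_like(work)
    groups = _pattern_groups(mask, jb, jc)
    for t in range(1, total + 1):
        theta = _draw_theta(work[:, jb], work[:, jc], prior, rng)
        _fill_missing(values, mask, jb, jc, theta, rng, buf, groups)
        work, buf = buf, work
        if t > cfg.burn_in and (t - cfg.burn_in) % cfg.thin == 0:
            completed.append(data.completed(work))
    return completed


def pool_estimates(
    completed: list[Dataset],
    response: str = "W2",
    covariates: tuple[str, ...] = ("W1", "Y"),
    coefficient: str = "Y",
) -> float:
    """Mean over completed datasets of one OLS coefficient of the analysis model.

    The default analysis model is the study's: regress W2 on (W1, Y) and
    pool the coefficient of Y by averaging across imputations.
    """
    if not completed:
        raise ValueError("need at least one completed dataset")
    vals = []
    for ds in completed:
        cols = [ds.column_index(c) for c in covariates]
        design = add_intercept(ds.values[:, cols])
        y = ds.values[:, ds.column_index(response)]
        coef, _, _ = ols_fit(design, y)
        vals.append(coef[1 + covariates.index(coefficient)])
    return float(np.mean(vals))
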