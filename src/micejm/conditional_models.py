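"""Per-variable imputation models for the chained-equations sampler.

Each incomplete variable gets a univariate model fitted, at every
iteration, to the rows where that variable is observed, conditioning on
the current (partly imputed) values of all other variables:

* ``normal_linear`` — Bayesian normal linear regression with the
  noninformative prior p(coefficients, omega) ∝ omega^(-kappa)
  (kappa = 3/2 by default). In proper mode the residual variance omega is
  drawn from its marginal scaled inverse chi-square posterior and the
  coefficients from their conditional normal; improper mode plugs in the
  OLS fit with the residual-variance MLE.
* ``logistic_mvn`` — logistic regression by maximum likelihood; proper
  mode draws the parameter from the multivariate normal approximation
  N(psi_hat, V_hat) with V_hat the inverse observed information.
* ``lda_glom`` — a linear-discriminant update for the binary variable:
  the full general location model is fitted to all rows where the binary
  variable is observed, so the fit also uses the marginal information
  about the continuous variables; imputation uses the implied class
  posterior pr(Y=1 | W).

Design matrices passed to these functions must already contain the
intercept column (see :func:`micejm._linalg.add_intercept`).

Marginal posterior of omega under p ∝ omega^(-kappa): integrating the
coefficients out of omega^(-kappa) * prod N(y; x'b, omega) leaves
omega^(-(n-p)/2 - kappa) * exp(-RSS/(2 omega)), a scaled inverse
chi-square with df = n - p + 2*kappa - 2 and scale RSS/df (so df =
n - p + 1 at the default kappa = 3/2). The test suite confirms this
against a brute-force Metropolis sampler of the written density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit as _expit

from ._linalg import add_intercept, ols_fit
from .joint_da import GLOMParams, GLOMPrior, _draw_theta, class_log_odds

__all__ = [
    "ConditionalSpec",
    "ParamDraw",
    "draw_normal_linear",
    "draw_logistic_mvn",
    "impute_binary",
    "impute_continuous",
    "draw_lda_glom",
    "logistic_mle",
]

FAMILIES = ("normal_linear", "logistic_mvn", "lda_glom")

#: |coefficient| beyond which a logistic fit is treated as separated
SEPARATION_BOUND = 15.0
#: ridge penalty applied when separation is detected
RIDGE_PENALTY = 1e-4
_MAX_NEWTON = 100


@dataclass(frozen=True)
class ConditionalSpec:
    """One incomplete variable's imputation model.

    ``prior`` carries family-specific hyperparameters: ``{"kappa": ...}``
    for ``normal_linear``; ``{"tau", "nu", "kappa"}`` for ``lda_glom``;
    ignored for ``logistic_mvn``. ``proper=False`` replaces the Bayesian
    parameter draw with the maximum-likelihood plug-in.
    """

    target: str
    covariates: tuple[str, ...]
    family: str
    prior: dict = field(default_factory=dict)
    proper: bool = True

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.target in self.covariates:
            raise ValueError("target must not appear among its covariates")


@dataclass
class ParamDraw:
    """Drawn (or plugged-in) parameters of one conditional model."""

    coefficients: np.ndarray
    scale: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.scale is not None and self.scale <= 0:
            raise ValueError("scale must be positive when present")


# ----------------------------------------------------------------------
# normal linear family


def draw_normal_linear(
    y: np.ndarray,
    design: np.ndarray,
    rng: np.random.Generator,
    proper: bool = True,
    kappa: float = 1.5,
) -> ParamDraw:
    """CE1 draw for a continuous target under prior ∝ omega^(-kappa).

    ``y`` holds the target where observed; ``design`` the matching rows of
    the covariate matrix (intercept included). Proper mode draws
    omega ~ RSS / chi2(n - p + 2*kappa - 2) then coefficients from
    N(b_ols, omega (X'X)^(-1)); improper mode returns the OLS fit with the
    residual-variance MLE RSS/n.
    """
    y = np.asarray(y, dtype=float)
    n, p = design.shape
    df = n - p + 2.0 * kappa - 2.0
    if proper and df <= 0:
        raise ValueError(f"too few observed rows: posterior df={df} <= 0")
    if n < p + 2:
        raise ValueError(f"too few observed rows ({n}) for {p} coefficients")
    xtx = design.T @ design
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("rank-deficient design matrix") from None
    b_hat = xtx_inv @ (design.T @ y)
    resid = y - design @ b_hat
    rss = float(resid @ resid)
    if rss <= 1e-12 * max(1.0, float(y @ y)):
        raise ValueError("degenerate omega posterior: residuals are identically zero")
    if not proper:
        return ParamDraw(b_hat, rss / n, {"mode": "improper"})
    omega = rss / rng.chisquare(df)
    chol = np.linalg.cholesky(xtx_inv)
    b = b_hat + np.sqrt(omega) * (chol @ rng.standard_normal(p))
    return ParamDraw(b, omega, {"mode": "proper", "df": df})


def impute_continuous(
    design: np.ndarray, draw: ParamDraw, rng: np.random.Generator
) -> np.ndarray:
    """CE2 draw: one N(x'b, omega) value per row of ``design``."""
    if draw.scale is None:
        raise ValueError("continuous imputation needs a scale")
    mean = design @ draw.coefficients
    return mean + np.sqrt(draw.scale) * rng.standard_normal(design.shape[0])


# ----------------------------------------------------------------------
# logistic family


def logistic_mle(
    y: np.ndarray,
    design: np.ndarray,
    penalty: float = 0.0,
    start: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton–Raphson logistic fit; returns (coef, inverse information, converged).

    With ``penalty`` > 0 a ridge term penalty/2 * ||b||^2 is subtracted
    from the log-likelihood (used as the separation fallback). The
    covariance is the inverse of the (penalized) observed information at
    the optimum, which for the canonical logit link equals the expected
    information. ``start`` warm-starts the iteration (the chained-equations
    engine passes the previous iteration's MLE; the optimum is unchanged).
    """
    n, p = design.shape
    b = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    converged = False
    eye = np.eye(p)
    for _ in range(_MAX_NEWTON):
        mu = _expit(design @ b)
        w = mu * (1.0 - mu)
        grad = design.T @ (y - mu) - penalty * b
        info = (design * w[:, None]).T @ design + penalty * eye
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        b = b + step
        if np.abs(step).max() < 1e-10:
            converged = True
            break
    mu = _expit(design @ b)
    info = (design * (mu * (1 - mu))[:, None]).T @ design + penalty * eye
    try:
        v = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        # information degenerates under separation; caller falls back to ridge
        return b, np.full((p, p), np.nan), False
    return b, v, converged


def draw_logistic_mvn(
    y: np.ndarray,
    design: np.ndarray,
    rng: np.random.Generator,
    proper: bool = True,
    start: np.ndarray | None = None,
) -> ParamDraw:
    """CE1 draw for a binary target via the MVN approximation N(psi_hat, V_hat).

    Fits logistic regression by maximum likelihood on the rows where the
    target is observed. If the fit fails to converge or any coefficient
    exceeds ``SEPARATION_BOUND`` in magnitude (separation, quite possible
    with 50 observed rows), the fit is redone with a small ridge penalty
    and the event recorded in ``meta["separation_fallback"]``.
    """
    y = np.asarray(y, dtype=float)
    k = y.sum()
    if k == 0 or k == y.size:
        raise ValueError("degenerate logistic fit: only one class observed")
    b, v, converged = logistic_mle(y, design, start=start)
    fallback = (not converged) or np.abs(b).max() > SEPARATION_BOUND
    if fallback and start is not None:
        # a bad warm start is not evidence of separation; retry cold first
        b, v, converged = logistic_mle(y, design)
        fallback = (not converged) or np.abs(b).max() > SEPARATION_BOUND
    if fallback:
        b, v, converged = logistic_mle(y, design, penalty=RIDGE_PENALTY)
    meta = {"converged": converged, "separation_fallback": fallback, "mle": b}
    if not proper:
        return ParamDraw(b, None, meta | {"mode": "improper"})
    coef = b + np.linalg.cholesky(v) @ rng.standard_normal(b.size)
    return ParamDraw(coef, None, meta | {"mode": "proper", "vcov": v})


def impute_binary(
    design: np.ndarray, draw: ParamDraw, rng: np.random.Generator
) -> np.ndarray:
    """CE2 draw: Bernoulli(expit(x'b)) per row of ``design``, coded 0/1."""
    p1 = _expit(design @ draw.coefficients)
    return (rng.random(design.shape[0]) < p1).astype(float)


# ----------------------------------------------------------------------
# linear discriminant (GLOM) family


def draw_lda_glom(
    y: np.ndarray,
    w: np.ndarray,
    prior: GLOMPrior,
    rng: np.random.Generator,
    proper: bool = True,
) -> GLOMParams:
    """CE1 draw for a binary target via the general location model.

    ``y`` holds the binary target where observed and ``w`` the matching
    rows of the continuous covariates (current working values). Proper
    mode draws (gamma, mu0, mu1, Sigma) from the same GLOM posterior used
    by joint-model imputation, restricted to the observed-target rows;
    improper mode plugs in maximum-likelihood estimates. Imputation of the
    target then uses the implied class posterior pr(Y=1 | W) — see
    :func:`impute_binary_glom`.
    """
    y = np.asarray(y, dtype=float)
    w = np.atleast_2d(np.asarray(w, dtype=float))
    n = y.size
    k = y.sum()
    if k == 0 or k == n:
        raise ValueError("degenerate LDA fit: only one class observed")
    if proper:
        return _draw_theta(y, w, prior, rng)
    gamma = k / n
    b_hat, s, _ = ols_fit(add_intercept(y), w)
    return GLOMParams(gamma, b_hat[0], b_hat[1], np.atleast_2d(s) / n)


def impute_binary_glom(
    theta: GLOMParams, w: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw the binary target from pr(Y=1 | W, theta) for each row of ``w``."""
    p1 = _expit(class_log_odds(theta, w))
    return (rng.random(np.atleast_2d(w).shape[0]) < p1).astype(float)
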