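import numpy as np
import pytest
import statsmodels.api as sm

from helpers import irls_logistic

from micejm import (
    ConditionalSpec,
    GLOMParams,
    GLOMPrior,
    SimConfig,
    draw_lda_glom,
    draw_logistic_mvn,
    draw_normal_linear,
    impute_binary,
    impute_continuous,
    simulate_complete,
)
from micejm._linalg import add_intercept
from micejm.conditional_models import impute_binary_glom, logistic_mle
from micejm.joint_da import _draw_theta, class_log_odds


@pytest.fixture
def toy_regression(rng):
    x = add_intercept(rng.normal(size=(20, 2)))
    y = x @ np.array([1.0, -0.5, 2.0]) + rng.normal(scale=1.3, size=20)
    return y, x


def test_spec_validation():
    with pytest.raises(ValueError, match="family"):
        ConditionalSpec("Y", ("W1",), "poisson")
    with pytest.raises(ValueError, match="covariates"):
        ConditionalSpec("Y", ("Y", "W1"), "logistic_mvn")


# ---------------------------------------------------------------- normal linear


def test_improper_normal_linear_is_exact_ols(toy_regression, rng):
    y, x = toy_regression
    fit = sm.OLS(y, x).fit()
    draw = draw_normal_linear(y, x, rng, proper=False)
    assert np.allclose(draw.coefficients, fit.params, atol=1e-10)
    assert np.isclose(draw.scale, fit.ssr / len(y), atol=1e-10)  # variance MLE


def test_normal_linear_degenerate_inputs(rng):
    x = add_intercept(np.arange(6.0).reshape(6, 1))
    with pytest.raises(ValueError, match="identically zero"):
        draw_normal_linear(x @ np.array([1.0, 2.0]), x, rng)  # zero residuals
    with pytest.raises(np.linalg.LinAlgError):
        draw_normal_linear(
            np.arange(6.0), np.column_stack([x, x[:, 1]]), rng
        )  # rank deficient
    with pytest.raises(ValueError, match="too few"):
        draw_normal_linear(np.arange(3.0), add_intercept(np.eye(3)[:, :2]), rng)


def test_proper_draws_average_to_plugin(toy_regression, rng):
    """Improper mode is the deterministic center of proper mode."""
    y, x = toy_regression
    plug = draw_normal_linear(y, x, rng, proper=False)
    draws = np.array(
        [draw_normal_linear(y, x, rng).coefficients for _ in range(4000)]
    )
    se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
    assert np.all(np.abs(draws.mean(axis=0) - plug.coefficients) < 4 * se)


def test_impute_continuous_moments_and_degenerate_scale(rng):
    from micejm.conditional_models import ParamDraw

    x = add_intercept(np.tile([1.0, 2.0], (50_000, 1)))
    draw = ParamDraw(np.array([0.5, 1.0, -0.25]), scale=2.0)
    vals = impute_continuous(x, draw, rng)
    mean = 0.5 + 1.0 - 0.5
    assert abs(vals.mean() - mean) < 4 * np.sqrt(2.0 / len(vals))
    assert abs(vals.var(ddof=1) - 2.0) < 4 * 2.0 * np.sqrt(2 / len(vals))
    tiny = ParamDraw(draw.coefficients, scale=1e-30)
    assert np.allclose(impute_continuous(x[:10], tiny, rng), mean, atol=1e-10)
    with pytest.raises(ValueError, match="scale"):
        ParamDraw(np.zeros(2), scale=-1.0)


# ---------------------------------------------------------------- logistic


def test_intercept_only_mle_is_logit_of_proportion(rng):
    y = np.repeat([1.0, 0.0], 25)
    x = np.ones((50, 1))
    draw = draw_logistic_mvn(y, x, rng, proper=False)
    assert np.isclose(draw.coefficients[0], 0.0, atol=1e-8)
    y2 = np.repeat([1.0, 0.0], [10, 40])
    d2 = draw_logistic_mvn(y2, x, rng, proper=False)
    assert np.isclose(d2.coefficients[0], np.log(10 / 40), atol=1e-8)


def test_logistic_mle_matches_irls_and_statsmodels_oracles(rng):
    x = add_intercept(rng.normal(size=(60, 2)))
    p = 1 / (1 + np.exp(-(0.3 + 0.8 * x[:, 1] - 0.5 * x[:, 2])))
    y = (rng.random(60) < p).astype(float)
    draw = draw_logistic_mvn(y, x, rng, proper=False)
    assert np.abs(draw.coefficients - irls_logistic(y, x)).max() < 1e-8
    res = sm.Logit(y, x).fit(disp=0)
    assert np.abs(draw.coefficients - res.params).max() < 1e-8
    b, v, _ = logistic_mle(y, x)
    assert np.abs(v - res.cov_params()).max() < 1e-8


def test_proper_logistic_covariance_matches_vhat(rng):
    x = add_intercept(rng.normal(size=(80, 1)))
    y = (rng.random(80) < 0.4).astype(float)
    draws = np.array(
        [draw_logistic_mvn(y, x, rng).coefficients for _ in range(20000)]
    )
    _, v, _ = logistic_mle(y, x)
    emp = np.cov(draws.T)
    for i in range(2):
        for j in range(2):
            se = np.sqrt((v[i, i] * v[j, j] + v[i, j] ** 2) / len(draws))
            assert abs(emp[i, j] - v[i, j]) < 4 * se


def test_single_class_and_separation_handling(rng):
    x = np.ones((20, 1))
    with pytest.raises(ValueError, match="one class"):
        draw_logistic_mvn(np.ones(20), x, rng)
    # perfectly separated data: fallback engages, fit stays finite
    xx = add_intercept(np.linspace(-2, 2, 30).reshape(-1, 1))
    y = (xx[:, 1] > 0).astype(float)
    draw = draw_logistic_mvn(y, xx, rng, proper=False)
    assert draw.meta["separation_fallback"]
    assert np.all(np.isfinite(draw.coefficients))


def test_impute_binary_probabilities(rng):
    from micejm.conditional_models import ParamDraw

    n = 100_000
    x = np.ones((n, 1))
    half = impute_binary(x, ParamDraw(np.zeros(1)), rng)
    assert abs(half.mean() - 0.5) < 4 * np.sqrt(0.25 / n)
    sat = impute_binary(x[:500], ParamDraw(np.array([50.0])), rng)
    assert sat.min() == 1.0
    p = 1 / (1 + np.exp(-1.0))
    freq = impute_binary(x, ParamDraw(np.array([1.0])), rng)
    assert abs(freq.mean() - p) < 4 * np.sqrt(p * (1 - p) / n)


# ---------------------------------------------------------------- LDA / GLOM


def test_lda_improper_mles_have_closed_form(rng):
    data = simulate_complete(SimConfig(n=200, beta=1.0, seed=21))
    y, w = data.values[:, 0], data.values[:, 1:]
    theta = draw_lda_glom(y, w, GLOMPrior(), rng, proper=False)
    assert np.isclose(theta.gamma, y.mean())
    assert np.allclose(theta.mu0, w[y == 0].mean(axis=0), atol=1e-10)
    assert np.allclose(
        theta.mu0 + theta.mu1, w[y == 1].mean(axis=0), atol=1e-10
    )
    # pooled within-class scatter / n is the covariance MLE
    resid = w - theta.mu0 - np.outer(y, theta.mu1)
    assert np.allclose(theta.Sigma, resid.T @ resid / len(y), atol=1e-10)


def test_lda_proper_draw_shares_glom_posterior(rng):
    """With the same stream, the LDA draw equals the joint-model posterior draw
    restricted to the observed-target rows."""
    data = simulate_complete(SimConfig(n=80, beta=1.0, seed=22))
    y, w = data.values[:, 0], data.values[:, 1:]
    a = draw_lda_glom(y, w, GLOMPrior(), np.random.default_rng(99))
    b = _draw_theta(y, w, GLOMPrior(), np.random.default_rng(99))
    assert a.gamma == b.gamma
    assert np.array_equal(a.Sigma, b.Sigma) and np.array_equal(a.mu1, b.mu1)


def test_identical_class_means_impute_at_gamma(rng):
    theta = GLOMParams(0.3, np.array([1.0, 2.0]), np.zeros(2), np.eye(2))
    n = 50_000
    w = rng.normal(size=(n, 2)) * 5
    vals = impute_binary_glom(theta, w, rng)
    assert abs(vals.mean() - 0.3) < 4 * np.sqrt(0.3 * 0.7 / n)
    with pytest.raises(ValueError, match="one class"):
        draw_lda_glom(np.zeros(10), np.zeros((10, 2)), GLOMPrior(), rng)


def test_glom_log_odds_affine_in_w(rng):
    """log pr(Y=1|W)/pr(Y=0|W) computed from the two normal densities is an
    affine function of W to 1e-10 (the logistic-regression compatibility)."""
    for _ in range(20):
        q = 2
        a = rng.normal(size=(q, q))
        theta = GLOMParams(
            rng.uniform(0.1, 0.9),
            rng.normal(size=q),
            rng.normal(size=q),
            a @ a.T + np.eye(q),
        )
        w = rng.normal(scale=3, size=(50, q))
        lo = class_log_odds(theta, w)
        design = add_intercept(w)
        coef, *_ = np.linalg.lstsq(design, lo, rcond=None)
        assert np.abs(design @ coef - lo).max() < 1e-10
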