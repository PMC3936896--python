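import numpy as np
import pytest
from scipy import stats

from micejm import (
    DAConfig,
    Dataset,
    GLOMParams,
    GLOMPrior,
    SimConfig,
    apply_mcar_mask,
    draw_missing_glom,
    draw_theta_complete,
    pool_estimates,
    run_data_augmentation,
    simulate_complete,
)
from micejm.joint_da import _invwishart_rvs, class_log_odds


def toy_complete(n=30, seed=4, beta=1.0):
    return simulate_complete(SimConfig(n=n, beta=beta, seed=seed))


def test_gamma_posterior_is_conjugate_beta(rng):
    """gamma draws follow Beta(tau+n1, nu+n-n1); checked against a grid oracle."""
    data = toy_complete(n=40, seed=2)
    n = data.n_rows
    n1 = data.values[:, 0].sum()
    prior = GLOMPrior(tau=0.5, nu=0.5, kappa=1.5)
    draws = np.array(
        [draw_theta_complete(data, prior, rng).gamma for _ in range(20000)]
    )
    # independent grid-integration oracle of gamma^(tau-1)(1-gamma)^(nu-1) x likelihood
    g = np.linspace(1e-6, 1 - 1e-6, 20001)
    dens = (prior.tau - 1 + n1) * np.log(g) + (prior.nu - 1 + n - n1) * np.log1p(-g)
    dens = np.exp(dens - dens.max())
    oracle_mean = np.trapezoid(g * dens, g) / np.trapezoid(dens, g)
    assert np.isclose(oracle_mean, (prior.tau + n1) / (prior.tau + prior.nu + n), atol=1e-6)
    se = draws.std(ddof=1) / np.sqrt(draws.size)
    assert abs(draws.mean() - oracle_mean) < 4 * se


def test_degenerate_inputs_raise(rng):
    data = toy_complete(n=20, seed=3)
    vals = data.values.copy()
    vals[:, 0] = 0.0  # single class
    single = Dataset(vals, data.mask, data.column_types, data.column_names)
    with pytest.raises(ValueError, match="one Y class"):
        draw_theta_complete(single, GLOMPrior(), rng)
    vals2 = data.values.copy()
    vals2[:, 1] = 5.0 + vals2[:, 0]  # W1 exactly linear in Y -> singular scatter
    vals2[:, 2] = 1.0 + 2 * vals2[:, 0]
    degen = Dataset(vals2, data.mask, data.column_types, data.column_names)
    with pytest.raises(ValueError, match="singular"):
        draw_theta_complete(degen, GLOMPrior(), rng)


def test_invwishart_matches_scipy_moments(rng):
    """The Bartlett-decomposition draw agrees with scipy's inverse-Wishart."""
    s = np.array([[2.0, 0.7], [0.7, 1.5]])
    df = 12
    mine = np.mean([_invwishart_rvs(df, s, rng) for _ in range(30000)], axis=0)
    theory = s / (df - 2 - 1)
    scale_se = theory * 4 / np.sqrt(30000) * 3  # loose elementwise band
    assert np.all(np.abs(mine - theory) < np.abs(scale_se) + 4e-3)
    sp = stats.invwishart.rvs(df=df, scale=s, size=30000, random_state=rng).mean(axis=0)
    assert np.all(np.abs(mine - sp) < 0.01)


def test_class_posterior_closed_form():
    """log-odds from the two class densities match the affine closed form."""
    theta = GLOMParams(0.5, np.zeros(2), np.array([1.0, 0.0]), np.eye(2))
    # logit pr(Y=1|W) = logit(gamma) + mu1' Sigma^-1 W - mu1' Sigma^-1 (mu0 + mu1/2)
    lo = class_log_odds(theta, np.array([[0.5, 123.4]]))
    assert np.isclose(lo[0], 0.0, atol=1e-12)
    p = 1 / (1 + np.exp(-lo[0]))
    assert np.isclose(p, 0.5)
    # mu1 = 0: W carries no information, pr(Y=1|W) = gamma for any W
    flat = GLOMParams(0.3, np.array([1.0, -2.0]), np.zeros(2), np.eye(2))
    lo = class_log_odds(flat, np.array([[5.0, -7.0], [0.0, 0.0]]))
    assert np.allclose(1 / (1 + np.exp(-lo)), 0.3)


def test_conditional_w1_draw_matches_bivariate_conditioning(rng):
    """Draws of W1 | Y, W2 match the closed-form conditional normal."""
    sigma = np.array([[9.0, 1.0], [1.0, 9.0]])
    theta = GLOMParams(0.3, np.array([10.0, 12.0]), np.array([1.0, 1.0]), sigma)
    n = 100_000
    w2 = 13.0
    vals = np.column_stack([np.ones(n), np.full(n, np.nan), np.full(n, w2)])
    mask = np.column_stack([np.ones(n, bool), np.zeros(n, bool), np.ones(n, bool)])
    ds = Dataset(vals, mask, ("binary", "continuous", "continuous"), ("Y", "W1", "W2"))
    comp = draw_missing_glom(ds, theta, rng)
    draws = comp.values[:, 1]
    m1 = 10.0 + 1.0  # class-1 mean of W1
    m2 = 12.0 + 1.0
    cond_mean = m1 + sigma[0, 1] / sigma[1, 1] * (w2 - m2)
    cond_var = sigma[0, 0] - sigma[0, 1] ** 2 / sigma[1, 1]
    assert abs(draws.mean() - cond_mean) < 4 * np.sqrt(cond_var / n)
    assert abs(draws.var(ddof=1) - cond_var) < 4 * cond_var * np.sqrt(2 / n)


def test_rows_missing_both_draw_y_then_w1(rng, masked_glom):
    """Completion fills every masked cell, keeps observed cells, respects types."""
    theta = GLOMParams(
        0.3, np.array([10.0, 12.0]), np.array([3.0, 3.3]),
        np.array([[9.0, 1.0], [1.0, 9.89]]),
    )
    comp = draw_missing_glom(masked_glom, theta, rng)
    assert comp.is_complete()
    assert np.array_equal(
        comp.values[masked_glom.mask], masked_glom.values[masked_glom.mask]
    )
    assert set(np.unique(comp.values[:50, 0])) <= {0.0, 1.0}


def test_da_schedule_and_complete_data_shortcut():
    data = toy_complete(n=25, seed=6)
    # fully observed: nothing to impute, input returned unchanged
    out = run_data_augmentation(data, GLOMPrior(), DAConfig(3, 0, 1, seed=1))
    assert len(out) == 3
    assert np.array_equal(out[0].values, data.values)
    masked = apply_mcar_mask(toy_complete(n=60, seed=8), 20)
    out = run_data_augmentation(masked, GLOMPrior(), DAConfig(4, 5, 3, seed=2))
    assert len(out) == 4
    for ds in out:
        assert ds.is_complete()
        assert np.array_equal(ds.values[masked.mask], masked.values[masked.mask])


def test_pooling_is_the_mean_of_per_dataset_fits():
    data = toy_complete(n=50, seed=10)
    assert np.isclose(
        pool_estimates([data, data]), pool_estimates([data]), atol=1e-12
    )


def test_pooled_estimate_unbiased_at_n1000():
    """With n=1000 the pooled joint-model estimate centers on the true beta."""
    estimates = []
    for i in range(8):
        complete = simulate_complete(SimConfig(n=1000, beta=1.0, n_missing=500, seed=100 + i))
        masked = apply_mcar_mask(complete, 500)
        out = run_data_augmentation(masked, GLOMPrior(), DAConfig(10, 30, 3, seed=i))
        estimates.append(pool_estimates(out))
    estimates = np.array(estimates)
    se = estimates.std(ddof=1) / np.sqrt(estimates.size)
    assert abs(estimates.mean() - 1.0) < 4 * se


def test_imputation_invariant_to_continuous_column_order():
    """Storing (Y, W2, W1) instead of (Y, W1, W2) leaves pooled estimates unchanged
    in distribution (single joint draw has no update ordering)."""
    pooled_a, pooled_b = [], []
    for i in range(10):
        complete = simulate_complete(SimConfig(n=100, beta=3.0, seed=300 + i))
        masked = apply_mcar_mask(complete, 50)
        swapped = Dataset(
            masked.values[:, [0, 2, 1]],
            masked.mask[:, [0, 2, 1]],
            ("binary", "continuous", "continuous"),
            ("Y", "W2", "W1"),
        )
        cfg = DAConfig(10, 20, 5, seed=i)
        pooled_a.append(pool_estimates(run_data_augmentation(masked, GLOMPrior(), cfg)))
        pooled_b.append(pool_estimates(run_data_augmentation(swapped, GLOMPrior(), cfg)))
    d = np.array(pooled_a) - np.array(pooled_b)
    se = d.std(ddof=1) / np.sqrt(d.size)
    assert abs(d.mean()) < 4 * se
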