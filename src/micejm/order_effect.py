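"""Order-effect diagnostics for the chained-equations sampler.

Within each iteration the analysis model (OLS of W2 on W1 and Y) is
refitted immediately after the binary variable is updated and again after
the continuous variable is updated, giving paired series beta_hat_b and
beta_hat_c of the Y coefficient. Averaging over retained iterations gives
beta_bar_b and beta_bar_c; their difference estimates the order effect in
one dataset. Because the series are serially correlated MCMC output, the
Monte Carlo standard error of the mean difference is estimated by the
batch-means method, and a 95% normal-theory confidence interval flags
datasets with significant order effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._linalg import add_intercept, ols_fit
from .dataset import Dataset
from .mice_engine import ImputationTrace

__all__ = [
    "OrderEffectResult",
    "analysis_fit",
    "analysis_hook",
    "batch_means_se",
    "forest_plot",
    "order_effect_from_series",
    "order_effect_test",
]


@dataclass(frozen=True)
class OrderEffectResult:
    """Mean analysis-model estimates after each update and their difference."""

    beta_bar_b: float
    beta_bar_c: float
    diff: float
    mcse: float
    ci_low: float
    ci_high: float
    significant: bool


def analysis_fit(
    completed: Dataset | np.ndarray,
    response: str | int = "W2",
    covariates: tuple = ("W1", "Y"),
    coefficient: str | int = "Y",
    column_names: tuple[str, ...] = ("Y", "W1", "W2"),
) -> float:
    """OLS coefficient of ``coefficient`` in the regression of the response.

    Accepts either a completed :class:`Dataset` or a bare value matrix
    (columns named by ``column_names``). Raises on a rank-deficient
    design, e.g. when Y is constant across rows.
    """
    if isinstance(completed, Dataset):
        values, names = completed.values, completed.column_names
    else:
        values, names = np.asarray(completed, dtype=float), column_names
    idx = {n: j for j, n in enumerate(names)}
    cols = [idx[c] if isinstance(c, str) else c for c in covariates]
    design = add_intercept(values[:, cols])
    y = values[:, idx[response] if isinstance(response, str) else response]
    coef, _, _ = ols_fit(design, y)
    pos = covariates.index(coefficient)
    return float(coef[1 + pos])


def analysis_hook(
    response: int, covariates: tuple[int, ...], coefficient_pos: int = 1
) -> callable:
    """Build a chain hook that records one analysis-model coefficient.

    Index-based so it can run tens of thousands of times per chain;
    ``coefficient_pos`` indexes ``covariates`` (default: its second
    entry, which is Y in the study's (W1, Y) ordering).
    """
    cov = list(covariates)
    buf: dict[int, np.ndarray] = {}  # reusable design matrix per row count

    def hook(values: np.ndarray, column: str, iteration: int) -> float:
        n = values.shape[0]
        design = buf.get(n)
        if design is None:
            design = buf[n] = np.ones((n, 1 + len(cov)))
        design[:, 1:] = values[:, cov]
        xtx = design.T @ design
        xty = design.T @ values[:, response]
        coef = np.linalg.solve(xtx, xty)
        return float(coef[1 + coefficient_pos])

    return hook


def default_batch_count(length: int) -> int:
    """Largest divisor of ``length`` not exceeding floor(sqrt(length)).

    Gives 100 batches for the study's 10000 retained iterations.
    """
    for b in range(int(np.sqrt(length)), 1, -1):
        if length % b == 0:
            return b
    raise ValueError(f"series of length {length} cannot be split into >= 2 batches")


def batch_means_se(series: np.ndarray, n_batches: int | None = None) -> float:
    """Batch-means Monte Carlo standard error of the series mean.

    Partitions the series into ``n_batches`` consecutive equal batches and
    returns sd(batch means) / sqrt(n_batches), the standard estimator for
    the standard error of a correlated chain's mean.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if n_batches is None:
        n_batches = default_batch_count(n)
    if n_batches < 2:
        raise ValueError("need at least 2 batches")
    if n % n_batches != 0:
        raise ValueError(f"length {n} is not divisible into {n_batches} equal batches")
    size = n // n_batches
    if size < 2:
        raise ValueError("batches must have size >= 2")
    if np.all(series == series[0]):
        return 0.0
    means = series.reshape(n_batches, size).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def order_effect_from_series(
    beta_b: np.ndarray, beta_c: np.ndarray, n_batches: int | None = None
) -> OrderEffectResult:
    """Order-effect estimate from paired retained series of analysis fits.

    The batch-means MCSE is computed on the per-iteration difference
    series d_t = beta_hat_b[t] - beta_hat_c[t]; the 95% CI is
    mean(d) ± 1.96 * MCSE and the effect is flagged significant when the
    interval excludes zero.
    """
    beta_b = np.asarray(beta_b, dtype=float)
    beta_c = np.asarray(beta_c, dtype=float)
    if beta_b.size == 0 or beta_b.shape != beta_c.shape:
        raise ValueError("need nonempty, equal-length paired series")
    d = beta_b - beta_c
    diff = float(d.mean())
    mcse = batch_means_se(d, n_batches)
    lo, hi = diff - 1.96 * mcse, diff + 1.96 * mcse
    return OrderEffectResult(
        beta_bar_b=float(beta_b.mean()),
        beta_bar_c=float(beta_c.mean()),
        diff=diff,
        mcse=mcse,
        ci_low=lo,
        ci_high=hi,
        significant=not (lo <= 0.0 <= hi),
    )


def forest_plot(results: list[OrderEffectResult], path, max_datasets: int = 30):
    """Forest plot of per-dataset order effects with 95% batch-means CIs.

    One marker per dataset at beta_bar_b - beta_bar_c, horizontal bar for
    the CI, dashed line at zero. Writes the figure to ``path``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = results[:max_datasets]
    fig, ax = plt.subplots(figsize=(5, 0.22 * len(rows) + 1))
    for i, r in enumerate(rows):
        y = len(rows) - i
        color = "firebrick" if r.significant else "gray"
        ax.plot([r.ci_low, r.ci_high], [y, y], color=color, lw=1.2)
        ax.plot(r.diff, y, "o", color=color, ms=3)
    ax.axvline(0.0, ls="--", color="black", lw=0.8)
    ax.set_xlabel(r"$\bar\beta_b - \bar\beta_c$ (95% CI)")
    ax.set_ylabel("dataset")
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def order_effect_test(
    trace: ImputationTrace,
    hook: str = "analysis",
    first: str = "Y",
    second: str = "W1",
    n_batches: int | None = None,
) -> OrderEffectResult:
    """Order-effect estimate from a chain trace carrying an analysis hook.

    ``first``/``second`` name the columns whose post-update records form
    beta_hat_b and beta_hat_c respectively.
    """
    return order_effect_from_series(
        trace.retained(hook, first), trace.retained(hook, second), n_batches
    )
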