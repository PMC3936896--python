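"""Synthetic data from a trivariate general location model with MCAR missingness.

The generating model is the study design used throughout this package: one
binary variable and two continuous variables,

    Y  ~ Bernoulli(gamma),
    W1 | Y       ~ N(mu_w1 + beta * Y, var_w1),
    W2 | W1, Y   ~ N(intercept_w2 + slope_w1 * W1 + beta * Y, var_w2),

with defaults gamma = 3/10, mu_w1 = 10, var_w1 = 9, intercept_w2 = 9 + 8/9,
slope_w1 = 1/9 and var_w2 = 8 + 8/9, n = 100 subjects. Missingness is MCAR
by design: Y and W1 are deleted for the first ``n_missing`` = 50 rows, so
any systematic imputation effect downstream cannot be an artefact of the
missingness mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataset import Dataset

__all__ = ["SimConfig", "simulate_complete", "apply_mcar_mask"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the generating model and the MCAR design."""

    n: int = 100
    beta: float = 1.0
    gamma: float = 0.3
    mu_w1: float = 10.0
    var_w1: float = 9.0
    intercept_w2: float = 9.0 + 8.0 / 9.0
    slope_w1: float = 1.0 / 9.0
    var_w2: float = 8.0 + 8.0 / 9.0
    n_missing: int | None = None  # None: half the rows (the 50-of-100 design)
    seed: int = 0

    @property
    def resolved_n_missing(self) -> int:
        return self.n // 2 if self.n_missing is None else self.n_missing

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie strictly between 0 and 1")
        if self.var_w1 <= 0 or self.var_w2 <= 0:
            raise ValueError("residual variances must be positive")
        if not 0 <= self.resolved_n_missing <= self.n:
            raise ValueError("n_missing must lie in [0, n]")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def simulate_complete(config: SimConfig, rng: np.random.Generator | None = None) -> Dataset:
    """Draw a fully observed ``n x 3`` dataset (columns Y, W1, W2).

    Rows are i.i.d. from the general location model described in the module
    docstring. Reproducible: with ``rng`` omitted, the stream is
    ``np.random.default_rng(config.seed)``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    y = (rng.random(n) < config.gamma).astype(float)
    w1 = config.mu_w1 + config.beta * y + rng.normal(0.0, np.sqrt(config.var_w1), n)
    w2 = (
        config.intercept_w2
        + config.slope_w1 * w1
        + config.beta * y
        + rng.normal(0.0, np.sqrt(config.var_w2), n)
    )
    values = np.column_stack([y, w1, w2])
    mask = np.ones_like(values, dtype=bool)
    return Dataset(values, mask, ("binary", "continuous", "continuous"), ("Y", "W1", "W2"))


def apply_mcar_mask(
    data: Dataset,
    n_missing: int,
    target_columns: tuple[str, ...] = ("Y", "W1"),
) -> Dataset:
    """Delete the target columns for the first ``n_missing`` rows.

    Observed cells are untouched; the deleted values are retained privately
    on the returned dataset (see :meth:`Dataset.hidden_truth`) for
    validation only — no imputation routine can reach them.
    """
    if not 0 <= n_missing <= data.n_rows:
        raise ValueError(f"n_missing must lie in [0, {data.n_rows}]")
    cols = [data.column_index(name) for name in target_columns]
    mask = data.mask.copy()
    mask[:n_missing, cols] = False
    hidden = np.where(data.mask, data.values, np.nan)
    values = np.where(mask, data.values, np.nan)
    return Dataset(
        values,
        mask,
        data.column_types,
        data.column_names,
        _hidden=hidden,
    )
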