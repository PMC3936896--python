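"""The chained-equations (fully conditional specification) sampler.

Each iteration visits the incomplete variables in a configurable order.
For each variable the two-step update is applied: CE1 draws the
imputation-model parameter from (or, improper mode, plugs in the MLE of)
its posterior given the rows where that variable is observed and the
current values of all other variables; CE2 redraws that variable's
missing cells from the fitted predictive distribution. Named hooks fire
after every single-variable update — the order-effect diagnostic uses a
hook that refits the analysis model on the working data — and their
records, with burn-in discarded and thinning applied, form the
:class:`ImputationTrace`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ._linalg import add_intercept
from .conditional_models import (
    ConditionalSpec,
    draw_lda_glom,
    draw_logistic_mvn,
    draw_normal_linear,
    impute_binary,
    impute_binary_glom,
    impute_continuous,
)
from .dataset import Dataset
from .joint_da import GLOMPrior, _initial_fill

__all__ = [
    "ChainConfig",
    "ImputationTrace",
    "initialize_missing",
    "run_chain",
    "extract_imputations",
]

#: hook signature: fn(working_values, column_just_updated, iteration) -> float
Hook = Callable[[np.ndarray, str, int], float]


@dataclass(frozen=True)
class ChainConfig:
    """Schedule of the chained-equations sampler.

    ``n_iter`` total iterations; the first ``burn_in`` are discarded from
    hook records; records are then retained every ``thin`` iterations.
    ``store_completed`` keeps a completed snapshot of the working data at
    each retained iteration (disable in large studies where only the hook
    records are needed).
    """

    visit_order: tuple[str, ...]
    n_iter: int = 10010
    burn_in: int = 10
    thin: int = 1
    seed: int = 0
    hooks: dict[str, Hook] = field(default_factory=dict)
    store_completed: bool = True

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class ImputationTrace:
    """Per-iteration hook records plus retained completed datasets.

    ``records[hook][column]`` is the full length-``n_iter`` series of hook
    values recorded immediately after each update of ``column``;
    :meth:`retained` applies the burn-in/thinning schedule.
    """

    config: ChainConfig
    records: dict[str, dict[str, np.ndarray]]
    completed: list[Dataset]
    retained_iterations: np.ndarray
    final_values: np.ndarray | None = None

    def retained(self, hook: str, column: str) -> np.ndarray:
        """Hook series at the retained iterations (burn-in dropped, thinned)."""
        return self.records[hook][column][self.retained_iterations - 1]

    @property
    def n_retained(self) -> int:
        return self.retained_iterations.size


def initialize_missing(data: Dataset, rng: np.random.Generator) -> Dataset:
    """Fill each missing cell with a uniform draw from its column's observed values.

    Returns a completed copy; the original dataset keeps the mask that
    tells the engine which cells to update. A fully observed dataset is
    returned unchanged.
    """
    if data.is_complete():
        return data.copy()
    for j, name in enumerate(data.column_names):
        if not data.mask[:, j].any():
            raise ValueError(f"column {name!r} is entirely missing; cannot initialize")
    return data.completed(_initial_fill(data.values, data.mask, rng))


def _check_specs(data: Dataset, specs: list[ConditionalSpec], cfg: ChainConfig):
    by_target = {s.target: s for s in specs}
    if len(by_target) != len(specs):
        raise ValueError("duplicate target in conditional specs")
    incomplete = set(data.incomplete_columns)
    if not incomplete <= set(cfg.visit_order):
        raise ValueError(
            f"visit_order {cfg.visit_order} must cover the incomplete "
            f"columns {sorted(incomplete)}"
        )
    for name in cfg.visit_order:
        if name not in by_target:
            raise ValueError(f"no conditional spec for incomplete column {name!r}")
    return by_target


def run_chain(
    data: Dataset,
    specs: list[ConditionalSpec],
    cfg: ChainConfig,
    rng: np.random.Generator | None = None,
) -> ImputationTrace:
    """Run the chained-equations sampler and return its trace.

    CE1 fits condition on current imputed values of the other columns for
    the rows where the target is observed; observed cells are never
    rewritten. Hook exceptions abort the run with context.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    by_target = _check_specs(data, specs, cfg)
    work = initialize_missing(data, rng).values  # ndarray copy, fully filled

    # precompute per-column structures
    plans = []
    for name in cfg.visit_order:
        spec = by_target[name]
        j = data.column_index(name)
        cov = np.array([data.column_index(c) for c in spec.covariates])
        obs = data.mask[:, j]
        mis = ~obs
        prior = GLOMPrior(**spec.prior) if spec.family == "lda_glom" else None
        kappa = spec.prior.get("kappa", 1.5) if spec.family == "normal_linear" else None
        obs_grid = np.ix_(obs, cov)
        mis_grid = np.ix_(mis, cov) if mis.any() else None
        plans.append((name, spec, j, cov, obs, mis, prior, kappa, obs_grid, mis_grid))

    n_iter = cfg.n_iter
    records = {
        h: {name: np.empty(n_iter) for name in cfg.visit_order} for h in cfg.hooks
    }
    retained = np.arange(cfg.burn_in + cfg.thin, n_iter + 1, cfg.thin)
    retained_set = set(retained.tolist()) if cfg.store_completed else set()
    completed: list[Dataset] = []
    observed_snapshot = data.values[data.mask].copy()
    warm_starts: dict[str, np.ndarray] = {}

    for t in range(1, n_iter + 1):
        for name, spec, j, cov, obs, mis, prior, kappa, obs_grid, mis_grid in plans:
            y_obs = data.values[obs, j]
            if spec.family == "lda_glom":
                theta = draw_lda_glom(y_obs, work[obs_grid], prior, rng, spec.proper)
                if mis_grid is not None:
                    work[mis, j] = impute_binary_glom(theta, work[mis_grid], rng)
            else:
                x_obs = add_intercept(work[obs_grid])
                if spec.family == "logistic_mvn":
                    draw = draw_logistic_mvn(
                        y_obs, x_obs, rng, spec.proper, start=warm_starts.get(name)
                    )
                    warm_starts[name] = draw.meta["mle"]
                    if mis_grid is not None:
                        work[mis, j] = impute_binary(add_intercept(work[mis_grid]), draw, rng)
                else:
                    draw = draw_normal_linear(y_obs, x_obs, rng, spec.proper, kappa)
                    if mis_grid is not None:
                        work[mis, j] = impute_continuous(add_intercept(work[mis_grid]), draw, rng)
            for hname, fn in cfg.hooks.items():
                try:
                    records[hname][name][t - 1] = fn(work, name, t)
                except Exception as exc:  # noqa: BLE001 - re-raise with context
                    raise RuntimeError(
                        f"hook {hname!r} failed at iteration {t} after updating {name!r}"
                    ) from exc
        if t in retained_set:
            completed.append(data.completed(work))

    # write barrier: observed cells must be untouched
    assert np.array_equal(data.values[data.mask], observed_snapshot)
    return ImputationTrace(cfg, records, completed, retained, final_values=work.copy())


def extract_imputations(trace: ImputationTrace, m: int) -> list[Dataset]:
    """The last ``m`` retained completed datasets (m=1: the final iteration's)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not trace.completed:
        raise ValueError("trace stored no completed datasets (store_completed=False?)")
    if m > len(trace.completed):
        raise ValueError(f"m={m} exceeds {len(trace.completed)} retained datasets")
    return trace.completed[-m:]
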