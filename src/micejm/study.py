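"""Orchestration of the full simulation study.

For each replicate dataset (n = 100 rows from the general location model,
Y and W1 deleted MCAR on the first 50 rows), every requested arm is run
on the identical masked data:

* ``CCA``    — complete-case OLS of W2 on (W1, Y);
* ``JM``     — joint-model imputation by data augmentation, pooling the
  analysis-model Y coefficient over the imputed datasets;
* ``CE_LR``  — chained equations with a logistic-regression conditional
  for Y, with the order-effect diagnostic;
* ``CE_LDA`` — chained equations with the linear-discriminant (GLOM)
  conditional for Y.

Replication discipline: base seed -> per-dataset seed (base + index) ->
per-arm substream at a fixed position per arm name, so every arm sees the
same datasets and per-arm results do not depend on which other arms run.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._linalg import add_intercept, ols_fit
from .conditional_models import ConditionalSpec
from .dataset import Dataset
from .glom_sim import SimConfig, apply_mcar_mask, simulate_complete
from .joint_da import DAConfig, GLOMPrior, pool_estimates, run_data_augmentation
from .mice_engine import ChainConfig, run_chain
from .order_effect import OrderEffectResult, analysis_hook, order_effect_test

__all__ = [
    "StudyConfig",
    "StudySummary",
    "run_study",
    "complete_case_estimate",
    "count_significant",
    "ce_specs",
]

ARMS = ("CCA", "JM", "CE_LR", "CE_LDA")


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one simulation study.

    Defaults follow the study design: 500 datasets of n = 100, effect
    sizes beta in {1, 3}, chained equations with 10010 iterations (10
    burn-in, thinning 1), joint modelling with 100 imputations / 100
    burn-in / 100 thinning, proper imputation, prior tau = nu = 1/2,
    kappa = 3/2, and 100 batches for the batch-means MCSE.
    """

    n_datasets: int = 500
    n: int = 100
    betas: tuple[float, ...] = (1.0, 3.0)
    arms: tuple[str, ...] = ARMS
    n_missing: int = 50
    ce_n_iter: int = 10010
    ce_burn_in: int = 10
    ce_thin: int = 1
    jm_m: int = 100
    jm_burn_in: int = 100
    jm_thin: int = 100
    proper: bool = True
    prior: GLOMPrior = GLOMPrior()
    n_batches: int | None = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if not self.arms:
            raise ValueError("at least one arm is required")
        for arm in self.arms:
            if arm not in ARMS:
                raise ValueError(f"unknown arm {arm!r}; choose from {ARMS}")

    # named sensitivity presets
    def jm250(self) -> "StudyConfig":
        from dataclasses import replace

        return replace(self, jm_m=250, jm_burn_in=250, jm_thin=250)

    def ce_burn1000(self) -> "StudyConfig":
        from dataclasses import replace

        return replace(self, ce_n_iter=11000, ce_burn_in=1000)

    def ce_thin50(self) -> "StudyConfig":
        from dataclasses import replace

        # thinning shortens the retained series; keep 200 retained draws
        return replace(self, ce_n_iter=10 + 50 * 200, ce_burn_in=10, ce_thin=50,
                       n_batches=None)

    def n1000(self) -> "StudyConfig":
        from dataclasses import replace

        return replace(self, n=1000, n_missing=500)


@dataclass
class StudySummary:
    """Per-dataset results plus Table-style aggregates.

    ``per_dataset`` has one row per (dataset, beta, arm); ``table`` one
    row per (beta, arm) with the across-dataset mean and its
    mean ± 1.96 sd/sqrt(D) confidence interval, and for CE arms the means
    of beta_bar_b, beta_bar_c and |beta_bar_b - beta_bar_c| with CIs plus
    the count of datasets showing a significant order effect.
    """

    config: StudyConfig
    per_dataset: pd.DataFrame
    table: pd.DataFrame = field(init=False)

    def __post_init__(self):
        self.table = _aggregate(self.per_dataset)

    def cell(self, beta: float, arm: str) -> pd.Series:
        t = self.table
        row = t[(t["beta"] == beta) & (t["arm"] == arm)]
        if row.empty:
            raise KeyError(f"no results for beta={beta}, arm={arm}")
        return row.iloc[0]


def complete_case_estimate(
    data: Dataset,
    response: str = "W2",
    covariates: tuple[str, ...] = ("W1", "Y"),
    coefficient: str = "Y",
) -> float:
    """OLS coefficient restricted to rows with no missing values."""
    rows = data.complete_rows
    if rows.sum() < len(covariates) + 2:
        raise ValueError("too few complete rows for the complete-case fit")
    cols = [data.column_index(c) for c in covariates]
    design = add_intercept(data.values[np.ix_(rows, cols)])
    y = data.values[rows, data.column_index(response)]
    coef, _, _ = ols_fit(design, y)
    return float(coef[1 + covariates.index(coefficient)])


def count_significant(results: list[OrderEffectResult]) -> int:
    """Number of order-effect results whose 95% CI excludes zero."""
    if not results:
        raise ValueError("empty result list")
    return int(sum(r.significant for r in results))


def ce_specs(kind: str, proper: bool = True, prior: GLOMPrior = GLOMPrior()):
    """Conditional specs of the two chained-equations arms.

    Y is imputed given (W1, W2) — logistic regression for ``CE_LR``, the
    GLOM/linear-discriminant fit for ``CE_LDA`` — and W1 given (Y, W2)
    under the normal linear model with prior ∝ omega^(-kappa); main
    effects only.
    """
    if kind == "CE_LR":
        y_spec = ConditionalSpec("Y", ("W1", "W2"), "logistic_mvn", proper=proper)
    elif kind == "CE_LDA":
        y_spec = ConditionalSpec(
            "Y",
            ("W1", "W2"),
            "lda_glom",
            prior={"tau": prior.tau, "nu": prior.nu, "kappa": prior.kappa},
            proper=proper,
        )
    else:
        raise ValueError(f"unknown CE arm {kind!r}")
    w1_spec = ConditionalSpec(
        "W1", ("Y", "W2"), "normal_linear", prior={"kappa": prior.kappa}, proper=proper
    )
    return [y_spec, w1_spec]


_ANALYSIS_HOOK = {"analysis": analysis_hook(response=2, covariates=(1, 0), coefficient_pos=1)}


def _run_arm(arm: str, masked: Dataset, cfg: StudyConfig, rng: np.random.Generator) -> dict:
    if arm == "CCA":
        return {"estimate": complete_case_estimate(masked)}
    if arm == "JM":
        completed = run_data_augmentation(
            masked,
            cfg.prior,
            DAConfig(cfg.jm_m, cfg.jm_burn_in, cfg.jm_thin),
            rng=rng,
        )
        return {"estimate": pool_estimates(completed)}
    # chained-equations arms
    chain_cfg = ChainConfig(
        visit_order=("Y", "W1"),
        n_iter=cfg.ce_n_iter,
        burn_in=cfg.ce_burn_in,
        thin=cfg.ce_thin,
        hooks=_ANALYSIS_HOOK,
        store_completed=False,
    )
    trace = run_chain(masked, ce_specs(arm, cfg.proper, cfg.prior), chain_cfg, rng=rng)
    res = order_effect_test(trace, n_batches=cfg.n_batches)
    return {
        "estimate": res.beta_bar_b,
        "beta_bar_b": res.beta_bar_b,
        "beta_bar_c": res.beta_bar_c,
        "diff": res.diff,
        "abs_diff": abs(res.diff),
        "mcse": res.mcse,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "significant": bool(res.significant),
    }


_COLUMNS = [
    "dataset",
    "beta",
    "arm",
    "estimate",
    "beta_bar_b",
    "beta_bar_c",
    "diff",
    "abs_diff",
    "mcse",
    "ci_low",
    "ci_high",
    "significant",
    "error",
]


def run_study(config: StudyConfig, out_dir: str | None = None) -> StudySummary:
    """Run every arm on every simulated dataset and aggregate.

    Arm failures are recorded per dataset (``error`` column) and the study
    continues. With ``out_dir`` set, per-dataset rows are appended to
    ``per_dataset.csv`` as they complete and previously written rows are
    reused, so an interrupted study resumes where it stopped.
    """
    rows: list[dict] = []
    done: set[tuple] = set()
    csv_path = None
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        csv_path = os.path.join(out_dir, "per_dataset.csv")
        if os.path.exists(csv_path):
            prev = pd.read_csv(csv_path)
            rows = prev.to_dict("records")
            done = {(r["dataset"], r["beta"], r["arm"]) for r in rows}

    for i in range(config.n_datasets):
        for beta in config.betas:
            # one stream per dataset (base seed + index), one substream per
            # beta, fixed substream positions per arm -> arm-order invariance
            ds_seq = np.random.SeedSequence(
                config.seed + i, spawn_key=(int(round(10 * beta)),)
            )
            streams = ds_seq.spawn(1 + len(ARMS))
            sim = SimConfig(n=config.n, beta=beta, n_missing=config.n_missing)
            complete = simulate_complete(sim, rng=np.random.default_rng(streams[0]))
            masked = apply_mcar_mask(complete, config.n_missing)
            for arm in config.arms:
                key = (i, beta, arm)
                if key in done:
                    continue
                arm_rng = np.random.default_rng(streams[1 + ARMS.index(arm)])
                row = {"dataset": i, "beta": beta, "arm": arm, "error": ""}
                try:
                    row.update(_run_arm(arm, masked, config, arm_rng))
                except Exception as exc:  # noqa: BLE001 - study continues
                    row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
                if csv_path is not None:
                    pd.DataFrame([row]).reindex(columns=_COLUMNS).to_csv(
                        csv_path,
                        mode="a",
                        header=not os.path.exists(csv_path),
                        index=False,
                    )
    frame = pd.DataFrame(rows).reindex(columns=_COLUMNS)
    return StudySummary(config, frame)


def _mean_ci(x: pd.Series) -> tuple[float, float, float]:
    x = x.dropna()
    m = float(x.mean())
    half = 1.96 * float(x.std(ddof=1)) / np.sqrt(len(x)) if len(x) > 1 else 0.0
    return m, m - half, m + half


def _aggregate(per_dataset: pd.DataFrame) -> pd.DataFrame:
    out = []
    for (beta, arm), grp in per_dataset.groupby(["beta", "arm"], sort=True):
        ok = grp[grp["error"].fillna("") == ""]
        rec: dict = {
            "beta": beta,
            "arm": arm,
            "n_datasets": len(ok),
            "n_failed": len(grp) - len(ok),
        }
        rec["mean"], rec["ci_low"], rec["ci_high"] = _mean_ci(ok["estimate"])
        if arm.startswith("CE"):
            for fieldname in ("beta_bar_b", "beta_bar_c", "abs_diff"):
                m, lo, hi = _mean_ci(ok[fieldname])
                rec[f"mean_{fieldname}"] = m
                rec[f"{fieldname}_ci_low"] = lo
                rec[f"{fieldname}_ci_high"] = hi
            rec["n_significant"] = int(ok["significant"].sum())
        out.append(rec)
    return pd.DataFrame(out)
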