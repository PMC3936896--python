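"""A scaled-down run of the full simulation study.

Forty replicate datasets per effect size (the full design uses 500) with
1010-iteration chained-equations samplers; arms: complete-case analysis,
joint-model imputation, chained equations with logistic-regression (LR)
and linear-discriminant (LDA) conditionals for Y. Expect: unbiased CCA,
order effects larger at beta = 3 than beta = 1 and larger for LR than
LDA, and a significance count well above the 5% nominal rate.
"""

import pandas as pd

from micejm import StudyConfig, run_study

config = StudyConfig(
    n_datasets=40,
    betas=(1.0, 3.0),
    arms=("CCA", "JM", "CE_LR", "CE_LDA"),
    ce_n_iter=1010,
    ce_burn_in=10,
    jm_m=20,
    jm_burn_in=50,
    jm_thin=10,
    n_batches=None,
    seed=0,
)
summary = run_study(config)

pd.set_option("display.width", 160)
cols = ["beta", "arm", "mean", "ci_low", "ci_high",
        "mean_abs_diff", "n_significant", "n_failed"]
print(summary.table[cols].round(4).to_string(index=False))
print("\nmean: across-dataset mean of the estimate of beta "
      "(beta_bar_b for the chained-equations arms)")
print("mean_abs_diff: average |beta_bar_b - beta_bar_c| — the order-effect size")
print("n_significant: datasets whose 95% batch-means CI excludes zero")
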