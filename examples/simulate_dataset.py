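"""Simulate one study dataset and delete Y, W1 on the first 50 rows.

The generating model is the general location model
Y ~ Bernoulli(0.3), W1|Y ~ N(10 + beta*Y, 9),
W2|W1,Y ~ N(9+8/9 + W1/9 + beta*Y, 8+8/9); missingness is MCAR by design.
"""

import numpy as np

from micejm import SimConfig, apply_mcar_mask, simulate_complete, write_csv

config = SimConfig(n=100, beta=3.0, n_missing=50, seed=44)
complete = simulate_complete(config)
masked = apply_mcar_mask(complete, config.resolved_n_missing)

print(f"simulated {masked.n_rows} rows; columns: {masked.column_names}")
print(f"complete rows: {masked.complete_rows.sum()} (rows 51-100)")
print(f"observed mean of Y: {np.nanmean(masked.values[:, 0]):.3f} (population 0.3)")
print(f"observed mean of W1: {np.nanmean(masked.values[:, 1]):.2f} (10 + 3*0.3 = 10.9)")

write_csv(masked, "scratch_example_dataset.csv")
print("wrote scratch_example_dataset.csv (missing cells as the token NA)")
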