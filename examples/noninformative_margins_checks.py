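"""Numeric checks of the non-informative-margins condition.

For the multivariate normal, the prior |Sigma|^(-kappa) factorizes into
independent priors for a coordinate's regression parameters and the
margin of the remaining coordinates because |Sigma| = omega_j *
|Sigma_tilde_j| (Schur). For the saturated multinomial, collapsing the
Dirichlet hyperparameter table gives the margin's prior, independent of
the conditional blocks. In both cases chained equations is a genuine
Gibbs sampler, so chained and joint imputation agree — verified here by
Monte Carlo.
"""

import numpy as np

from micejm import (
    DirichletTable,
    det_partition_identity,
    dirichlet_collapse,
    equivalence_multinomial,
    equivalence_mvn,
    mvn_conditional,
    MVNPartition,
)

sigma = np.array([[2.0, 1.0, 0.5], [1.0, 2.0, 0.8], [0.5, 0.8, 1.5]])
alpha_j, beta_j, omega_j = mvn_conditional(MVNPartition.from_joint(np.zeros(3), sigma, 0))
print(f"X1 | X2, X3: slope {np.round(beta_j, 3)}, residual variance {omega_j:.3f}")
print(f"Schur determinant identity discrepancy: {det_partition_identity(sigma, 0):.2e}")

table = DirichletTable(np.ones((2, 2)))
print(f"Dirichlet table alpha=1 collapsed over X1: {dirichlet_collapse(table, 0).alpha}")

rep = equivalence_mvn(n_sims=100, seed=0)
print(f"\nMVN chained vs joint over {rep.n_sims} replicates:")
print(f"  moment z-scores: { {k: round(v, 2) for k, v in rep.z_mean.items()} }")
print(f"  order-effect significance rates: { {k: v for k, v in rep.sig_rate.items()} }")
print("  (z within +-4 and rates near 0.05: the two samplers agree)")

rep2 = equivalence_multinomial(n_sims=200, seed=0)
print(f"\n2x2 multinomial chained vs joint over {rep2.n_sims} replicates:")
print(f"  imputed-frequency z-scores: { {k: round(v, 2) for k, v in rep2.z_mean.items()} }")
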