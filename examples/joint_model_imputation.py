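"""Joint-model imputation by data augmentation, the study's gold standard.

Alternates draws of the missing cells given theta = (gamma, mu0, mu1, Sigma)
and of theta given the completed data, under the prior
gamma^(tau-1) (1-gamma)^(nu-1) |Sigma|^(-kappa) with tau = nu = 1/2,
kappa = 3/2. The analysis model (OLS of W2 on W1 and Y) is fitted to each
imputed dataset and the Y coefficients are averaged.
"""

from micejm import (
    DAConfig,
    GLOMPrior,
    SimConfig,
    apply_mcar_mask,
    pool_estimates,
    run_data_augmentation,
    simulate_complete,
)

masked = apply_mcar_mask(simulate_complete(SimConfig(n=100, beta=3.0, seed=44)), 50)

completed = run_data_augmentation(
    masked,
    prior=GLOMPrior(tau=0.5, nu=0.5, kappa=1.5),
    cfg=DAConfig(m_imputations=100, burn_in=100, thin=100, seed=1),
)
pooled = pool_estimates(completed)
print(f"{len(completed)} imputed datasets from a {100 + 100 * 100}-iteration chain")
print(f"pooled Y coefficient: {pooled:.3f} (true beta = 3; the prior shrinks the")
print("estimate slightly toward the null at n = 100)")
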