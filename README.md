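# micejm

Chained-equations (MICE / fully conditional specification) and
joint-model multiple imputation for mixed binary/continuous data, with
diagnostics for **order effects** — systematic dependence of the imputed
values on the sequence in which variables are updated.

## The problem

Chained equations imputes each incomplete variable X_j from its own
conditional regression p(x_j | x_-j, ψ_j): draw ψ_j from
p(ψ_j) p(x_j^obs | x_-j, ψ_j), then redraw the missing x_j. Joint
modelling instead draws the missing data from the posterior predictive
of one parametric joint model, via Tanner–Wong data augmentation. The
two coincide — chained equations is then a genuine Gibbs sampler — when
the conditionals are compatible with the joint model **and** the prior
for each (ψ_j, ψ̃_j) factorizes into independent pieces for the
conditional parameter ψ_j and the margin parameter ψ̃_j (the
*non-informative margins* condition).

The condition holds for the multivariate normal with prior
p(μ, Σ) ∝ |Σ|^(−κ) (because |Σ| = ω_j·|Σ̃_j|) and for the saturated
multinomial with a Dirichlet prior. It fails for the **general location
model** (GLOM)

    Y ~ Bernoulli(γ),   W | Y ~ N(μ0 + μ1·Y, Σ),

even though the conditionals (a logistic regression for Y, normal
linear regressions for the W's) are perfectly compatible: the W-margin
is a two-component normal mixture whose parameter determines ψ_Y. The
consequence is measurable order effects. This package implements both
samplers, the diagnostic, and a simulation study that quantifies the
effect, for biostatisticians studying imputation methodology and for
anyone who wants a transparent, testable MICE engine for the
three-variable GLOM setting.

## What's in the box

| module | contents |
| --- | --- |
| `micejm.glom_sim` | simulate the study's GLOM datasets, apply the MCAR mask |
| `micejm.joint_da` | GLOM data augmentation: complete-data posterior draws, posterior-predictive fills, pooling |
| `micejm.conditional_models` | per-variable CE1/CE2 updates: Bayesian normal-linear, logistic with N(ψ̂, V̂) draws, linear-discriminant (GLOM) fit; proper and improper modes |
| `micejm.mice_engine` | the chained-equations sampler with configurable visit order and per-update hooks |
| `micejm.order_effect` | analysis-model refits, batch-means Monte Carlo standard errors, order-effect tests |
| `micejm.nim_checks` | executable non-informative-margins checks: Schur determinant identity, Dirichlet collapsing, Monte Carlo equivalence of chained vs joint imputation |
| `micejm.study` | the full multi-arm simulation study (complete-case, joint model, CE with logistic or LDA conditional) |

A thin CLI (`micejm simulate|impute-jm|impute-ce|diagnose|check-nim|study`)
wraps the same functions; `examples/` contains one narrative script per
capability.

## Worked example

Impute one study dataset (n = 100, β = 3, Y and W1 missing for rows
1–50) with the augmented chained-equations sampler and test for an
order effect (`examples/chained_equations_order_effect.py`):

```text
beta_bar_b (after Y update):  3.0843
beta_bar_c (after W1 update): 3.0926
difference: -0.0083  batch-means MCSE: 0.0016
95% CI: [-0.0116, -0.0051]
significant order effect in this dataset (direction and size are dataset dependent)
```

Both β̄_b and β̄_c estimate β well, but they differ by more than their
Monte Carlo error can explain: the value the analysis model sees
depends on whether it is fitted just after the Y update or just after
the W1 update, so this chain is not drawing from any single joint
model. Joint-model imputation of the same dataset
(`examples/joint_model_imputation.py`) has no such asymmetry by
construction and pools to 2.699 — slightly below β = 3 because the
|Σ|^(−κ) prior shrinks the fit at n = 100; the shrinkage vanishes at
n = 1000 or with improper (maximum-likelihood) imputation, both of
which are exercised in the tests.

`examples/noninformative_margins_checks.py` shows the flip side: for a
trivariate *normal* (condition satisfied) chained and joint imputations
agree in moments and distribution, and the order-effect significance
rate sits at the nominal 5%.

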