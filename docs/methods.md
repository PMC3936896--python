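# Methods

## Problem

Multiple imputation of multivariate, nonmonotone missing data comes in
two flavours. *Joint modelling* posits a parametric joint model
p(x | θ) with prior p(θ) and draws the missing cells from the posterior
predictive p(x_mis | x_obs), in practice by Tanner–Wong data
augmentation (alternate draws of x_mis | x_obs, θ and θ | completed
data). *Chained equations* (fully conditional specification, MICE)
instead specifies one univariate regression per incomplete variable and
cycles: for each incomplete X_j, draw the model parameter ψ_j from
p(ψ_j) p(x_j^obs | x_-j, ψ_j) (step CE1), then redraw the missing x_j
from the fitted predictive distribution (step CE2).

When are the two the same sampler? Write ψ_j for the parameter of the
conditional of X_j given the rest and ψ̃_j for the parameter of the
marginal of X_-j, both functions of θ. If, for every incomplete j, the
prior factorizes as p(ψ_j, ψ̃_j) = p(ψ_j) p(ψ̃_j) — the
**non-informative margins condition** — and the conditionals are
compatible with the joint model, the chained-equations algorithm is an
ordinary Gibbs sampler for that joint model: at convergence it draws
x_mis from the same predictive distribution, and the result cannot
depend on the order in which variables are visited. When the condition
fails, the margin of X_-j carries information about ψ_j that the joint
sampler uses and the chained sampler discards, and the two can differ.
The observable symptom is an **order effect**: the distribution of the
final imputations depends on the visit order.

This package makes both samplers, the condition, and the symptom
executable and measurable.

## The study design

All GLOM (general location model) simulations use one binary and two
continuous variables:

    Y ~ Bernoulli(γ),   W1 | Y ~ N(μ_w1 + βY, σ²_1),
    W2 | W1, Y ~ N(a + b·W1 + βY, σ²_2),

with defaults γ = 3/10, μ_w1 = 10, σ²_1 = 9, a = 9+8/9, b = 1/9,
σ²_2 = 8+8/9, n = 100 rows, and β ∈ {1, 3}. Equivalently
W | Y ~ N(μ0 + μ1 Y, Σ) with

    μ0 = (10, 9+8/9 + 10/9),  μ1 = (β, β(1 + 1/9)),
    Σ = [[9, 1], [1, 8+8/9 + 1/9]] = [[9, 1], [1, 9]].

Y and W1 are deleted for the first 50 rows (MCAR by construction, so
any downstream discrepancy is attributable to the samplers, not the
missingness mechanism). The analysis model is OLS of W2 on (W1, Y); the
quantity of interest is the Y coefficient (true value β). These
defaults are fixed: the synthetic-data generator *is* the study
condition, not a tuning knob.

## Samplers

**Joint model (gold standard).** Prior
p(θ) = γ^(τ−1)(1−γ)^(ν−1)|Σ|^(−κ), defaults τ = ν = 1/2, κ = 3/2.
Complete-data posterior: γ ~ Beta(τ+n₁, ν+n−n₁) independent of the
normal block; writing the W-part as a multivariate regression on
X = [1, Y] (p = 2 columns, q = 2 responses) with coefficient matrix
B = [μ0; μ1],

    Σ | data ~ InvWishart(df = n − p + 2κ − q − 1, scale = S),
    B | Σ    ~ MatrixNormal(B̂_OLS, (XᵀX)⁻¹, Σ),

with S the residual cross-product at the OLS fit. The degrees of
freedom come from matching exponents of |Σ| after integrating B out of
|Σ|^(−κ) × likelihood; a brute-force random-walk Metropolis sampler of
the written density validates the draw in the test suite. Missing cells
are drawn per row: a missing Y from pr(Y = 1 | observed W components, θ)
via Bayes' rule on the class-conditional normal densities, then missing
W components from the conditional normal given Y and the observed W.
The DA schedule retains one completed dataset every `thin` iterations
after `burn_in`, the first one sitting one thinning gap after burn-in
(`burn_in + m·thin` iterations in total); defaults 100/100/100. The
chain is started by filling each missing cell with a uniform draw from
its column's observed values — the same initialization the chained
sampler uses — since the start point of a converged chain is arbitrary.

**Chained equations.** Two conditionals, visited Y-then-W1 by default
(configurable, which is the whole point of the order-effect diagnostic):

* Y | W1, W2 — logistic regression fitted by Newton–Raphson on the rows
  with Y observed; proper mode draws ψ_Y from the multivariate normal
  approximation N(ψ̂, V̂) with V̂ the inverse observed information at the
  MLE (for the canonical logit link this equals the expected
  information). The LDA variant instead fits the full GLOM to the
  observed-Y rows under the same prior as the joint sampler and imputes
  from the implied class posterior pr(Y=1 | W) — it thus *does* use the
  W-margin information on those rows, which is why its order effects are
  smaller.
* W1 | Y, W2 — Bayesian normal linear regression under
  p(coefficients, ω) ∝ ω^(−κ). Integrating the p coefficients out
  leaves ω ~ ScaledInvχ²(df = n_obs − p + 2κ − 2, scale RSS/df) — i.e.
  df = n_obs − p + 1 at κ = 3/2 — then coefficients ~ N(b̂, ω(XᵀX)⁻¹);
  validated against the same Metropolis oracle. Improper mode plugs in
  the OLS fit and the residual-variance MLE.

Compatibility holds here (both conditionals derive from the GLOM), but
ψ̃_Y — the parameter of the W-margin, a two-component normal mixture —
cannot be parameterized more parsimoniously than θ itself, so ψ_Y and
ψ̃_Y are not distinct and the non-informative margins condition fails
for the Y update. Order effects are therefore possible, and the study
measures them.

**Separation.** With only 50 observed-Y rows the logistic fit can
separate. The engine detects nonconvergence within 100 Newton steps or
any |coefficient| > 15 and refits with a ridge penalty of 1e-4 on the
log-likelihood, recording the event in the draw's metadata. The chain
must not abort mid-study; the fallback is deliberately weak so it only
regularizes genuinely degenerate fits. (A warm start from the previous
iteration's MLE speeds the refits; a failed warm start is retried cold
before the separation fallback is engaged, so the fallback never
triggers on a bad start alone.)

## Order-effect diagnostic

Within each chain iteration the analysis model is refitted immediately
after the Y update (β̂_b) and after the W1 update (β̂_c). Over the
retained iterations (default 10010 total, first 10 discarded as
burn-in) the means β̄_b, β̄_c and the per-iteration difference series
d_t = β̂_b,t − β̂_c,t are formed. Because d_t is serially correlated
MCMC output, the Monte Carlo standard error of its mean uses the
batch-means estimator: split into B consecutive equal batches,
MCSE = sd(batch means)/√B. B defaults to 100 when 100 divides the
series length 10000 (the study setting); the general default is the
largest divisor of the length not exceeding ⌊√length⌋. The 95% interval
is mean(d) ± 1.96·MCSE; a dataset shows a *significant order effect*
when the interval excludes zero. The batch-means estimator is applied
to the difference series, not to each series separately, since the
difference is the reported quantity.

Across replicate datasets the study reports the means of β̄_b, β̄_c and
|β̄_b − β̄_c| with across-dataset intervals mean ± 1.96·sd/√D, plus the
count of significant datasets. Note the two interval types are
different objects: per-dataset intervals use the batch-means MCSE of
one chain; across-dataset intervals use the spread over replicates.

## Non-informative-margins checks

`nim_checks` turns the two positive cases into code:

* **Multivariate normal.** For X ~ N(μ, Σ), partitioning around
  coordinate j gives the regression form X_j | X_-j ~
  N(α_j + β_jᵀX_-j, ω_j) with β_jᵀ = ς_jᵀΣ̃_j⁻¹, α_j = μ_j − β_jᵀμ̃_j,
  ω_j = σ_j − ς_jᵀΣ̃_j⁻¹ς_j. The Schur determinant identity
  |Σ| = ω_j·|Σ̃_j| (checked numerically to < 1e-10 on random SPD
  matrices) factorizes the prior |Σ|^(−κ) into ω_j^(−κ) ×
  |Σ̃_j|^(−(κ−1)): independent priors, condition satisfied. The
  `equivalence_mvn` driver imputes the same masked trivariate-normal
  datasets by chained equations (normal-linear conditionals, prior
  ω^(−κ)) and by joint MVN data augmentation (prior |Σ|^(−κ)), and
  compares imputed-cell moments (paired z across replicates), pooled
  distributions (two-sample energy distance with a permutation test at
  the 1% level), and the order-effect significance rate under both
  visit orders, which should sit at the nominal 5%.
* **Saturated multinomial.** Collapsing a Dirichlet hyperparameter
  table over variable j yields the margin's Dirichlet prior,
  independent of the conditional blocks; `equivalence_multinomial`
  runs conjugate-Dirichlet chained equations against joint
  Dirichlet-multinomial data augmentation on a 2×2 table.

The negative case — the GLOM — is exercised by the study itself: the
significance rate rises far above 5% and the mean |β̄_b − β̄_c| grows
with β and is larger for the LR conditional than the LDA one.

## Numerical and design choices

* Binary variables are stored as 0/1 floats with a type tag, so all
  conditionals share one matrix representation.
* Masked cells are NaN in the exposed matrix; the pre-masking truth is
  retained only behind `Dataset.hidden_truth()` for validation, so no
  sampler can touch it. Observed cells are write-protected by an
  end-of-run assertion in the engine.
* Replication streams: dataset i uses `SeedSequence(base_seed + i)`
  with a per-β spawn key; each arm draws from a fixed child substream,
  so all arms see identical datasets and per-arm results are invariant
  to which other arms run.
* Hot-loop fits (the chain refits ~10⁴ logistic and linear regressions
  per dataset) use a hand-written Newton solver and normal-equation
  OLS plus closed-form 1×1/2×2 inverses/Cholesky factors and a
  Bartlett-decomposition inverse-Wishart draw; statsmodels and
  scipy.stats serve as independent oracles for all of them in the test
  suite rather than as the in-loop implementation.
* Exact zero residuals (noiseless data) are detected by a relative
  threshold (RSS ≤ 1e-12·‖y‖²) and raise, since the ω-posterior is then
  degenerate.

## Problem sizes in the shipped checks

The full published design (500 replicate datasets) takes hours on one
core. The shipped acceptance tests keep every *within-dataset* setting
at full scale — 10010 chained-equations iterations, joint-model
schedule 100/100/100, n = 100 with 50 rows masked — because the
order-effect magnitudes and significance rates depend directly on the
retained-chain length, and reduce only the number of replicate datasets
to 40. Because all arms run on identical datasets, comparisons of the
imputation arms against the published table are *anchored*: the
per-dataset difference between the arm's estimate and the complete-case
estimate is averaged and compared with the published arm-minus-CCA
difference, which cancels the shared dataset-level sampling noise (at
40 replicates the absolute means can sit a few tenths from their
expectations while the paired differences resolve the ~0.1-sized prior
shrinkage). The complete-case means, order-effect magnitudes and
significance rates are compared directly by overlapping 95% CIs, which
widen honestly with fewer replicates.
The desk-scale order-effect study uses 100 datasets at 1010 iterations,
and `scripts/acceptance.py` reruns the complete-case arm at the full
500 datasets. Monte Carlo oracle comparisons use 3×10⁴ direct draws
against 3–4×10⁵ Metropolis steps on n = 20–30 toy data, with 4-standard-
error bands combining both chains' uncertainties.

## What the generator does and does not emulate

The generator reproduces the study conditions exactly: i.i.d. rows from
a three-variable GLOM, a single MCAR block pattern, and two effect
sizes. It does not emulate features of real medical data — MAR/MNAR
mechanisms, more than one categorical variable, nonlinearities,
interactions, semicontinuous variables, or general missingness
patterns. Passing tests therefore demonstrate correctness of the
samplers and diagnostics under the stated model, and the existence and
direction of order effects in this setting; they do not bound order
effects for arbitrary real datasets (the chained-equations machinery
itself accepts arbitrary nonmonotone patterns, and the joint sampler
handles any GLOM missingness pattern, but only the study pattern is
exercised quantitatively).

## Known limitations

* Only one binary variable is supported by the GLOM samplers (the
  general K-category location model with log-linear restrictions is out
  of scope).
* Rubin's-rules variance estimation is not implemented; the study pools
  point estimates only, as the design requires.
* The multinomial equivalence driver covers two categorical variables;
  the unsaturated (log-linear) case has no executable procedure and is
  excluded.
* Batch-means is the only MCSE estimator (no spectral or overlapping
  batches); the batch count for lengths other than 10⁴ is a heuristic
  default and exposed as a parameter.
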