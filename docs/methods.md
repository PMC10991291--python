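# Methods

## Setting and assumptions

`fedsurv` models a star-topology federation: K institutions each hold a
right-censored survival table (time in days from treatment start, death
indicator, p continuous features) that never leaves the institution. The
aggregator is an ordinary orchestrator with no privileged data view; all it
ever sees are aggregate payloads. The survival model is a Cox proportional
hazards model with shared coefficients; proportional hazards and
non-informative censoring are assumed throughout.

**Stratification by institution.** Risk sets are formed within each node
only (stratified partial likelihood, one baseline hazard per institution).
This is both a statistical choice — it absorbs inter-institution differences
in baseline prognosis — and the architectural one that makes the federation
work: risk-set sums are computable locally, so every exchanged array is
sized by the feature count p, never by the patient count n. A
shared-timeline (single-baseline) mode is deliberately not offered. The
consequence to keep in mind: federated fits here reproduce a *centralized
stratified* analysis, not a pooled-risk-set one.

**Ties.** Tied event times use the Breslow approximation, the standard
choice for coordinate-descent Cox solvers. Times measured in days make heavy
ties unlikely; the synthetic generator produces continuous times, so its
fits are also comparable against Efron-based references.

## Federated statistics

Nodes return additive sufficient statistics (n, Σx, Σxx', Σy, Σy², Σxy).
Pearson correlations and means/SDs computed from the merged sums equal the
pooled-data quantities *exactly* (up to floating-point reassociation), which
the test suite enforces at 1e-10 over random partitions into 1–10 nodes.
Variances use the population convention (divisor n) so the formulas stay
exactly additive; correlations are invariant to that choice. Zero-variance
features get correlations of 0 and a degeneracy flag rather than an error.

The outcome column for feature–outcome correlation is configurable:
`time` (observed survival days, the default) or `event` (the 0/1 death
indicator). Neither fully respects censoring — this is a screening
heuristic, not an estimator — and the choice is logged and propagated.

## CFS

Hall's merit with absolute correlations, forward best-first search from the
empty set, open list ordered by merit, stopping after five consecutive
expansions (configurable) without improving the incumbent. Tie-breaking is
total and platform-independent: higher merit, then smaller subset, then
lexicographic. An exhaustive enumerator (guarded at p ≤ 15) is the test
oracle: the heuristic can never exceed it, and on separable constructions
(a mutually uncorrelated predictive block amid redundant noise) it must
match it exactly.

## Penalized Cox: IRLS + cyclical coordinate descent

At the current linear predictors each node computes per-subject scores
`g_i = δ_i − θ_i Σ_{j: t_j≤T_i} d_j/S0_j` and diagonal-Hessian weights
`w_i = θ_i Σ d_j/S0_j − θ_i² Σ d_j/S0_j²`, then ships the p-vector
`Σ w_i z_i x_i` (formed as `w·η + g`, so w ≈ 0 needs no division) and the
p×p weighted Gram matrix. The aggregator runs cyclic coordinate descent

    β_k ← S( (Σ_nodes B_k)/N, λ ) / ( (Σ_nodes A_k)/N )

with exact residual bookkeeping: because residual corrections are linear in
the Gram rows, updating coordinates against the Gram matrix is numerically
identical to broadcasting every single-coordinate update back to the nodes,
at one message exchange per IRLS round instead of per coordinate. At any
IRLS fixed point `Σ w_i (z_i − η_i) x_ik` telescopes to the true score
`U_k(β)`, so the converged solution satisfies the exact L1 KKT conditions of
the partial likelihood — verified in tests against a self-contained
proximal-gradient solver and a direct KKT check, both written from the
definitions.

Numerical choices: linear predictors are max-centred before exponentiation
(the partial likelihood and all derivatives are invariant); convergence
requires max |Δβ| < 1e-7 across an outer round *and* relative deviance
change < 1e-6; |β| > 50 on the standardized scale raises a
monotone-likelihood error; a Gram diagonal of zero pins that coordinate at
zero.

**Standardization.** Features are centred/scaled with *federated* pooled
means and population SDs before fitting, so the L1 penalty treats features
symmetrically and hazard ratios are per 1 SD; raw-scale coefficients
(β_k/sd_k) are also reported.

**Grid.** `λ_max = max_k |U_k(0)|/N` (the smallest penalty at which the
solution is exactly zero — the first path column is asserted to be all
zeros), K = 100 points log-spaced down to `0.01·λ_max`, warm-started.
Entry order ranks features by entry λ (|β| > 1e-8), ties by |β| at the
smallest penalty, then lexicographically; never-entering features go last,
flagged.

## Model selection

Candidate sets are entry-order prefixes of sizes 2…p. Leave-one-node-out
folds rotate the held-out institution from last-registered to first. Fold
models are *unpenalized* Cox fits on the candidate features (hazard ratios
with Wald CIs per fold are part of the report, which a LASSO fit would not
naturally provide), with standardization re-derived from the fold's training
nodes only. Validation scores the held-out node's training partition — the
20% test partition stays untouched until final evaluation. Fold C-indices
are summarised as mean ± t(0.975, nfolds−1)·sd/√nfolds; this Student-t
convention reproduces published three-fold summaries of this design to two
decimals from their fold values. Selection maximises the mean C-index, ties
preferring the smaller and then earlier set; any set with a failed fold is
excluded and logged.

Harrell's C-index follows the classical definition: pairs (i, j) with
T_i < T_j and δ_i = 1 are comparable; score ties count ½. Pairs with tied
times are not comparable (reference implementations that count
tied-time/discordant-event pairs agree with ours exactly on tie-free data).
Zero comparable pairs raise an undefined-metric error, which final
evaluation isolates per node.

## Final model, risk stratification, KM

Newton–Raphson with step halving on the pooled gradient and full p×p
Hessian; convergence at ‖U‖∞ < 1e-8; SEs from the inverse observed
information; Wald 95% CIs `exp(β ± 1.96·se)`. Risk score = exp(linear
predictor on the standardized scale). The global cutoff is the median of
per-node median risk scores, computed by default on the test partitions
(configurable to training); scores equal to the threshold go to the
high-risk group (only "below" is defined as low risk). Kaplan–Meier tables
(product-limit, steps at event times only) and the two-group log-rank test
(O−E with hypergeometric variance, χ² with 1 df) are computed per node;
log-rank p-values are reported without multiplicity adjustment.

## Privacy contract

Every node→aggregator message is an `AggregatePayload` whose arrays carry
declared dimensions checked at construction. The validator flags any
dimension ≥ the node's patient count unless it is ≤ p or equals the λ-grid
size. Kaplan–Meier tables are whitelisted: their event-time axis can
approach n, and sharing them in the clear matches the practice of central
KM plotting (an encrypted alternative is future work, out of scope here).
The full pipeline transcript is recorded and re-audited end-to-end in tests
and in the acceptance script; the audit is also exposed via
`fedsurv validate`.

## Synthetic data

Features: block-equicorrelated standard normals (`x = √ρ·u_block +
√(1−ρ)·ε`), emulating correlated radiomics families; blocks are independent.
Survival: per-node Weibull baseline with hazard multiplied by exp(x'β_true),
i.e. `T = scale·(E·e^{−η})^{1/shape}`, E ~ Exp(1) — proportional hazards by
construction, node heterogeneity through differing scales. Censoring:
min(administrative horizon, exponential) with the exponential rate bisected
to hit the target overall censoring fraction; the achieved rate must land
within ±0.05 or configuration fails loudly.

Reference study conditions (`default_config`): three nodes of 300/600/300
patients (echoing 187/420/221 cohort proportions), p = 60 in ten blocks of
six with ρ alternating 0.6/0.2, three informative features in distinct
blocks with per-SD log hazards +0.8/−0.8/+0.5, Weibull baselines whose
median survivals echo 964/549/500 days, 20% target censoring under a
five-year horizon. These sizes keep a full pipeline run under a few seconds
while leaving per-node event fractions (≈ 69/77/85%) inside the 58–93%
range reported for real multicentre lung cohorts.

What passing tests on this generator do **not** show: robustness to scanner/
protocol batch effects, non-Gaussian or heavy-tailed feature marginals,
informative censoring, missing data beyond row deletion, or violations of
proportional hazards — real radiomics federations exhibit all of these.

## Design choices where the design was open

- Per-IRLS-round Gram-matrix exchange instead of per-coordinate broadcast:
  identical numerics (see above), far fewer messages, payloads still
  p-sized.
- Split rule: test size = round(fraction·n) half-away-from-zero, clamped so
  both sides keep ≥ 1 patient; splits are deterministic from (seed,
  fraction, n) via PCG64.
- Missing data: row-wise deletion at load with a logged count.
- CV validation slice: the held-out node's training partition (keeps the
  final test sets unseen by any selection step).
- Threshold medians from test-set scores by default; training-set medians
  behind a flag.
- Node failures abort the round (fail-fast), naming the failing node; an
  event-free node contributes zero likelihood rather than aborting a fit.

## Limitations

No Efron ties, no elastic-net mixing, no baseline-hazard export, no
calibration, no proportional-hazards diagnostics (e.g. Schoenfeld
residuals), no harmonization of site effects beyond stratification, and no
real networking — the federation is in-process, though payloads are
serializable so a transport could be added without touching the algorithms.
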