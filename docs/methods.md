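# Methods

This note documents the models, estimators, defaults, and numerical choices
behind `expomed`, and what the synthetic-data experiments do and do not
establish.

## Structural model and estimands

All analyses assume the linear structural equation system, per exposure A
(log analyte or standardized risk score), mediator M (log biomarker or a
derived score), covariate vector C (intercept + dummy-coded covariates),
and continuous outcome Y (gestational age at delivery, weeks):

    M_i = alpha_a A_i + alpha_c' C_i + eps_i
    Y_i = beta_a A_i + beta_m M_i + beta_c' C_i + delta_i

Under sequential ignorability (no unmeasured confounding of the A→Y, M→Y,
and A→M relations, no exposure-induced mediator-outcome confounders, and
temporal ordering A before M before Y), the natural indirect effect is the
product alpha_a·beta_m, the natural direct effect is beta_a, and the total
effect decomposes as TE = NDE + NIE. These assumptions are maintained, not
tested; the sensitivity module quantifies how wrong they can be before the
conclusions flip. For binary outcomes (preterm, spontaneous preterm) the
outcome model is a weighted logit and the same product construction is
applied on the log-odds scale; the case fraction in the analytic subset is
~32%, well outside the rare-outcome regime in which log-odds products
approximate risk-scale effects, so every binary-outcome result carries a
`log_odds_scale_nonrare_outcome` flag. The binary-outcome TE is taken from
the outcome model that omits the mediator (difference of nested models);
for continuous outcomes product and difference methods coincide exactly and
both identities are enforced in the test suite (1e-10 and 1e-8).

## Nested case-control weighting

The analytic subset oversamples cases. Subjects are weighted by the inverse
of their stratum selection probability (cases: n_cases_sampled /
n_cohort_cases; controls analogously), and all regressions are weighted by
these IPW weights with HC0 sandwich standard errors — the design-robust
variance a survey-weighted engine reports by default. Weights are treated
as fixed design constants: the bootstrap resamples subjects but never
re-estimates weights. Simple IPW only; no finite-population or
stratified-design corrections.

## Synthetic cohort generator

The generator emulates the target study's data structure, not any
particular dataset:

- **Exposures**: log-scale Gaussians with exchangeable within-class
  correlation (one-factor construction), exponentiated so raw values are
  positive and log-transformation downstream recovers Gaussianity. Default
  classes phthalate/phenol/PAH/metal of sizes 9/9/8/12; default
  within-class rho 0.6 (observed within-class correlations in such panels
  run from moderate up to ~0.97).
- **Mediators**: log-scale linear in the log exposures plus covariate
  effects plus within-group-correlated Gaussian noise (default rho 0.3);
  seven groups of sizes 14/18/14/5/5/2/3.
- **Covariates** (6): standardized age, specific gravity ~ N(1.015, 0.005),
  3-level BMI category, 4-level education, private insurance and tobacco
  use indicators — dummy-coded with first-level reference downstream.
  Unobserved levels in a subsample are dropped from the design.
- **Outcome**: intercept 39.0 weeks, linear direct + mediated effects,
  Gaussian noise sd 1.2; preterm = Y < 37.
- **Default effects**: three phthalates → four cytochrome-p450 mediators
  with alpha = 0.25 and beta_m = −0.15, direct effects −0.1. These defaults
  were calibrated once so the full cohort shows an outcome SD ≈ 1.4 weeks,
  preterm prevalence ≈ 8% (≈130 cases in a 1600-subject cohort), and an
  outcome-model R² ≈ 0.3 — a realistic epidemiologic signal.
- **Sampling**: 52 cases and 109 controls drawn by case status with
  recorded selection probabilities (the full-cohort case count behind the
  real weights is not published; it is a free parameter here).

Ground truth is defined on the log-standardized scale, where the log
exposures have unit variance by construction: true NIE(l, j) =
alpha[l, j]·beta_m[l]; the pair-level true NDE is the total effect minus
that pair's NIE, so TE = NDE + NIE holds in truth by construction. With
correlated co-exposures the one-at-a-time regression estimand differs from
these structural values (co-exposure confounding — the reason the framework
moves to risk scores); recovery tests therefore use single-pathway
configurations with independent exposures.

What the generator does **not** emulate: assay detection limits, batch
effects, missingness, non-Gaussian tails, nonlinear dose-response, or
exposure-mediator interactions. Passing tests show the estimators recover
the linear model they assume — not that the linear model holds in real
cohorts.

## Environmental risk scores

Per class, the adaptive elastic net minimizes

    (1/n) Σ (y_i − gamma_c'C_i − gamma_k'A_ik)² + lambda1 Σ w_j|gamma_kj|
        + (lambda2/2) Σ gamma_kj²

with covariates unpenalized (profiled out exactly via Frisch–Waugh
residualization) and adaptive weights w_j = (|gamma_init,j| + 1/n)^(−1)
from a ridge-heavy initial fit (lambda1 = 0, lambda2 CV-chosen over
{0.01, 0.1, 1, 10}); the +1/n stabilizer keeps weights finite when the
initial coefficient is zero. The solver is covariance-update coordinate
descent (update gamma_j = S((2/n)x_j'r, lambda1·w_j)/((2/n)x_j'x_j +
lambda2)), verified against the KKT system to 1e-6 at every returned
solution. (lambda1, lambda2) are chosen jointly on a grid — 50 log-spaced
lambda1 values spanning four decades below the data-derived maximum, and
lambda2 ∈ {0, 0.01, 0.1, 1, 10} — by seeded k-fold CV whose fold assignment
is a pure function of (seed, n, folds). A class with no outcome signal
legitimately shrinks to all zeros; it returns a flagged degenerate model
(constant score) that downstream stages exclude.

The stored score is gamma_k'A_ik standardized and *oriented* so that a
higher score associates with a shorter gestation (risk-score convention);
the orientation sign is stored with the model, and the fitted gamma is left
untouched (flipping it would leave the penalized optimum). The same outcome
is used for weight estimation and downstream mediation — no sample
splitting, matching the intended workflow; the resulting optimism is a
documented caveat, not corrected.

## Bayesian shrinkage mediation

The Gibbs sampler fits the joint outcome model and the q_g mediator
equations with two-component normal mixtures on each (alpha_a)_l and
(beta_m)_l: component membership ~ Bernoulli(0.5), inverse-gamma(2, 1)
hyperpriors on the spike and slab variances, slab ≥ 100× spike enforced by
rejection (with a deterministic clip after 100 failed draws), N(0, 100)
priors on unshrunk coefficients, and inverse-gamma(2, 1) priors on both
residual variances (one shared across mediator equations). The PIP of
mediator l is the posterior mean of [both its indicators in the slab].
Updates are fully conjugate: one joint multivariate-normal draw for the
outcome coefficients per iteration (single Cholesky of the posterior
precision), a shared-precision vectorized draw for the mediator-model
covariate coefficients, and vectorized scalar draws for the alpha_a. IPW
weights exponentiate likelihood contributions (weighted likelihood) — an
approximation documented as such, since the underlying shrinkage model is
unweighted. Outcomes are restricted to the continuous scale.

Library defaults are 30,000 iterations / 15,000 burn-in. The bundled
analysis scripts and calibration suites use shorter chains (4,000/1,500 and
800/300 respectively) — at q ≤ 61 and n ≤ 1000 these pass the split-chain
R-hat diagnostic (reported per parameter block) and reproduce the long-chain
PIP rankings; chain length is a per-call argument. Both global-effect
summaries are computed per draw: the conventional global NIE
Σ (alpha_a)_l(beta_m)_l, and the sum of squared products Σ{(alpha_a)_l
(beta_m)_l}² — the two published forms of the pathway-global effect differ
on this point, so neither is silently preferred.

## Directions of mediation

For mediator group g, the first direction of mediation w_g (‖w‖₂ = 1)
maximizes the Gaussian profile log-likelihood of the two-equation system
with M_g·w as the mediator. After residualizing on [A, C] (weighted), both
residual sums of squares are closed forms in w:

    RSS1(w) = w'Sw,   RSS2(w) = c − (b'w)² / (w'Sw)
    obj(w)  = −(n/2)[log RSS1 + log RSS2]

with S = M'RM, b = M'Ry, c = y'Ry precomputed, so the unit-sphere
optimization (projected gradient ascent with backtracking, tolerance 1e-8
on relative objective change, 20 seeded random restarts plus the first-PC
start) costs O(q²) per step. Sign convention: the largest-|loading| entry
is made positive. Mediators are standardized first, which keeps the
−log RSS1 term from chasing artificial low-variance directions. A direction
whose MGE explains less than 1e-4 of the outcome's residual variance is
returned with a typed `sparse_signal` status rather than an exception —
the analogue of group effects the decomposition cannot estimate. Only the
first direction per group is extracted; groups with fewer than five
biomarkers are excluded from by-group runs but retained in the all-mediator
run. The MGE is standardized before being mediated.

The sparse-PC alternative uses L1-penalized power iteration (soft-threshold
the loading update, renormalize) with projection deflation; penalty 0
reproduces ordinary PCA loadings to 1e-8, and components accumulate until
the cumulative explained-variance fraction reaches the target (default 0.8).

## Penalized pathway selection

**Pathway lasso.** The joint objective over the two equations plus
lambda Σ(|alpha_j beta_j| + phi(alpha_j² + beta_j²)) + omega Σ(|alpha_j| +
|beta_j|) with phi = 2 (the pair penalty is convex for phi ≥ 1/2) and
omega = 0.1·lambda. Covariates are profiled out exactly; the solver is
proximal gradient with backtracking line search (monotone objective) and
the *exact* prox of each (alpha_j, beta_j) pair, computed by enumerating
the four sign quadrants (2×2 linear stationarity systems), the two axes,
and the origin. The path (30 log-spaced lambdas, warm-started) is tuned by
5-fold CV on the combined held-out residual loss with the one-standard-error
rule. Because the convexified penalty leaves small nonzero remnants,
"selected" means the pathway product exceeds 5% of the largest product
magnitude (with a 1e-8 absolute floor) — at the chosen lambda the true and
remnant products separate by two orders of magnitude in simulation. No
debiased inference is attempted for the penalized estimates.

**MCP + joint significance.** Stage 1: sure-independence screening keeps
the top d = ceil(2n / log n) mediators by covariate-adjusted marginal
outcome association. Stage 2: MCP-penalized outcome regression over the
survivors (coordinate descent with the exact scalar MCP threshold on
unit-mean-square columns, gamma = 3, 30-lambda path, BIC tuning); exposure
and covariates unpenalized. Stage 3: for mediators with nonzero MCP
estimates, p_alpha from the mediator model and p_beta from an unpenalized
refit of the outcome model on the selected set; p_joint = max, adjusted by
BH and Bonferroni (both reported). The refit p-values carry no
post-selection correction — the same caveat as the source procedure.

## Sensitivity analyses

- **NIE(rho)**: for the linear SEM, NIE(rho) = (alpha·s1/s2)[rho~ −
  rho·sqrt((1 − rho~²)/(1 − rho²))], where s1, s2 are the weighted residual
  SDs of the reduced outcome (Y on A, C) and mediator models and rho~ their
  residual correlation. At rho = 0 this equals the product estimate exactly
  (Frisch–Waugh); the curve crosses zero at rho = rho~, found by bisection
  on the default grid (−0.9 to 0.9, step 0.01). The threshold is also
  reported as the product of variance fractions unmeasured confounders
  would need to explain in the two equations, rho_zero²(1 − R²_M)(1 − R²_Y)
  on the original-variance scale. Exact — no simulation noise.
- **E-value**: RR ≈ exp(0.91·beta) for a standardized continuous outcome
  (the 0.91 constant is the standard approximation and configurable);
  E = RR + sqrt(RR(RR − 1)) with the reciprocal transform for protective
  effects; the CI bound uses the confidence limit closer to the null and
  collapses to 1 when the interval crosses it.
- **Covariate scan**: the mediation model refit under all 2^r − 1 non-empty
  subsets of the conceptual covariates (each categorical enters as its full
  dummy block; 63 subsets for six covariates), reporting the NIE range and
  sign-stability fraction; rank-deficient subsets yield flagged rows.

## Problem sizes in the bundled experiments

The acceptance suite and `scripts/acceptance.py` run: the full 2,318-model
screen at n = 161; 500 single-pathway recovery replicates at n = 1000;
50 + 50 Bayesian calibration chains at n = 500, q = 20 (800 iterations /
300 burn-in); 50 direction-recovery replicates at n = 1000, q = 10; and 200
global-null joint-significance replicates at n = 500, q = 61. The module
test suite runs scaled-down counterparts of the same designs. These sizes
are the package's chosen desk-scale defaults; every replicate count and
chain length is an explicit argument.

## Known limitations

- Additive models only: no exposure-mediator interactions, no nonlinear
  dose-response.
- Binary-outcome mediation is on the log-odds scale with a non-rare
  outcome; estimates are flagged, not corrected.
- The weighted-likelihood treatment of IPW in the Bayesian sampler is an
  approximation without design-based uncertainty.
- ERS inference is optimistic (no sample splitting), and pathway-lasso /
  MCP selections carry no post-selection inference guarantees.
- The profile-likelihood direction of mediation recovers a single dominant
  direction; diffuse multi-directional mediation within a group is
  summarized, not resolved.
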