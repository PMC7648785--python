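# expomed

Multivariate mediation analysis for environmental exposure mixtures.

## The problem

Prenatal exposure to chemical mixtures — phthalates, phenols, polycyclic
aromatic hydrocarbons (PAHs), and trace metals — is a suspected risk factor
for shortened gestation. The biological question is *through which pathways*:
does a toxicant act on gestational age directly, or via endogenous signaling
biomarkers (eicosanoids from the cyclooxygenase / cytochrome p450 /
lipoxygenase pathways, parent lipids, inflammation, oxidative-stress and
protein-damage markers)? With p = 38 correlated analytes and q = 61
correlated biomarkers measured on a nested case-control sample, neither the
exposures nor the mediators can be analyzed one at a time without bias, and
the cross of both panels is 2,318 models.

`expomed` implements a complete analysis framework for this setting, driven
by a synthetic cohort generator with known ground-truth effects so every
stage is testable:

1. **Pairwise mediation screen** — for each exposure A and mediator M, fit
   the IPW-weighted models

       M = alpha_a A + alpha_c' C + eps
       Y = beta_a A + beta_m M + beta_c' C + delta

   and decompose the natural indirect effect NIE = alpha_a x beta_m, the
   natural direct effect NDE = beta_a, and TE = NDE + NIE (continuous Y;
   a logit outcome model on the log-odds scale for preterm birth). Sobel or
   bootstrap standard errors; Storey/BH q-values across the screen.
2. **Environmental risk scores (ERS)** — per exposure class, an adaptive
   elastic net `argmin (1/n)||y - gamma_c'C - gamma_k'A_k||^2 +
   lambda1 sum w_j|gamma_j| + (lambda2/2) sum gamma_j^2` with 5-fold CV over
   the (lambda1, lambda2) grid; ERS_ik = gamma_k' A_ik reduces 38 collinear
   analytes to 4 nearly orthogonal scores (and the screen to 244 models).
3. **Multivariate mediator strategies** —
   * *Bayesian shrinkage*: a Gibbs sampler with two-component normal-mixture
     (spike/slab-style) priors on all (alpha_a)_l and (beta_m)_l jointly,
     posterior inclusion probabilities, and global mediation effects
     (sum of products, and sum of squared products);
   * *Directions of mediation*: the unit-norm loading vector w_g maximizing
     the two-equation profile likelihood, giving per-subject mediator group
     effects MGE_ig = w_g' M_ig that are mediated one at a time;
   * *Pathway lasso*: joint penalization of the pathway products
     lambda sum_j(|alpha_j beta_j| + phi(alpha_j^2 + beta_j^2)) via proximal
     gradient with an exact pair prox;
   * *MCP + joint significance*: sure-independence screening, minimax-
     concave-penalty outcome regression tuned by BIC, then
     p_joint = max(p_alpha, p_beta) with BH/Bonferroni adjustment.
4. **Sensitivity analyses** — the closed-form NIE(rho) curve under
   mediator/outcome error correlation (with the zero crossing and its
   R²-product equivalent), E-values for standardized continuous outcomes,
   and the exhaustive 2^6 − 1 = 63 covariate-subset scan.

Nested case-control sampling is handled throughout by inverse-probability
weights (weight = 1 / P(selected | case status)) with design-robust sandwich
standard errors.

## Worked example

```python
import numpy as np
from expomed import SimConfig, generate_cohort, mediate_pair

cohort, exposures, mediators, truth = generate_cohort(SimConfig(seed=11))
res = mediate_pair(
    np.log(exposures.matrix()[:, 0]),      # first phthalate, log scale
    np.log(mediators.matrix()[:, 14]),     # a cytochrome-p450 eicosanoid
    cohort,
    exposure_id="exp_phthalate_1", mediator_id="med_cyp450_1",
)
print(f"NIE = {res.nie:.3f} (SE {res.se_nie:.3f}), "
      f"TE = {res.te:.3f}, proportion mediated = {res.prop_mediated:.2f}")
```

prints

```
NIE = -0.121 (SE 0.042), TE = -0.428, proportion mediated = 0.28
```

i.e. in this draw a one-SD increase in the log-analyte is associated with a
0.43-week shorter gestation, 28% of which flows through this biomarker.
The generating truth for this pair is NIE = 0.25 × −0.15 = −0.0375 per
log-SD: at n = 161 a single-pair estimate is this noisy, which is exactly
why the framework proceeds to risk scores and multivariate mediator models.

The numbered scripts under `analysis/` run the full study pipeline on the
default synthetic cohort (simulate → 2,318-model screen → risk scores →
Bayesian shrinkage → directions of mediation → penalized selection →
sensitivity), each printing what it found and writing tables under
`results/`. The same pipeline is scriptable via the `mediate` CLI
(`mediate run-all --seed 11`).

## Caveats

The ERS weights are estimated against the same outcome later used in the
mediation models (no sample splitting), so downstream inference for the
scores is optimistic — this mirrors the intended two-stage workflow and is
flagged here rather than silently corrected. Binary-outcome NIEs are
reported on the log-odds scale; with a ~32% case fraction in the analytic
subset the rare-outcome approximation is strained, and results carry a
structured warning flag. See `docs/methods.md` for the full model account,
parameter defaults, and limitations.
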