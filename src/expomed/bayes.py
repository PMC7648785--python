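"""Bayesian multivariate mediation with spike-like continuous shrinkage.

All q_g mediator pathways are modeled jointly:

    Y_i   = beta_a A_i + beta_m' M_i + beta_c' C_i + delta_i
    M_il  = alpha_al A_i + alpha_cl' C_i + eps_il

with two-component normal mixture priors on every (alpha_a)_l and
(beta_m)_l: a small-variance (spike) and a large-variance (slab) component,
Bernoulli(1/2) membership, and inverse-gamma hyperpriors on the component
variances with the slab constrained to at least 100x the spike. The
posterior inclusion probability (PIP) of mediator l is the posterior
probability that BOTH its pathway coefficients sit in the slab.

A Gibbs sampler with fully conjugate updates does the work: the outcome
coefficients are drawn jointly from their multivariate normal conditional;
mediator-model coefficients are drawn with the alpha_a scalars vectorized
across mediators. IPW weights enter as likelihood exponents (weighted
likelihood) — an approximation, since the source shrinkage method is
unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla


@dataclass
class PriorSpec:
    """Hyperparameters; the defaults are deliberately weakly informative.

    ``fixed_*`` entries freeze a variance at a constant (no hyperprior
    update) — mainly for degenerate-limit checks such as spike = slab, where
    the mixture collapses to a single normal and the posterior mean must
    match ridge regression.
    """

    tau2: float = 100.0  # prior variance of unshrunk coefficients
    ig_shape: float = 2.0
    ig_rate: float = 1.0
    slab_spike_ratio: float = 100.0
    inclusion_prob: float = 0.5
    fixed_slab_var: float | None = None
    fixed_spike_var: float | None = None
    fixed_resid_var_outcome: float | None = None
    fixed_resid_var_mediator: float | None = None


@dataclass
class ShrinkagePosterior:
    exposure_id: str
    group: str
    mediator_names: list[str]
    draws: dict[str, np.ndarray]  # alpha_a, beta_m: (n_draws, q); beta_a: (n_draws,)
    pip: np.ndarray
    global_nie: dict
    global_effect_sq: dict
    chain_meta: dict
    rhat: dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.draws["beta_a"])


def _draw_mvn(rng, precision: np.ndarray, linear: np.ndarray) -> np.ndarray:
    """Draw from N(P^-1 b, P^-1) via one Cholesky of the precision."""
    L = sla.cholesky(precision, lower=True)
    mean = sla.cho_solve((L, True), linear)
    z = rng.standard_normal(len(linear))
    return mean + sla.solve_triangular(L, z, lower=True, trans="T")


def _ig_draw(rng, shape: float, rate: float) -> float:
    return float(rate / rng.gamma(shape, 1.0))


def _draw_variance_pair(rng, prior: PriorSpec, slab_vals, spike_vals) -> tuple[float, float]:
    """Slab/spike variance updates with the slab >= ratio * spike constraint
    enforced by rejection (deterministic clip after 100 failed tries)."""
    a, b, ratio = prior.ig_shape, prior.ig_rate, prior.slab_spike_ratio
    sh_slab = a + len(slab_vals) / 2.0
    ra_slab = b + float(np.sum(np.square(slab_vals))) / 2.0
    sh_spk = a + len(spike_vals) / 2.0
    ra_spk = b + float(np.sum(np.square(spike_vals))) / 2.0
    for _ in range(100):
        v_slab = _ig_draw(rng, sh_slab, ra_slab)
        v_spk = _ig_draw(rng, sh_spk, ra_spk)
        if v_slab >= ratio * v_spk:
            return v_slab, v_spk
    v_slab = _ig_draw(rng, sh_slab, ra_slab)
    return v_slab, v_slab / ratio


def _mixture_indicator(rng, vals: np.ndarray, v_slab: float, v_spk: float, p_incl: float) -> np.ndarray:
    log_slab = -0.5 * (np.log(2 * np.pi * v_slab) + vals**2 / v_slab) + np.log(p_incl)
    log_spk = -0.5 * (np.log(2 * np.pi * v_spk) + vals**2 / v_spk) + np.log1p(-p_incl)
    prob = 1.0 / (1.0 + np.exp(np.clip(log_spk - log_slab, -700, 700)))
    return (rng.random(len(vals)) < prob).astype(float)


def fit_bayes_mediation(
    exposure: np.ndarray,
    mediators: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray,
    weights: np.ndarray | None = None,
    prior: PriorSpec | None = None,
    iterations: int = 30_000,
    burnin: int = 15_000,
    thin: int = 1,
    seed: int = 0,
    exposure_id: str = "exposure",
    group: str = "all",
    mediator_names: list[str] | None = None,
) -> ShrinkagePosterior:
    """Run the Gibbs sampler; reproducible given the seed.

    Inputs should be standardized (the exposure, each mediator, and the
    continuous outcome); ``covariates`` should include an intercept column.
    Warns when q >= n.
    """
    import warnings

    prior = prior or PriorSpec()
    rng = np.random.default_rng(seed)
    a = np.asarray(exposure, float)
    M = np.asarray(mediators, float)
    y = np.asarray(outcome, float)
    C = np.asarray(covariates, float)
    n, q = M.shape
    r = C.shape[1]
    for arr, name in ((a, "exposure"), (M, "mediators"), (y, "outcome"), (C, "covariates")):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in {name}")
    if q >= n:
        warnings.warn(f"q = {q} >= n = {n}: posterior will lean heavily on the prior")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    names = mediator_names if mediator_names is not None else [f"m{l}" for l in range(q)]
    if burnin >= iterations:
        raise ValueError("burnin must be smaller than iterations")

    X = np.column_stack([a, M, C])  # outcome design: beta_a | beta_m | beta_c
    XtW = X.T * w
    XtWX = XtW @ X
    XtWy = XtW @ y
    CtW = C.T * w
    CtWC = CtW @ C
    aWa = float(np.sum(w * a * a))

    # state
    v_slab_b, v_spk_b = 1.0, 0.01
    v_slab_a, v_spk_a = 1.0, 0.01
    if prior.fixed_slab_var is not None:
        v_slab_b = v_slab_a = prior.fixed_slab_var
    if prior.fixed_spike_var is not None:
        v_spk_b = v_spk_a = prior.fixed_spike_var
    sig_e = prior.fixed_resid_var_outcome or 1.0
    sig_g = prior.fixed_resid_var_mediator or 1.0
    r_beta = np.ones(q)
    r_alpha = np.ones(q)
    alpha_a = np.zeros(q)
    alpha_c = np.zeros((q, r))
    theta = np.zeros(1 + q + r)

    kept = (iterations - burnin) // thin
    draws_alpha = np.empty((kept, q))
    draws_beta = np.empty((kept, q))
    draws_beta_a = np.empty(kept)
    draws_incl = np.empty((kept, q))
    k = 0

    for it in range(iterations):
        # --- outcome coefficients jointly ---
        prior_var = np.concatenate(
            [[prior.tau2], np.where(r_beta == 1.0, v_slab_b, v_spk_b), np.full(r, prior.tau2)]
        )
        P = XtWX / sig_e + np.diag(1.0 / prior_var)
        theta = _draw_mvn(rng, P, XtWy / sig_e)
        beta_m = theta[1 : 1 + q]

        # --- outcome-side indicators + variances ---
        if prior.fixed_slab_var is None:
            r_beta = _mixture_indicator(rng, beta_m, v_slab_b, v_spk_b, prior.inclusion_prob)
            v_slab_b, v_spk_b = _draw_variance_pair(
                rng, prior, beta_m[r_beta == 1.0], beta_m[r_beta == 0.0]
            )
        # --- mediator-model alpha_c (shared precision across mediators) ---
        R = M - np.outer(a, alpha_a)
        Pc = CtWC / sig_g + np.eye(r) / prior.tau2
        Lc = sla.cholesky(Pc, lower=True)
        Bc = CtW @ R / sig_g  # r x q
        mean_c = sla.cho_solve((Lc, True), Bc)
        Zc = rng.standard_normal((r, q))
        alpha_c = (mean_c + sla.solve_triangular(Lc, Zc, lower=True, trans="T")).T

        # --- alpha_a scalars, vectorized across mediators ---
        S = M - C @ alpha_c.T
        v_alpha = np.where(r_alpha == 1.0, v_slab_a, v_spk_a)
        prec = aWa / sig_g + 1.0 / v_alpha
        mean_a = ((w * a) @ S / sig_g) / prec
        alpha_a = mean_a + rng.standard_normal(q) / np.sqrt(prec)

        if prior.fixed_slab_var is None:
            r_alpha = _mixture_indicator(rng, alpha_a, v_slab_a, v_spk_a, prior.inclusion_prob)
            v_slab_a, v_spk_a = _draw_variance_pair(
                rng, prior, alpha_a[r_alpha == 1.0], alpha_a[r_alpha == 0.0]
            )

        # --- residual variances ---
        if prior.fixed_resid_var_outcome is None:
            resid_y = y - X @ theta
            sig_e = _ig_draw(
                rng, prior.ig_shape + n / 2.0, prior.ig_rate + float(np.sum(w * resid_y**2)) / 2.0
            )
        if prior.fixed_resid_var_mediator is None:
            resid_m = M - np.outer(a, alpha_a) - C @ alpha_c.T
            sig_g = _ig_draw(
                rng,
                prior.ig_shape + n * q / 2.0,
                prior.ig_rate + float(np.sum(w[:, None] * resid_m**2)) / 2.0,
            )
        if not (np.isfinite(sig_e) and np.isfinite(sig_g)) or sig_e <= 0 or sig_g <= 0:
            raise ValueError(f"divergent variance draw at iteration {it}")

        if it >= burnin and (it - burnin) % thin == 0:
            draws_alpha[k] = alpha_a
            draws_beta[k] = beta_m
            draws_beta_a[k] = theta[0]
            draws_incl[k] = r_alpha * r_beta
            k += 1

    draws = {"alpha_a": draws_alpha[:k], "beta_m": draws_beta[:k], "beta_a": draws_beta_a[:k]}
    pip = draws_incl[:k].mean(axis=0)
    products = draws["alpha_a"] * draws["beta_m"]
    g_nie = products.sum(axis=1)
    g_sq = (products**2).sum(axis=1)
    post = ShrinkagePosterior(
        exposure_id=exposure_id,
        group=group,
        mediator_names=list(names),
        draws=draws,
        pip=pip,
        global_nie=_summ(g_nie),
        global_effect_sq=_summ(g_sq),
        chain_meta={"iterations": iterations, "burnin": burnin, "thin": thin, "seed": seed},
    )
    post.rhat = {
        "beta_a": _split_rhat(draws["beta_a"]),
        "alpha_a_max": float(np.max([_split_rhat(draws["alpha_a"][:, l]) for l in range(q)])),
        "beta_m_max": float(np.max([_split_rhat(draws["beta_m"][:, l]) for l in range(q)])),
    }
    return post


def _summ(x: np.ndarray) -> dict:
    lo, hi = np.percentile(x, [2.5, 97.5])
    return {"mean": float(np.mean(x)), "ci_low": float(lo), "ci_high": float(hi)}


def _split_rhat(chain: np.ndarray) -> float:
    """Split-chain potential scale reduction (two half-chains)."""
    m = len(chain) // 2
    if m < 2:
        return float("nan")
    halves = np.stack([chain[:m], chain[m : 2 * m]])
    within = halves.var(axis=1, ddof=1).mean()
    between = m * halves.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0
    var_plus = (m - 1) / m * within + between / m
    return float(np.sqrt(var_plus / within))


def global_mediation_effect(post: ShrinkagePosterior, form: str = "sum_products") -> dict:
    """Posterior mean + 95% credible interval of the global mediation effect.

    ``sum_products`` is the conventional global NIE, sum_l alpha_l beta_l;
    ``sum_sq_products`` sums the squared per-pathway products instead. Both
    are computed per-draw and then summarized.
    """
    products = post.draws["alpha_a"] * post.draws["beta_m"]
    if form == "sum_products":
        return _summ(products.sum(axis=1))
    if form == "sum_sq_products":
        return _summ((products**2).sum(axis=1))
    raise ValueError(f"unknown form {form!r}")


def run_shrinkage_over_exposures(
    exposure_panel: pd.DataFrame,
    mediators,
    cohort,
    grouping: str = "by_group",
    min_group_size: int = 5,
    prior: PriorSpec | None = None,
    iterations: int = 30_000,
    burnin: int = 15_000,
    seed: int = 0,
    use_weights: bool = True,
) -> tuple[pd.DataFrame, list[ShrinkagePosterior]]:
    """One posterior per (exposure, mediator-group) combination.

    ``exposure_panel`` holds standardized exposure columns (individual log-z
    analytes or ERS). Under ``grouping='by_group'`` mediator groups with
    fewer than ``min_group_size`` members are excluded; ``grouping='all'``
    fits a single joint model over all q mediators per exposure.
    Per-combination failures are flagged rows; the run continues.
    """
    med_z = mediators.log_z()
    y = cohort.outcome("continuous")
    y_std = (y - y.mean()) / y.std(ddof=0)
    covs, _ = cohort.covariate_design()
    w = cohort.ipw_weight if use_weights else None

    if grouping == "all":
        blocks = [("all", med_z.columns)]
    elif grouping == "by_group":
        blocks = [
            (g, med_z.columns_of(g))
            for g in med_z.groups()
            if len(med_z.columns_of(g)) >= min_group_size
        ]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    rows, posteriors = [], []
    for i, exp_name in enumerate(exposure_panel.columns):
        a = exposure_panel[exp_name].to_numpy(float)
        a_std = (a - a.mean()) / a.std(ddof=0)
        for g, cols in blocks:
            try:
                post = fit_bayes_mediation(
                    a_std,
                    med_z.values[cols].to_numpy(float),
                    y_std,
                    covs,
                    weights=w,
                    prior=prior,
                    iterations=iterations,
                    burnin=burnin,
                    seed=seed + 7919 * i,
                    exposure_id=exp_name,
                    group=g,
                    mediator_names=cols,
                )
                posteriors.append(post)
                rows.append(
                    {
                        "exposure": exp_name,
                        "group": g,
                        "q_g": len(cols),
                        "max_pip": float(post.pip.max()),
                        "top_mediator": cols[int(post.pip.argmax())],
                        "global_nie_mean": post.global_nie["mean"],
                        "global_nie_ci_low": post.global_nie["ci_low"],
                        "global_nie_ci_high": post.global_nie["ci_high"],
                        "global_effect_sq_mean": post.global_effect_sq["mean"],
                        "status": "ok",
                    }
                )
            except ValueError as exc:
                rows.append({"exposure": exp_name, "group": g, "status": f"error: {exc}"})
    return pd.DataFrame(rows), posteriors
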