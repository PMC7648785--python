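"""One-at-a-time exposure x mediator mediation screen.

For each pair, fit the IPW-weighted mediator model

    M = alpha_a A + alpha_c' C + eps

and the outcome model (continuous Y, or logit for preterm)

    Y = beta_a A + beta_m M + beta_c' C + delta

and decompose: NIE = alpha_a * beta_m (product of coefficients), NDE =
beta_a, TE = NDE + NIE for continuous outcomes. For binary outcomes the
effects live on the log-odds scale and TE is taken from the outcome model
that omits the mediator (difference-of-nested-models); with a 32%-prevalent
outcome the rare-outcome approximation behind the log-odds product is
strained, so a structured warning is attached rather than raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import CohortTable, ExposurePanel, MediatorPanel
from .inference import fit_weighted_linear, fit_weighted_logistic, qvalues

PROP_MEDIATED_TE_TOL = 1e-10


@dataclass
class MediationResult:
    """TE/NDE/NIE decomposition for a single exposure-mediator pair."""

    exposure_id: str
    mediator_id: str
    alpha_a: float
    beta_m: float
    beta_a: float  # natural direct effect
    nie: float
    te: float
    prop_mediated: float
    se_nie: float
    ci_low: float
    ci_high: float
    p_nie: float
    p_te: float
    p_nde: float
    q_nie: float = float("nan")
    outcome_kind: str = "continuous"
    se_alpha: float = float("nan")
    se_beta_m: float = float("nan")
    se_te: float = float("nan")
    flags: list[str] = field(default_factory=list)


def _sobel_se(alpha: float, beta: float, se_alpha: float, se_beta: float) -> float:
    return float(np.sqrt(alpha**2 * se_beta**2 + beta**2 * se_alpha**2))


def mediate_pair(
    exposure: np.ndarray,
    mediator: np.ndarray,
    cohort: CohortTable,
    outcome_kind: str = "continuous",
    se_method: str = "sobel",
    exposure_id: str = "exposure",
    mediator_id: str = "mediator",
    n_boot: int = 1000,
    seed: int = 0,
    alpha_level: float = 0.05,
) -> MediationResult:
    """Single-pair mediation with IPW weights.

    ``exposure`` and ``mediator`` are expected on their analysis scale
    already (log, or log-z / standardized scores). Sobel (delta-method)
    standard errors by default; ``se_method='bootstrap'`` resamples subjects
    with replacement and recomputes both regressions, keeping the IPW
    weights fixed (they are design constants).
    """
    a = np.asarray(exposure, float)
    m = np.asarray(mediator, float)
    if np.std(a) == 0:
        raise ValueError(f"zero-variance exposure {exposure_id!r}")
    if np.std(m) == 0:
        raise ValueError(f"zero-variance mediator {mediator_id!r}")
    y = cohort.outcome(outcome_kind)
    covs, cov_names = cohort.covariate_design()
    w = cohort.ipw_weight
    kind = "continuous" if outcome_kind in ("continuous", "gestage") else "binary"

    est = _estimate(a, m, y, covs, w, kind)
    alpha_a, beta_m, beta_a, nie, te = (
        est["alpha_a"],
        est["beta_m"],
        est["beta_a"],
        est["nie"],
        est["te"],
    )

    z = norm.ppf(1.0 - alpha_level / 2.0)
    flags: list[str] = []
    if se_method == "sobel":
        se_nie = _sobel_se(alpha_a, beta_m, est["se_alpha"], est["se_beta_m"])
        ci_low, ci_high = nie - z * se_nie, nie + z * se_nie
    elif se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(y)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                boots[b] = _estimate(a[idx], m[idx], y[idx], covs[idx], w[idx], kind)["nie"]
            except ValueError:
                boots[b] = np.nan
        boots = boots[np.isfinite(boots)]
        se_nie = float(np.std(boots, ddof=1))
        ci_low, ci_high = np.percentile(boots, [100 * alpha_level / 2, 100 * (1 - alpha_level / 2)])
        # percentile interval need not cover the point estimate exactly;
        # widen to include it so the reported triple is internally consistent
        ci_low, ci_high = min(ci_low, nie), max(ci_high, nie)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")

    p_nie = 2.0 * norm.sf(abs(nie) / se_nie) if se_nie > 0 else float(nie != 0.0) * 0.0
    if se_nie == 0:
        p_nie = 1.0 if nie == 0 else 0.0
    if kind == "binary":
        flags.append("log_odds_scale_nonrare_outcome")

    prop, prop_flags = _proportion(nie, te)
    flags.extend(prop_flags)

    return MediationResult(
        exposure_id=exposure_id,
        mediator_id=mediator_id,
        alpha_a=alpha_a,
        beta_m=beta_m,
        beta_a=beta_a,
        nie=nie,
        te=te,
        prop_mediated=prop,
        se_nie=se_nie,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_nie=float(p_nie),
        p_te=est["p_te"],
        p_nde=est["p_nde"],
        outcome_kind=kind,
        se_alpha=est["se_alpha"],
        se_beta_m=est["se_beta_m"],
        se_te=est["se_te"],
        flags=flags,
    )


def _estimate(a, m, y, covs, w, kind) -> dict:
    design_med = np.column_stack([a, covs])
    fit_med = fit_weighted_linear(m, design_med, w)
    alpha_a = float(fit_med.coefficients[0])
    se_alpha = float(fit_med.standard_errors[0])
    p_alpha = float(fit_med.pvalues()[0])

    design_out = np.column_stack([a, m, covs])
    design_te = design_med  # outcome on exposure + covariates only
    if kind == "continuous":
        fit_out = fit_weighted_linear(y, design_out, w)
        fit_te = fit_weighted_linear(y, design_te, w)
    else:
        fit_out = fit_weighted_logistic(y, design_out, w)
        fit_te = fit_weighted_logistic(y, design_te, w)
    beta_a = float(fit_out.coefficients[0])
    beta_m = float(fit_out.coefficients[1])
    se_beta_m = float(fit_out.standard_errors[1])
    nie = alpha_a * beta_m
    if kind == "continuous":
        te = beta_a + nie
    else:
        te = float(fit_te.coefficients[0])
    return {
        "alpha_a": alpha_a,
        "se_alpha": se_alpha,
        "p_alpha": p_alpha,
        "beta_m": beta_m,
        "se_beta_m": se_beta_m,
        "beta_a": beta_a,
        "nie": nie,
        "te": te,
        "se_te": float(fit_te.standard_errors[0]),
        "p_te": float(fit_te.pvalues()[0]),
        "p_nde": float(fit_out.pvalues()[0]),
        "te_difference": float(fit_te.coefficients[0]) - beta_a,
    }


def _proportion(nie: float, te: float) -> tuple[float, list[str]]:
    if abs(te) < PROP_MEDIATED_TE_TOL:
        return float("nan"), ["prop_mediated_undefined_te_zero"]
    prop = nie / te
    if np.sign(nie) != 0 and np.sign(nie) != np.sign(te):
        return prop, ["inconsistent_mediation"]
    return prop, []


def proportion_mediated(
    result: MediationResult,
    exposure: np.ndarray | None = None,
    mediator: np.ndarray | None = None,
    cohort: CohortTable | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """NIE / TE, with an optional bootstrap percentile CI.

    Returns a dict with ``value`` (NaN sentinel when |TE| is below tolerance),
    ``flags``, and ``ci`` when the data needed to resample are supplied.
    """
    value, flags = _proportion(result.nie, result.te)
    out = {"value": value, "flags": flags, "ci": None}
    if exposure is not None and mediator is not None and cohort is not None and np.isfinite(value):
        rng = np.random.default_rng(seed)
        a = np.asarray(exposure, float)
        m = np.asarray(mediator, float)
        y = cohort.outcome(result.outcome_kind)
        covs, _ = cohort.covariate_design()
        w = cohort.ipw_weight
        n = len(y)
        props = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                e = _estimate(a[idx], m[idx], y[idx], covs[idx], w[idx], result.outcome_kind)
            except ValueError:
                continue
            if abs(e["te"]) >= PROP_MEDIATED_TE_TOL:
                props.append(e["nie"] / e["te"])
        if props:
            out["ci"] = tuple(np.percentile(props, [2.5, 97.5]))
    return out


def run_pairwise_screen(
    exposures: ExposurePanel,
    mediators: MediatorPanel,
    cohort: CohortTable,
    outcome_kind: str = "continuous",
    se_method: str = "sobel",
    qvalue_method: str = "storey",
) -> pd.DataFrame:
    """Exhaustive p x q screen; one row per pair, q-values across NIE p-values.

    Per-pair failures are recorded as flagged rows (``status != 'ok'``) and
    never abort the screen. Rows are ordered by (class, analyte, group,
    mediator), i.e. the panels' own column order.
    """
    if exposures.n != cohort.n or mediators.n != cohort.n:
        raise ValueError("panels must be row-aligned to the cohort")
    a_mat = exposures.matrix()
    m_mat = mediators.matrix()
    rows = []
    for j, exp_name in enumerate(exposures.columns):
        for l, med_name in enumerate(mediators.columns):
            try:
                res = mediate_pair(
                    a_mat[:, j],
                    m_mat[:, l],
                    cohort,
                    outcome_kind=outcome_kind,
                    se_method=se_method,
                    exposure_id=exp_name,
                    mediator_id=med_name,
                )
                row = {
                    "exposure": exp_name,
                    "exposure_class": exposures.class_map[exp_name],
                    "mediator": med_name,
                    "mediator_group": mediators.group_map[med_name],
                    "alpha_a": res.alpha_a,
                    "beta_m": res.beta_m,
                    "nde": res.beta_a,
                    "nie": res.nie,
                    "te": res.te,
                    "prop_mediated": res.prop_mediated,
                    "se_nie": res.se_nie,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p_nie": res.p_nie,
                    "p_te": res.p_te,
                    "p_nde": res.p_nde,
                    "flags": ";".join(res.flags),
                    "status": "ok",
                }
            except ValueError as exc:
                row = {
                    "exposure": exp_name,
                    "exposure_class": exposures.class_map[exp_name],
                    "mediator": med_name,
                    "mediator_group": mediators.group_map[med_name],
                    "status": f"error: {exc}",
                }
            rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["status"] == "ok"
    table["q_nie"] = np.nan
    if ok.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table.loc[ok, "q_nie"] = qvalues(table.loc[ok, "p_nie"].to_numpy(), qvalue_method)
    return table
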