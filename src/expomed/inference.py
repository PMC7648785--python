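"""Weighted regression engines, IPW construction, and multiple testing.

All fits treat the IPW weights as fixed design constants and report
design-robust (HC-type sandwich) standard errors, the behaviour of
survey-weighted regression engines. The linear solver is closed-form WLS
(it sits inside the 2,318-model screen); the logistic solver wraps
statsmodels GLM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg as sla


@dataclass
class FitResult:
    coefficients: np.ndarray
    standard_errors: np.ndarray  # sandwich-robust
    residual_variance: float
    n_used: int
    model_kind: str  # "linear" | "logistic"
    cov: np.ndarray | None = None
    converged: bool = True

    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coefficients / self.standard_errors

    def pvalues(self) -> np.ndarray:
        from scipy.stats import norm

        return 2.0 * norm.sf(np.abs(self.zvalues()))


def compute_ipw(
    case_status: np.ndarray,
    cohort_case_count: int,
    cohort_control_count: int,
) -> np.ndarray:
    """Inverse-probability-of-selection weights for a nested case-control sample.

    weight = 1 / P(selected | status), constant within each status stratum, so
    the weighted subset re-represents the source cohort's case mix.
    """
    status = np.asarray(case_status)
    n_cases = int(np.sum(status == "case"))
    n_controls = int(np.sum(status == "control"))
    if n_cases == 0 or n_controls == 0:
        raise ValueError("a case-control stratum is absent from the sample")
    if n_cases > cohort_case_count or n_controls > cohort_control_count:
        raise ValueError("sampled stratum larger than its cohort stratum")
    w_case = cohort_case_count / n_cases
    w_control = cohort_control_count / n_controls
    return np.where(status == "case", w_case, w_control)


def _check_rank(design: np.ndarray, names: list[str] | None = None) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        _, _, piv = sla.qr(design, mode="economic", pivoting=True)
        bad = sorted(piv[rank:].tolist())
        labels = [names[i] if names else str(i) for i in bad]
        raise ValueError(f"design is rank deficient; collinear columns: {labels}")


def fit_weighted_linear(
    y: np.ndarray,
    design: np.ndarray,
    weights: np.ndarray | None = None,
    names: list[str] | None = None,
) -> FitResult:
    """Weighted least squares with HC0 sandwich standard errors.

    With equal weights this reduces to OLS, and duplicating a row is
    equivalent to doubling its weight (frequency-weight semantics for the
    point estimate).
    """
    y = np.asarray(y, float)
    X = np.asarray(design, float)
    n, k = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if len(y) != n or len(w) != n:
        raise ValueError("y, design and weights must have matching rows")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    _check_rank(X, names)

    xtw = X.T * w
    bread = np.linalg.inv(xtw @ X)
    beta = bread @ (xtw @ y)
    resid = y - X @ beta
    # sandwich: (X'WX)^-1 X'W diag(e^2) WX (X'WX)^-1
    meat = (xtw * resid**2) @ xtw.T
    cov = bread @ meat @ bread
    wss = float(np.sum(w * resid**2))
    dof = max(n - k, 1)
    resid_var = wss / np.sum(w) * n / dof
    return FitResult(
        coefficients=beta,
        standard_errors=np.sqrt(np.diag(cov)),
        residual_variance=resid_var,
        n_used=n,
        model_kind="linear",
        cov=cov,
    )


def fit_weighted_logistic(
    y: np.ndarray,
    design: np.ndarray,
    weights: np.ndarray | None = None,
    names: list[str] | None = None,
    maxiter: int = 100,
) -> FitResult:
    """Weighted logistic regression (GLM binomial) with sandwich SEs.

    Raises on perfect separation or non-convergence rather than returning a
    silently divergent fit.
    """
    y = np.asarray(y, float)
    X = np.asarray(design, float)
    n = len(y)
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("binary outcome must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("binary outcome has a single class")
    _check_rank(X, names)

    model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
    try:
        res = model.fit(cov_type="HC0", maxiter=maxiter)
    except Exception as exc:  # statsmodels PerfectSeparationError and kin
        raise ValueError(f"logistic fit failed: {exc}") from exc
    if not res.converged:
        raise ValueError(f"logistic fit did not converge in {maxiter} iterations")
    mu = res.fittedvalues
    if np.min(mu) < 1e-10 or np.max(mu) > 1 - 1e-10:
        raise ValueError("perfect separation: fitted probabilities at the boundary")
    return FitResult(
        coefficients=np.asarray(res.params),
        standard_errors=np.asarray(res.bse),
        residual_variance=float(res.scale),
        n_used=n,
        model_kind="logistic",
        cov=np.asarray(res.cov_params()),
    )


def _bh_step_up(p: np.ndarray, pi0: float = 1.0) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def storey_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's pi0 estimate: cubic smoother over a lambda grid, read at max."""
    p = np.asarray(p, float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    if len(lambdas) >= 4:
        coeffs = np.polyfit(lambdas, pi0_l, 3)
        pi0 = float(np.polyval(coeffs, lambdas[-1]))
    else:
        pi0 = float(pi0_l[-1])
    return float(np.clip(pi0, 1e-8, 1.0))


def qvalues(p: np.ndarray, method: str = "storey") -> np.ndarray:
    """False-discovery-rate q-values (Storey default; BH by flag).

    BH:    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    Storey: same step-up with the estimated null fraction pi0 multiplied in,
    so q >= p * pi0 and ordering is preserved.
    """
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return _bh_step_up(p)
    if method == "storey":
        return _bh_step_up(p, pi0=storey_pi0(p))
    raise ValueError(f"unknown method {method!r}")


def weighted_quantile(values: np.ndarray, weights: np.ndarray, qs) -> np.ndarray:
    """Quantiles interpolated on the weighted empirical CDF."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cdf = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return np.interp(np.atleast_1d(qs), cdf, v)


def weighted_descriptives(cohort) -> pd.DataFrame:
    """Weighted medians/IQRs for numeric variables and weighted percentages
    for categoricals, in the shape of a cohort-profile table."""
    w = cohort.ipw_weight
    rows = []
    numeric = {"gestational_age": cohort.outcome_continuous}
    for col in cohort.covariates.columns:
        series = cohort.covariates[col]
        if pd.api.types.is_numeric_dtype(series) and series.nunique() > 2:
            numeric[col] = series.to_numpy(float)
    for name, vals in numeric.items():
        q25, q50, q75 = weighted_quantile(vals, w, [0.25, 0.5, 0.75])
        rows.append({"variable": name, "level": "", "statistic": "median", "value": q50})
        rows.append({"variable": name, "level": "", "statistic": "iqr", "value": q75 - q25})
    categoricals = {"case_status": pd.Series(cohort.case_status)}
    for col in cohort.covariates.columns:
        series = cohort.covariates[col]
        if not (pd.api.types.is_numeric_dtype(series) and series.nunique() > 2):
            categoricals[col] = series.astype(str)
    for name, series in categoricals.items():
        total = np.sum(w)
        for level in sorted(series.unique()):
            pct = 100.0 * np.sum(w[(series == level).to_numpy()]) / total
            rows.append({"variable": name, "level": str(level), "statistic": "weighted_pct", "value": pct})
    return pd.DataFrame(rows)
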