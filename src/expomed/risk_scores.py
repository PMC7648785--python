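"""Environmental risk scores via per-class adaptive elastic net.

Each exposure class k (phthalates, phenols, PAHs, metals) is regressed
against gestational age with the penalized objective

    (1/n) sum_i (y_i - gamma_c' C_i - gamma_k' A_ik)^2
        + lambda1 * sum_j w_j |gamma_kj| + (lambda2 / 2) * sum_j gamma_kj^2

where covariates are unpenalized and the adaptive weights
w_j = (|gamma_init_j| + 1/n)^-1 come from a ridge-heavy initial fit. The
class risk score is the linear combination ERS_ik = gamma_k' A_ik,
standardized, which replaces p_k collinear analytes with one score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CohortTable, ExposurePanel, MediatorPanel
from .pairwise import mediate_pair

LAMBDA2_GRID = (0.0, 0.01, 0.1, 1.0, 10.0)


@dataclass
class RiskScoreModel:
    class_k: str
    feature_names: list[str]
    gamma_k: np.ndarray
    gamma_c: np.ndarray
    adaptive_weights: np.ndarray
    lambda1: float
    lambda2: float
    cv_folds: int
    cv_error_path: pd.DataFrame
    ers: np.ndarray  # standardized per-subject score
    degenerate: bool = False
    kkt_max_violation: float = 0.0
    orientation: float = 1.0  # sign so that higher ERS tracks higher risk


def _soft(z: float, t: float) -> float:
    return np.sign(z) * max(abs(z) - t, 0.0)


def _residualize_on(X_unpen: np.ndarray, arrs: list[np.ndarray]) -> list[np.ndarray]:
    if X_unpen.shape[1] == 0:
        return [np.asarray(v, float) for v in arrs]
    Q, _ = np.linalg.qr(X_unpen)
    return [np.asarray(v, float) - Q @ (Q.T @ np.asarray(v, float)) for v in arrs]


def _gram_cd(
    G: np.ndarray,
    c: np.ndarray,
    diag: np.ndarray,
    lambda1: float,
    lambda2: float,
    adaptive_weights: np.ndarray,
    gamma: np.ndarray,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Covariance-update coordinate descent; G = (2/n) A'A, c = (2/n) A'y."""
    p = len(c)
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            old = gamma[j]
            z = c[j] - G[j] @ gamma + diag[j] * old
            new = _soft(z, lambda1 * adaptive_weights[j]) / (diag[j] + lambda2)
            if new != old:
                gamma[j] = new
                delta = max(delta, abs(new - old))
        if delta < tol:
            break
    return gamma


def enet_coordinate_descent(
    y: np.ndarray,
    X_pen: np.ndarray,
    X_unpen: np.ndarray,
    lambda1: float,
    lambda2: float,
    adaptive_weights: np.ndarray,
    start: tuple[np.ndarray, np.ndarray] | None = None,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate descent for the (1/n)-loss adaptive elastic net.

    The unpenalized block is profiled out exactly (Frisch-Waugh): the
    penalized problem is solved on covariate-residualized data with
    covariance-update coordinate descent (penalized update gamma_j =
    S((2/n) x'r, lambda1 w_j) / ((2/n) x'x + lambda2)), and the unpenalized
    coefficients are recovered by least squares afterwards.
    """
    y = np.asarray(y, float)
    n = len(y)
    At, yt = _residualize_on(X_unpen, [X_pen, y])
    G = (2.0 / n) * (At.T @ At)
    c = (2.0 / n) * (At.T @ yt)
    gamma = np.zeros(X_pen.shape[1]) if start is None else start[0].copy()
    gamma = _gram_cd(G, c, np.diag(G).copy(), lambda1, lambda2, adaptive_weights, gamma, tol, max_iter)
    if X_unpen.shape[1] > 0:
        gamma_c, *_ = np.linalg.lstsq(X_unpen, y - X_pen @ gamma, rcond=None)
    else:
        gamma_c = np.zeros(0)
    return gamma, gamma_c


def kkt_violation(
    y: np.ndarray,
    X_pen: np.ndarray,
    X_unpen: np.ndarray,
    gamma: np.ndarray,
    gamma_c: np.ndarray,
    lambda1: float,
    lambda2: float,
    adaptive_weights: np.ndarray,
) -> float:
    """Max stationarity violation of the elastic-net KKT system at a point."""
    n = len(y)
    resid = y - X_pen @ gamma - X_unpen @ gamma_c
    viol = float(np.max(np.abs(X_unpen.T @ resid / n))) if X_unpen.shape[1] else 0.0
    grad = (2.0 / n) * (X_pen.T @ resid)
    for j in range(len(gamma)):
        t = lambda1 * adaptive_weights[j]
        if gamma[j] != 0.0:
            viol = max(viol, abs(grad[j] - lambda2 * gamma[j] - t * np.sign(gamma[j])))
        else:
            viol = max(viol, max(abs(grad[j]) - t, 0.0))
    return viol


def cv_fold_assignment(n: int, folds: int, seed: int) -> np.ndarray:
    """Deterministic fold labels: a pure function of (seed, n, folds)."""
    perm = np.random.default_rng(seed).permutation(n)
    labels = np.empty(n, int)
    labels[perm] = np.arange(n) % folds
    return labels


def lambda1_max(y, X_pen, X_unpen, adaptive_weights) -> float:
    n = len(y)
    coef, *_ = np.linalg.lstsq(X_unpen, y, rcond=None)
    r = y - X_unpen @ coef
    return float(np.max(np.abs((2.0 / n) * (X_pen.T @ r)) / adaptive_weights))


def fit_adaptive_elastic_net(
    y: np.ndarray,
    exposures_k: np.ndarray,
    covariates: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    class_k: str = "class",
    feature_names: list[str] | None = None,
    lambda1_grid: np.ndarray | None = None,
    lambda2_grid: tuple[float, ...] = LAMBDA2_GRID,
    n_lambda1: int = 50,
) -> RiskScoreModel:
    """Fit one class's adaptive elastic net with (lambda1, lambda2) chosen
    jointly on a seeded k-fold CV grid.

    ``exposures_k`` must be log-z-scored; ``covariates`` should include an
    intercept column and is never penalized. A class where every grid point
    shrinks all weights to zero returns a degenerate (all-zero) model with a
    warning flag rather than raising.
    """
    y = np.asarray(y, float)
    A = np.asarray(exposures_k, float)
    C = np.asarray(covariates, float)
    n, p_k = A.shape
    if folds < 2:
        raise ValueError("folds must be >= 2")
    names = feature_names if feature_names is not None else [f"x{j}" for j in range(p_k)]

    # ridge-heavy initial fit for the adaptive weights (lambda1 = 0)
    fold_labels = cv_fold_assignment(n, folds, seed)
    fold_ctx = _fold_context(y, A, C, fold_labels, folds)
    ones = np.ones(p_k)
    ridge_err = _cv_grid(fold_ctx, np.array([0.0]), (0.01, 0.1, 1.0, 10.0), ones)
    best_ridge = (0.01, 0.1, 1.0, 10.0)[int(np.argmin(ridge_err[:, 0]))]
    gamma_init, _ = enet_coordinate_descent(y, A, C, 0.0, best_ridge, ones)
    adaptive_weights = 1.0 / (np.abs(gamma_init) + 1.0 / n)

    lam_max = lambda1_max(y, A, C, adaptive_weights)
    if lambda1_grid is None:
        lambda1_grid = np.geomspace(lam_max, lam_max * 1e-4, n_lambda1)
    lambda1_grid = np.sort(np.asarray(lambda1_grid, float))[::-1]

    errs = _cv_grid(fold_ctx, lambda1_grid, lambda2_grid, adaptive_weights)
    records = [
        {"lambda1": lam1, "lambda2": lam2, "cv_error": errs[i2, i1]}
        for i2, lam2 in enumerate(lambda2_grid)
        for i1, lam1 in enumerate(lambda1_grid)
    ]
    i2, i1 = np.unravel_index(int(np.argmin(errs)), errs.shape)
    lam1_star, lam2_star = float(lambda1_grid[i1]), float(lambda2_grid[i2])
    gamma, gamma_c = enet_coordinate_descent(y, A, C, lam1_star, lam2_star, adaptive_weights)
    viol = kkt_violation(y, A, C, gamma, gamma_c, lam1_star, lam2_star, adaptive_weights)

    degenerate = bool(np.all(gamma == 0.0))
    raw = A @ gamma
    orientation = 1.0
    if degenerate:
        ers = np.zeros(n)
    else:
        # risk-score convention: a higher score means a worse expected
        # outcome (here, shorter gestation), so flip when the raw linear
        # combination tracks the outcome positively
        if np.corrcoef(raw, y)[0, 1] > 0:
            orientation = -1.0
        ers = orientation * (raw - raw.mean()) / raw.std(ddof=0)
    return RiskScoreModel(
        class_k=class_k,
        feature_names=list(names),
        gamma_k=gamma,
        gamma_c=gamma_c,
        adaptive_weights=adaptive_weights,
        lambda1=float(lam1_star),
        lambda2=float(lam2_star),
        cv_folds=folds,
        cv_error_path=pd.DataFrame(records),
        ers=ers,
        degenerate=degenerate,
        kkt_max_violation=viol,
        orientation=orientation,
    )


def _fold_context(y, A, C, fold_labels, folds) -> list[dict]:
    """Precomputed per-fold pieces: train Gram on residualized data, a train
    QR for recovering the unpenalized block, and the held-out arrays."""
    ctx = []
    for f in range(folds):
        test = fold_labels == f
        At, yt = _residualize_on(C[~test], [A[~test], y[~test]])
        n_tr = int(np.sum(~test))
        Q, R = np.linalg.qr(C[~test])
        ctx.append(
            {
                "G": (2.0 / n_tr) * (At.T @ At),
                "c": (2.0 / n_tr) * (At.T @ yt),
                "A_tr": A[~test],
                "y_tr": y[~test],
                "QR": (Q, R),
                "A_te": A[test],
                "C_te": C[test],
                "y_te": y[test],
            }
        )
    return ctx


def _cv_grid(fold_ctx, lam1_path, lam2_grid, w_adapt, tol=1e-9, max_iter=2000) -> np.ndarray:
    """CV error over the (lambda2, lambda1) grid, warm-starting each fold's
    solution down the lambda1 path."""
    errs = np.zeros((len(lam2_grid), len(lam1_path)))
    for ctx in fold_ctx:
        G, c = ctx["G"], ctx["c"]
        diag = np.diag(G).copy()
        Q, R = ctx["QR"]
        for i2, lam2 in enumerate(lam2_grid):
            gamma = np.zeros(len(c))
            for i1, lam1 in enumerate(lam1_path):
                gamma = _gram_cd(G, c, diag, lam1, lam2, w_adapt, gamma, tol, max_iter)
                gamma_c = np.linalg.solve(R, Q.T @ (ctx["y_tr"] - ctx["A_tr"] @ gamma))
                pred = ctx["A_te"] @ gamma + ctx["C_te"] @ gamma_c
                errs[i2, i1] += np.mean((ctx["y_te"] - pred) ** 2)
    return errs / len(fold_ctx)


def compute_ers(exposures_k: np.ndarray, model: RiskScoreModel) -> np.ndarray:
    """Score new subjects with a fitted model (same transform as the fit)."""
    A = np.asarray(exposures_k, float)
    if A.shape[1] != len(model.gamma_k):
        raise ValueError(
            f"column mismatch: panel has {A.shape[1]} analytes, model expects {len(model.gamma_k)}"
        )
    raw = A @ model.gamma_k
    if model.degenerate:
        return np.zeros(len(raw))
    return model.orientation * (raw - raw.mean()) / raw.std(ddof=0)


def build_risk_scores(
    exposures: ExposurePanel,
    cohort: CohortTable,
    folds: int = 5,
    seed: int = 0,
    **kwargs,
) -> tuple[pd.DataFrame, dict[str, RiskScoreModel]]:
    """One adaptive-elastic-net model and standardized ERS per exposure class."""
    logz = exposures.log_z()
    y = cohort.outcome("continuous")
    covs, _ = cohort.covariate_design()
    models: dict[str, RiskScoreModel] = {}
    scores = {}
    for k in logz.classes():
        cols = logz.columns_of(k)
        model = fit_adaptive_elastic_net(
            y,
            logz.values[cols].to_numpy(float),
            covs,
            folds=folds,
            seed=seed,
            class_k=k,
            feature_names=cols,
            **kwargs,
        )
        models[k] = model
        scores[f"ers_{k}"] = model.ers
    return pd.DataFrame(scores), models


def ers_mediation_screen(
    ers_panel: pd.DataFrame,
    mediators: MediatorPanel,
    cohort: CohortTable,
    se_method: str = "sobel",
) -> pd.DataFrame:
    """Mediation screen with each class ERS as the exposure (4 x q rows).

    ERS are already standardized; mediators are log-z-scored here to match.
    """
    from .inference import qvalues

    med_z = mediators.log_z()
    m_mat = med_z.matrix()
    rows = []
    for score_name in ers_panel.columns:
        score = ers_panel[score_name].to_numpy(float)
        for l, med_name in enumerate(med_z.columns):
            try:
                res = mediate_pair(
                    score,
                    m_mat[:, l],
                    cohort,
                    outcome_kind="continuous",
                    se_method=se_method,
                    exposure_id=score_name,
                    mediator_id=med_name,
                )
                rows.append(
                    {
                        "exposure": score_name,
                        "mediator": med_name,
                        "mediator_group": med_z.group_map[med_name],
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
                        "status": "ok",
                    }
                )
            except ValueError as exc:
                rows.append(
                    {
                        "exposure": score_name,
                        "mediator": med_name,
                        "mediator_group": med_z.group_map[med_name],
                        "status": f"error: {exc}",
                    }
                )
    table = pd.DataFrame(rows)
    ok = table["status"] == "ok"
    table["q_nie"] = np.nan
    if ok.any():
        table.loc[ok, "q_nie"] = qvalues(table.loc[ok, "p_nie"].to_numpy(), "storey")
    return table
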