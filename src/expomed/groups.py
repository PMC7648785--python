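"""Mediator dimension reduction: directions of mediation and sparse PCs.

The first direction of mediation for a group g is the unit-norm loading
vector w_g maximizing the Gaussian profile log-likelihood of the
two-equation mediation system with M_g w as the (single) mediator:

    obj(w) = -(n/2) [ log RSS_1(w) + log RSS_2(w) ]

where RSS_1 is from the mediator model (M_g w on exposure + covariates) and
RSS_2 from the outcome model (Y on exposure, M_g w, covariates). With
residualized cross-products precomputed, both terms are closed forms in w:

    RSS_1(w) = w' S w,          S = M' R M
    RSS_2(w) = c - (b'w)^2 / (w'S w),   b = M' R y,  c = y' R y

(R the weighted residual-maker of the exposure+covariate design), so the
sphere optimization is cheap. The induced per-subject mediator group effect
is MGE_ig = M_ig w_g.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CohortTable, MediatorPanel
from .pairwise import MediationResult, mediate_pair

#: fraction of the outcome residual variance the MGE must explain in-sample
#: for the direction to count as estimable rather than "sparse signal"
SPARSE_SIGNAL_FRACTION = 1e-4


@dataclass
class DirectionOfMediation:
    group_g: str
    mediator_names: list[str]
    w_g: np.ndarray  # unit Euclidean norm
    mge: np.ndarray  # M_g @ w_g on standardized mediators
    objective_value: float
    converged: bool
    status: str = "ok"  # ok | sparse_signal
    contribution_rho: pd.Series | None = None
    n_restarts: int = 0


@dataclass
class SparsePCSet:
    loadings: np.ndarray  # q x n_components
    explained_variance_fraction: np.ndarray
    n_components: int
    penalty: float


def _weighted_residual_maker(design: np.ndarray, w: np.ndarray):
    """Return a function projecting out the weighted span of ``design``."""
    sw = np.sqrt(w)
    Xs = design * sw[:, None]
    Q, _ = np.linalg.qr(Xs)

    def residualize(v: np.ndarray) -> np.ndarray:
        vs = v * (sw[:, None] if v.ndim == 2 else sw)
        return vs - Q @ (Q.T @ vs)

    return residualize


class _ProfileObjective:
    """Closed-form profile log-likelihood and gradient on the sphere."""

    def __init__(self, exposure, mediators_g, outcome, covariates, weights):
        n = len(outcome)
        w = np.ones(n) if weights is None else np.asarray(weights, float)
        design = np.column_stack([exposure, covariates])
        resid = _weighted_residual_maker(design, w)
        Mt = resid(np.asarray(mediators_g, float))
        yt = resid(np.asarray(outcome, float))
        self.S = Mt.T @ Mt
        self.b = Mt.T @ yt
        self.c = float(yt @ yt)
        self.n = n

    def value(self, w: np.ndarray) -> float:
        rss1 = float(w @ self.S @ w)
        rss2 = self.c - float(self.b @ w) ** 2 / rss1
        return -0.5 * self.n * (np.log(rss1) + np.log(max(rss2, 1e-300)))

    def grad(self, w: np.ndarray) -> np.ndarray:
        Sw = self.S @ w
        rss1 = float(w @ Sw)
        bw = float(self.b @ w)
        rss2 = self.c - bw**2 / rss1
        d_rss1 = 2.0 * Sw
        d_rss2 = -(2.0 * bw * self.b * rss1 - bw**2 * d_rss1) / rss1**2
        return -0.5 * self.n * (d_rss1 / rss1 + d_rss2 / max(rss2, 1e-300))

    def mge_outcome_fraction(self, w: np.ndarray) -> float:
        """Share of the outcome's residual variance the MGE explains."""
        rss1 = float(w @ self.S @ w)
        return float(self.b @ w) ** 2 / rss1 / self.c


def _sphere_ascent(obj: _ProfileObjective, w0: np.ndarray, tol: float = 1e-8, max_iter: int = 2000):
    """Projected gradient ascent on the unit sphere with backtracking."""
    w = w0 / np.linalg.norm(w0)
    f = obj.value(w)
    step = 1.0 / max(obj.n, 1)
    for _ in range(max_iter):
        g = obj.grad(w)
        g_tan = g - (g @ w) * w
        if np.linalg.norm(g_tan) < 1e-12:
            return w, f, True
        s = step
        improved = False
        for _ in range(60):
            cand = w + s * g_tan
            cand /= np.linalg.norm(cand)
            fc = obj.value(cand)
            if fc > f:
                improved = True
                break
            s *= 0.5
        if not improved:
            return w, f, True
        if fc - f < tol * (1.0 + abs(f)):
            w, f = cand, fc
            return w, f, True
        w, f = cand, fc
        step = min(s * 2.0, 1.0)
    return w, f, False


def estimate_direction(
    exposure: np.ndarray,
    mediators_g: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray,
    weights: np.ndarray | None = None,
    group_g: str = "all",
    mediator_names: list[str] | None = None,
    n_restarts: int = 20,
    seed: int = 0,
) -> DirectionOfMediation:
    """Best direction over (first-PC start + seeded random restarts).

    Sign convention: flipped so the largest-|loading| entry is positive.
    Groups whose MGE explains essentially none of the outcome's residual
    variance come back with ``status='sparse_signal'`` (not an exception),
    mirroring group effects the decomposition cannot estimate.
    """
    M = np.asarray(mediators_g, float)
    n, q_g = M.shape
    names = mediator_names if mediator_names is not None else [f"m{l}" for l in range(q_g)]
    if q_g == 1:
        w = np.array([1.0])
        mge = M[:, 0].copy()
        obj = _ProfileObjective(exposure, M, outcome, covariates, weights)
        return DirectionOfMediation(
            group_g=group_g,
            mediator_names=list(names),
            w_g=w,
            mge=mge,
            objective_value=obj.value(w),
            converged=True,
            contribution_rho=pd.Series([1.0], index=names),
        )

    obj = _ProfileObjective(exposure, M, outcome, covariates, weights)
    rng = np.random.default_rng(seed)
    Mc = M - M.mean(axis=0)
    _, _, vt = np.linalg.svd(Mc, full_matrices=False)
    starts = [vt[0]] + [rng.standard_normal(q_g) for _ in range(n_restarts)]
    best_w, best_f, best_conv = None, -np.inf, False
    for w0 in starts:
        w, f, conv = _sphere_ascent(obj, w0)
        if f > best_f:
            best_w, best_f, best_conv = w, f, conv
    if best_w is None:
        raise ValueError("direction optimization failed from every start")

    if best_w[np.argmax(np.abs(best_w))] < 0:
        best_w = -best_w
    mge = M @ best_w
    status = "ok"
    if obj.mge_outcome_fraction(best_w) < SPARSE_SIGNAL_FRACTION:
        status = "sparse_signal"
    rho = pd.Series(
        [float(np.corrcoef(mge, M[:, l])[0, 1]) if np.std(M[:, l]) > 0 else np.nan for l in range(q_g)],
        index=names,
    )
    return DirectionOfMediation(
        group_g=group_g,
        mediator_names=list(names),
        w_g=best_w,
        mge=mge,
        objective_value=best_f,
        converged=best_conv,
        status=status,
        contribution_rho=rho,
        n_restarts=n_restarts,
    )


def mge_mediation(
    exposure: np.ndarray,
    direction: DirectionOfMediation,
    cohort: CohortTable,
    se_method: str = "sobel",
    exposure_id: str = "exposure",
) -> MediationResult:
    """Single-mediator mediation with the (standardized) MGE as mediator."""
    if not direction.converged:
        raise ValueError(f"direction for group {direction.group_g!r} did not converge")
    mge = direction.mge
    mge_std = (mge - mge.mean()) / mge.std(ddof=0)
    return mediate_pair(
        exposure,
        mge_std,
        cohort,
        outcome_kind="continuous",
        se_method=se_method,
        exposure_id=exposure_id,
        mediator_id=f"mge_{direction.group_g}",
    )


def contribution_correlations(
    direction: DirectionOfMediation, mediators: MediatorPanel
) -> pd.Series:
    """Pearson rho between the MGE and every mediator in the full panel."""
    med_z = mediators.log_z()
    mat = med_z.matrix()
    out = {}
    for l, name in enumerate(med_z.columns):
        col = mat[:, l]
        out[name] = float(np.corrcoef(direction.mge, col)[0, 1]) if np.std(col) > 0 else np.nan
    return pd.Series(out, name=f"rho_mge_{direction.group_g}")


def run_group_mediation(
    exposure_panel: pd.DataFrame,
    mediators: MediatorPanel,
    cohort: CohortTable,
    min_group_size: int = 5,
    include_all: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], DirectionOfMediation]]:
    """(s + 1) MGE mediation analyses per exposure: each eligible group plus
    the all-mediators direction. Sparse-signal groups appear as flagged rows."""
    med_z = mediators.log_z()
    y = cohort.outcome("continuous")
    covs, _ = cohort.covariate_design()
    w = cohort.ipw_weight
    blocks = []
    if include_all:
        blocks.append(("all", med_z.columns))
    blocks += [
        (g, med_z.columns_of(g))
        for g in med_z.groups()
        if len(med_z.columns_of(g)) >= min_group_size
    ]
    rows, directions = [], {}
    for exp_name in exposure_panel.columns:
        a = exposure_panel[exp_name].to_numpy(float)
        for g, cols in blocks:
            direction = estimate_direction(
                a,
                med_z.values[cols].to_numpy(float),
                y,
                covs,
                weights=w,
                group_g=g,
                mediator_names=cols,
                seed=seed,
            )
            directions[(exp_name, g)] = direction
            if direction.status != "ok":
                rows.append(
                    {"exposure": exp_name, "group": g, "status": direction.status}
                )
                continue
            res = mge_mediation(a, direction, cohort, exposure_id=exp_name)
            rows.append(
                {
                    "exposure": exp_name,
                    "group": g,
                    "nie": res.nie,
                    "nde": res.beta_a,
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
    return pd.DataFrame(rows), directions


def sparse_pca(
    M: np.ndarray,
    penalty: float,
    variance_target: float = 0.8,
    max_components: int | None = None,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> SparsePCSet:
    """L1-penalized power iteration with projection deflation.

    Each component alternates u = Mv / ||Mv|| and v = soft(M'u, penalty)
    normalized; with penalty 0 this is exact power iteration (ordinary PCA
    loadings). Components accumulate until the cumulative explained-variance
    fraction reaches ``variance_target``.
    """
    X = np.asarray(M, float) - np.asarray(M, float).mean(axis=0)
    n, q = X.shape
    total_var = float(np.sum(X**2))
    if total_var == 0:
        raise ValueError("mediator matrix has zero variance")
    rank = np.linalg.matrix_rank(X)
    cap = min(max_components or rank, rank)
    loadings, evf = [], []
    Xd = X.copy()
    for _ in range(cap):
        # init from leading right singular vector of the deflated matrix
        _, _, vt = np.linalg.svd(Xd, full_matrices=False)
        v = vt[0]
        for _ in range(max_iter):
            u = Xd @ v
            nu = np.linalg.norm(u)
            if nu == 0:
                break
            u /= nu
            z = Xd.T @ u
            v_new = np.sign(z) * np.maximum(np.abs(z) - penalty, 0.0)
            nv = np.linalg.norm(v_new)
            if nv == 0:
                raise ValueError("penalty too large: all loadings vanished")
            v_new /= nv
            if np.linalg.norm(v_new - v) < tol:
                v = v_new
                break
            v = v_new
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        score = X @ v
        loadings.append(v)
        evf.append(float(np.sum((Xd @ v) ** 2)) / total_var)
        s = Xd @ v
        ns = float(s @ s)
        if ns > 0:
            Xd = Xd - np.outer(s, s @ Xd) / ns
        if float(np.sum(evf)) >= variance_target:
            break
    return SparsePCSet(
        loadings=np.column_stack(loadings),
        explained_variance_fraction=np.array(evf),
        n_components=len(evf),
        penalty=penalty,
    )


def sparse_pc_mediation(
    exposure: np.ndarray,
    mediators: MediatorPanel,
    cohort: CohortTable,
    variance_target: float = 0.8,
    penalty: float = 0.0,
    exposure_id: str = "exposure",
) -> tuple[pd.DataFrame, SparsePCSet]:
    """Mediate each sparse-PC score one-at-a-time; reports the sign split of
    the component NIEs alongside the per-component decomposition."""
    med_z = mediators.log_z()
    pcs = sparse_pca(med_z.matrix(), penalty=penalty, variance_target=variance_target)
    X = med_z.matrix() - med_z.matrix().mean(axis=0)
    rows = []
    for c in range(pcs.n_components):
        score = X @ pcs.loadings[:, c]
        score = (score - score.mean()) / score.std(ddof=0)
        res = mediate_pair(
            exposure,
            score,
            cohort,
            outcome_kind="continuous",
            exposure_id=exposure_id,
            mediator_id=f"spc_{c + 1}",
        )
        rows.append(
            {
                "component": c + 1,
                "explained_variance_fraction": pcs.explained_variance_fraction[c],
                "nie": res.nie,
                "te": res.te,
                "p_nie": res.p_nie,
                "nie_sign": int(np.sign(res.nie)),
            }
        )
    return pd.DataFrame(rows), pcs
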