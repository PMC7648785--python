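"""Directions of mediation, MGE mediation, and sparse-PC mediation."""

import numpy as np
import pandas as pd
import pytest

from expomed.groups import (
    _ProfileObjective,
    contribution_correlations,
    estimate_direction,
    mge_mediation,
    run_group_mediation,
    sparse_pc_mediation,
    sparse_pca,
)
from expomed.data import MediatorPanel
from expomed.simulate import SimConfig, generate_cohort

from conftest import plain_cohort


def _directional_data(seed, n=1000, q=10, strength=1.0):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    w_star = rng.standard_normal(q)
    w_star /= np.linalg.norm(w_star)
    M = np.outer(a, 0.8 * w_star) + rng.standard_normal((n, q))
    y = strength * (M @ w_star) + rng.standard_normal(n)
    return a, M, y, np.ones((n, 1)), w_star


class TestDirection:
    def test_single_mediator_group_is_identity(self):
        rng = np.random.default_rng(0)
        n = 200
        a = rng.standard_normal(n)
        m = (0.5 * a + rng.standard_normal(n))[:, None]
        d = estimate_direction(a, m, rng.standard_normal(n), np.ones((n, 1)))
        assert np.array_equal(d.w_g, [1.0])
        assert np.array_equal(d.mge, m[:, 0])
        assert d.contribution_rho.iloc[0] == 1.0

    def test_unit_norm_and_sign_convention(self):
        a, M, y, C, _ = _directional_data(1)
        d = estimate_direction(a, M, y, C, seed=0)
        assert np.linalg.norm(d.w_g) == pytest.approx(1.0, abs=1e-8)
        assert d.w_g[np.argmax(np.abs(d.w_g))] > 0

    def test_direction_recovery(self):
        hits = 0
        n_seeds = 15  # acceptance suite runs the 50-seed version
        for seed in range(n_seeds):
            a, M, y, C, w_star = _directional_data(seed)
            d = estimate_direction(a, M, y, C, seed=seed)
            hits += int(abs(d.w_g @ w_star) >= 0.9)
        assert hits >= int(0.9 * n_seeds)

    def test_objective_beats_first_principal_component(self):
        a, M, y, C, _ = _directional_data(3)
        d = estimate_direction(a, M, y, C, seed=0)
        obj = _ProfileObjective(a, M, y, C, None)
        _, _, vt = np.linalg.svd(M - M.mean(0), full_matrices=False)
        assert d.objective_value >= obj.value(vt[0]) - 1e-9

    def test_column_permutation_invariance(self):
        a, M, y, C, _ = _directional_data(4, q=6)
        d1 = estimate_direction(a, M, y, C, seed=0)
        perm = np.array([3, 1, 5, 0, 2, 4])
        d2 = estimate_direction(a, M[:, perm], y, C, seed=0)
        assert np.allclose(np.sort(np.abs(d1.w_g)), np.sort(np.abs(d2.w_g)), atol=1e-4)
        assert np.allclose(d1.mge, d2.mge, atol=1e-3) or np.allclose(d1.mge, -d2.mge, atol=1e-3)

    def test_pure_noise_direction_is_flagged_or_null(self):
        rng = np.random.default_rng(5)
        n, q = 600, 8
        a = rng.standard_normal(n)
        M = rng.standard_normal((n, q))
        y = rng.standard_normal(n)
        d = estimate_direction(a, M, y, np.ones((n, 1)), seed=0)
        if d.status == "ok":
            res = mge_mediation(a, d, plain_cohort(y))
            assert abs(res.nie) < 4 * res.se_nie


class TestContributions:
    def test_driver_mediators_exceed_threshold(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(300 + seed)
            n, q = 1000, 8
            a = rng.standard_normal(n)
            latent = rng.standard_normal(n)
            M = rng.standard_normal((n, q))
            M[:, 2] += 0.9 * latent + 0.5 * a
            M[:, 5] += 0.9 * latent + 0.5 * a
            y = latent + 0.2 * a + rng.standard_normal(n)
            d = estimate_direction(a, (M - M.mean(0)) / M.std(0), y, np.ones((n, 1)), seed=0)
            rho = np.abs(d.contribution_rho.to_numpy())
            hits += int(set(np.flatnonzero(rho > 0.3)) == {2, 5})
        assert hits >= int(0.9 * n_seeds)

    def test_full_panel_correlations(self, default_draw):
        cohort, _, mediators, _ = default_draw
        med_z = mediators.log_z()
        cols = med_z.columns_of("cox")
        a = np.random.default_rng(0).standard_normal(cohort.n)
        covs, _ = cohort.covariate_design()
        d = estimate_direction(
            a, med_z.values[cols].to_numpy(), cohort.outcome("continuous"), covs,
            group_g="cox", mediator_names=cols, seed=0,
        )
        rho = contribution_correlations(d, mediators)
        assert len(rho) == 61
        assert rho.loc[cols].abs().max() > 0.2  # own group dominates


class TestSparsePCA:
    def test_zero_penalty_equals_pca(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((150, 7)) @ np.diag([3, 2.5, 2, 1.5, 1, 0.5, 0.2])
        pcs = sparse_pca(X, penalty=0.0, variance_target=1.0)
        _, s, vt = np.linalg.svd(X - X.mean(0), full_matrices=False)
        for i in range(pcs.n_components):
            dist = min(
                np.linalg.norm(pcs.loadings[:, i] - vt[i]),
                np.linalg.norm(pcs.loadings[:, i] + vt[i]),
            )
            assert dist < 1e-8
        expected = s**2 / np.sum(s**2)
        assert np.allclose(pcs.explained_variance_fraction, expected[: pcs.n_components], atol=1e-8)

    def test_full_variance_target_gives_rank_components(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((50, 6))
        pcs = sparse_pca(X, penalty=0.0, variance_target=1.0)
        assert pcs.n_components == np.linalg.matrix_rank(X - X.mean(0))

    def test_deflation_orthogonality(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((120, 5))
        pcs = sparse_pca(X, penalty=0.0, variance_target=1.0)
        G = pcs.loadings.T @ pcs.loadings
        assert np.allclose(G, np.eye(pcs.n_components), atol=1e-8)

    def test_rank_recovery(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(400 + seed)
            n, q, r = 1000, 12, 3
            scores = rng.standard_normal((n, r)) * [6, 5, 4]
            load = np.linalg.qr(rng.standard_normal((q, r)))[0]
            X = scores @ load.T + 0.5 * rng.standard_normal((n, q))
            pcs = sparse_pca(X, penalty=0.0, variance_target=0.8)
            hits += int(pcs.n_components == r)
        assert hits >= int(0.9 * n_seeds)

    def test_excessive_penalty_raises(self):
        X = np.random.default_rng(9).standard_normal((60, 4))
        with pytest.raises(ValueError, match="penalty too large"):
            sparse_pca(X, penalty=1e6)

    def test_penalty_produces_exact_zero_loadings(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((200, 10))
        X[:, 0] *= 5
        pcs = sparse_pca(X, penalty=2.0, variance_target=0.2, max_components=1)
        assert np.any(pcs.loadings == 0.0)


class TestGroupPipeline:
    def test_s_plus_one_results_per_exposure(self, default_draw):
        cohort, exposures, mediators, _ = default_draw
        panel = pd.DataFrame({"x": np.random.default_rng(1).standard_normal(cohort.n)})
        table, directions = run_group_mediation(panel, mediators, cohort, seed=0)
        assert len(table) == 6  # all + 5 eligible groups
        assert set(directions) == {("x", g) for g in ("all", "cox", "cyp450", "lox", "parent", "inflam")}

    def test_sparse_pc_mediation_table(self, default_draw):
        cohort, exposures, mediators, _ = default_draw
        a = exposures.log_z().matrix()[:, 0]
        table, pcs = sparse_pc_mediation(a, mediators, cohort, variance_target=0.8)
        assert len(table) == pcs.n_components
        assert np.cumsum(pcs.explained_variance_fraction)[-1] >= 0.8
        assert set(table["nie_sign"]) <= {-1, 0, 1}
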