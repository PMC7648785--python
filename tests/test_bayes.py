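"""Bayesian shrinkage mediation: conjugate limits, PIPs, determinism."""

import numpy as np
import pytest

from expomed.bayes import (
    PriorSpec,
    fit_bayes_mediation,
    global_mediation_effect,
    run_shrinkage_over_exposures,
)
from expomed.pairwise import mediate_pair
from expomed.simulate import SimConfig, generate_cohort

from conftest import plain_cohort


def _one_pathway(seed, n=800, q=10, alpha=1.0, beta=1.0):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    M = rng.standard_normal((n, q))
    M[:, 0] += alpha * a
    y = beta * M[:, 0] + rng.standard_normal(n)
    C = np.ones((n, 1))
    return a, M, y, C


class TestSampler:
    def test_same_seed_bit_identical(self):
        a, M, y, C = _one_pathway(0, n=200, q=5)
        kw = dict(iterations=300, burnin=100, seed=42)
        p1 = fit_bayes_mediation(a, M, y, C, **kw)
        p2 = fit_bayes_mediation(a, M, y, C, **kw)
        assert np.array_equal(p1.draws["beta_m"], p2.draws["beta_m"])
        assert np.array_equal(p1.pip, p2.pip)

    def test_draw_count_and_pip_range(self):
        a, M, y, C = _one_pathway(1, n=200, q=5)
        post = fit_bayes_mediation(a, M, y, C, iterations=500, burnin=200, seed=0)
        assert post.n_draws == 300
        assert np.all((post.pip >= 0) & (post.pip <= 1))

    def test_nonfinite_inputs_rejected(self):
        a, M, y, C = _one_pathway(2, n=100, q=3)
        y[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_bayes_mediation(a, M, y, C, iterations=100, burnin=10)

    def test_equal_spike_slab_matches_ridge(self):
        """With the mixture collapsed (spike = slab = v) and residual
        variances frozen, the posterior mean of the outcome coefficients is
        the ridge estimator with per-block penalties."""
        rng = np.random.default_rng(3)
        n, q = 300, 4
        a = rng.standard_normal(n)
        M = rng.standard_normal((n, q))
        y = M @ [1.0, -0.5, 0.0, 0.3] + 0.5 * a + rng.standard_normal(n)
        C = np.ones((n, 1))
        v = 0.5
        prior = PriorSpec(
            fixed_slab_var=v, fixed_spike_var=v,
            fixed_resid_var_outcome=1.0, fixed_resid_var_mediator=1.0,
        )
        post = fit_bayes_mediation(
            a, M, y, C, prior=prior, iterations=6000, burnin=1000, seed=7
        )
        X = np.column_stack([a, M, C])
        D = np.diag([1 / prior.tau2] + [1 / v] * q + [1 / prior.tau2])
        ridge = np.linalg.solve(X.T @ X + D, X.T @ y)
        post_mean = np.concatenate(
            [[post.draws["beta_a"].mean()], post.draws["beta_m"].mean(axis=0)]
        )
        mc_se = np.concatenate(
            [[post.draws["beta_a"].std()], post.draws["beta_m"].std(axis=0)]
        ) / np.sqrt(post.n_draws / 10)  # conservative ESS deflation
        assert np.all(np.abs(post_mean - ridge[: q + 1]) < 4 * mc_se + 1e-3)

    def test_posterior_mean_approaches_wls_with_n(self):
        rng = np.random.default_rng(4)
        n, q = 5000, 2
        a = rng.standard_normal(n)
        M = rng.standard_normal((n, q))
        M[:, 0] += 0.5 * a
        y = 0.8 * M[:, 0] - 0.4 * M[:, 1] + 0.2 * a + rng.standard_normal(n)
        C = np.ones((n, 1))
        post = fit_bayes_mediation(a, M, y, C, iterations=2000, burnin=500, seed=5)
        X = np.column_stack([a, M, C])
        wls = np.linalg.lstsq(X, y, rcond=None)[0]
        bm = post.draws["beta_m"].mean(axis=0)
        mc = post.draws["beta_m"].std(axis=0) / np.sqrt(post.n_draws / 10)
        assert np.all(np.abs(bm - wls[1:3]) < 3 * mc + 5e-3)


class TestGlobalEffect:
    def test_constant_draw_arithmetic(self):
        a, M, y, C = _one_pathway(6, n=100, q=1)
        post = fit_bayes_mediation(a, M, y, C, iterations=200, burnin=100, seed=1)
        post.draws["alpha_a"] = np.full((50, 1), 2.0)
        post.draws["beta_m"] = np.full((50, 1), 3.0)
        assert global_mediation_effect(post, "sum_products")["mean"] == pytest.approx(6.0)
        assert global_mediation_effect(post, "sum_sq_products")["mean"] == pytest.approx(36.0)
        post.draws["alpha_a"][:] = 0.0
        assert global_mediation_effect(post, "sum_products")["mean"] == 0.0
        assert global_mediation_effect(post, "sum_sq_products")["mean"] == 0.0

    def test_sum_products_matches_two_stage_ols_when_identified(self):
        rng = np.random.default_rng(7)
        n = 2000
        a = rng.standard_normal(n)
        m = 0.7 * a + rng.standard_normal(n)
        y = 0.5 * m + 0.2 * a + rng.standard_normal(n)
        C = np.ones((n, 1))
        post = fit_bayes_mediation(
            a, m[:, None], y, C, iterations=3000, burnin=1000, seed=2
        )
        bayes_nie = global_mediation_effect(post, "sum_products")["mean"]
        freq = mediate_pair(a, m, plain_cohort(y))
        assert abs(bayes_nie - freq.nie) < 0.03


class TestCalibration:
    def test_signal_pathway_attains_top_pip(self):
        hits = 0
        n_seeds = 10  # acceptance suite runs the full 50-seed version
        for seed in range(n_seeds):
            a, M, y, C = _one_pathway(100 + seed, n=800, q=20)
            az = (a - a.mean()) / a.std()
            Mz = (M - M.mean(0)) / M.std(0)
            yz = (y - y.mean()) / y.std()
            post = fit_bayes_mediation(az, Mz, yz, C, iterations=800, burnin=300, seed=seed)
            hits += int(post.pip.argmax() == 0)
        assert hits >= n_seeds - 1

    def test_null_pips_stay_small(self):
        ok = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(200 + seed)
            n, q = 500, 20
            a = rng.standard_normal(n)
            M = rng.standard_normal((n, q))
            y = rng.standard_normal(n)
            post = fit_bayes_mediation(a, M, y, np.ones((n, 1)), iterations=800, burnin=300, seed=seed)
            ok += int(post.pip.max() < 0.5)
        assert ok >= n_seeds - 1


class TestGroupedRuns:
    def test_by_group_excludes_small_groups(self, default_draw):
        cohort, exposures, mediators, _ = default_draw
        panel = exposures.log_z().values.iloc[:, :1]  # one exposure for speed
        table, posts = run_shrinkage_over_exposures(
            panel, mediators, cohort, grouping="by_group",
            iterations=120, burnin=40, seed=0,
        )
        groups = set(table["group"])
        assert groups == {"cox", "cyp450", "lox", "parent", "inflam"}
        assert "oxstress" not in groups and "protein" not in groups
        assert len(table) == 5

    def test_grouping_all_is_single_joint_model(self, default_draw):
        cohort, exposures, mediators, _ = default_draw
        panel = exposures.log_z().values.iloc[:, :1]
        table, posts = run_shrinkage_over_exposures(
            panel, mediators, cohort, grouping="all",
            iterations=120, burnin=40, seed=0,
        )
        assert len(table) == 1
        assert table["q_g"].iloc[0] == 61
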