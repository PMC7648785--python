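"""Weighted regression engines, IPW, q-values, weighted descriptives."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from expomed.inference import (
    compute_ipw,
    fit_weighted_linear,
    fit_weighted_logistic,
    qvalues,
    storey_pi0,
    weighted_descriptives,
    weighted_quantile,
)

from conftest import plain_cohort


class TestIPW:
    @pytest.mark.parametrize(
        "cases,controls,n_case,n_ctrl,w_case,w_ctrl",
        [
            (100, 900, 50, 50, 2.0, 18.0),
            (130, 1470, 52, 109, 2.5, 1470 / 109),
        ],
    )
    def test_reciprocal_selection_probability(self, cases, controls, n_case, n_ctrl, w_case, w_ctrl):
        status = np.array(["case"] * n_case + ["control"] * n_ctrl)
        w = compute_ipw(status, cases, controls)
        assert np.allclose(w[:n_case], w_case)
        assert np.allclose(w[n_case:], w_ctrl)

    def test_full_sample_gives_unit_weights(self):
        status = np.array(["case"] * 10 + ["control"] * 30)
        assert np.allclose(compute_ipw(status, 10, 30), 1.0)

    def test_absent_stratum_rejected(self):
        with pytest.raises(ValueError, match="stratum"):
            compute_ipw(np.array(["case"] * 5), 10, 20)


class TestWeightedLinear:
    def test_exact_fit_has_zero_residual_variance(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(50), rng.standard_normal((50, 2))])
        b = np.array([1.0, 2.0, -3.0])
        fit = fit_weighted_linear(X @ b, X, rng.uniform(0.5, 2.0, 50))
        assert np.allclose(fit.coefficients, b)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-20)

    def test_duplicated_rows_equal_double_weight(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(40), rng.standard_normal(40)])
        y = X @ [1.0, 0.5] + rng.standard_normal(40)
        dup = fit_weighted_linear(np.r_[y, y], np.r_[X, X])
        weighted = fit_weighted_linear(y, X, np.full(40, 2.0))
        assert np.allclose(dup.coefficients, weighted.coefficients)

    def test_matches_statsmodels_wls_sandwich(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(300), rng.standard_normal((300, 3))])
        y = X @ [1, 2, -1, 0.5] + rng.standard_normal(300) * (1 + 0.5 * np.abs(X[:, 1]))
        w = rng.uniform(0.5, 4.0, 300)
        ours = fit_weighted_linear(y, X, w)
        ref = sm.WLS(y, X, weights=w).fit(cov_type="HC0")
        assert np.allclose(ours.coefficients, ref.params)
        assert np.allclose(ours.standard_errors, ref.bse)

    def test_monte_carlo_slope_recovery(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(10_000)
        y = 2.0 * x + rng.standard_normal(10_000)
        fit = fit_weighted_linear(y, np.column_stack([np.ones_like(x), x]))
        assert abs(fit.coefficients[1] - 2.0) < 3 * fit.standard_errors[1]

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(20), np.arange(20.0), 2 * np.arange(20.0)])
        with pytest.raises(ValueError, match="collinear"):
            fit_weighted_linear(np.zeros(20), X, names=["intercept", "a", "b"])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(100), rng.standard_normal(100)])
        y = X @ [1.0, 2.0] + rng.standard_normal(100)
        base = fit_weighted_linear(y, X)
        scaled = fit_weighted_linear(y, X * [1.0, 10.0])
        assert scaled.coefficients[1] == pytest.approx(base.coefficients[1] / 10.0)
        assert scaled.standard_errors[1] == pytest.approx(base.standard_errors[1] / 10.0)


class TestWeightedLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(25), np.zeros(75)]
        fit = fit_weighted_logistic(y, np.ones((100, 1)))
        assert fit.coefficients[0] == pytest.approx(np.log(1 / 3), abs=1e-8)

    def test_weighting_equals_duplication(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(200)
        y = (rng.random(200) < 1 / (1 + np.exp(-x))).astype(float)
        X = np.column_stack([np.ones(200), x])
        dup_idx = np.r_[np.arange(200), np.flatnonzero(y == 1)]
        dup = fit_weighted_logistic(y[dup_idx], X[dup_idx])
        w = np.where(y == 1, 2.0, 1.0)
        weighted = fit_weighted_logistic(y, X, w)
        assert np.allclose(dup.coefficients, weighted.coefficients, atol=1e-6)

    def test_monte_carlo_slope_recovery(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(20_000)
        y = (rng.random(20_000) < 1 / (1 + np.exp(-x))).astype(float)
        fit = fit_weighted_logistic(y, np.column_stack([np.ones_like(x), x]))
        assert abs(fit.coefficients[1] - 1.0) < 3 * fit.standard_errors[1]

    def test_perfect_separation_raises(self):
        x = np.r_[np.linspace(-2, -1, 30), np.linspace(1, 2, 30)]
        y = (x > 0).astype(float)
        with pytest.raises(ValueError):
            fit_weighted_logistic(y, np.column_stack([np.ones_like(x), x]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_weighted_logistic(np.ones(20), np.ones((20, 1)))


class TestQValues:
    def test_bh_step_up_example(self):
        assert np.allclose(qvalues(np.array([0.01, 0.02, 0.03]), "bh"), [0.03, 0.03, 0.03])

    def test_equal_pvalues_give_equal_qvalues(self):
        q = qvalues(np.full(7, 0.2), "bh")
        assert np.allclose(q, q[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qvalues(np.array([0.5, 1.2]))

    def test_storey_pi0_near_one_under_uniform_null(self):
        pi0s = [
            storey_pi0(np.random.default_rng(seed).uniform(size=1000)) for seed in range(100)
        ]
        assert abs(np.mean(pi0s) - 1.0) < 0.1

    def test_storey_never_exceeds_bh(self):
        rng = np.random.default_rng(12)
        p = np.concatenate([rng.uniform(size=400), rng.beta(0.2, 5.0, 100)])
        assert np.all(qvalues(p, "storey") <= qvalues(p, "bh") + 1e-12)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=40),
        st.sampled_from(["bh", "storey"]),
    )
    def test_monotone_in_p(self, pvals, method):
        p = np.asarray(pvals)
        q = qvalues(p, method)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestWeightedDescriptives:
    def test_equal_weights_reduce_to_plain_quantiles(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(1001)
        w = np.ones(1001)
        assert weighted_quantile(x, w, 0.5)[0] == pytest.approx(np.median(x), abs=1e-2)

    def test_dominant_weight_pulls_median(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 100.0])
        w = np.array([1.0, 1.0, 1.0, 1.0, 1e9])
        assert weighted_quantile(x, w, 0.5)[0] == pytest.approx(100.0, rel=1e-3)

    def test_ipw_recovers_cohort_prevalence(self, default_draw, full_cohort_draw):
        cohort = default_draw[0]
        full = full_cohort_draw[0]
        table = weighted_descriptives(cohort)
        row = table[(table.variable == "case_status") & (table.level == "case")]
        weighted_pct = float(row.value.iloc[0])
        cohort_pct = 100.0 * full.outcome_binary.mean()
        assert abs(weighted_pct - cohort_pct) < 1.0

    def test_percentages_sum_to_100(self, default_draw):
        table = weighted_descriptives(default_draw[0])
        pct = table[table.statistic == "weighted_pct"]
        for _, group in pct.groupby("variable"):
            assert group.value.sum() == pytest.approx(100.0, abs=0.1)
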