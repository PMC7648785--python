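"""Pairwise mediation: decomposition identities, SEs, and the screen."""

import numpy as np
import pandas as pd
import pytest

from expomed.pairwise import (
    MediationResult,
    _estimate,
    _sobel_se,
    mediate_pair,
    proportion_mediated,
    run_pairwise_screen,
)
from expomed.simulate import SimConfig, generate_cohort

from conftest import plain_cohort, single_pathway_config


def _toy_data(seed=0, n=400):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    m = 0.7 * a + rng.standard_normal(n)
    y = 0.5 * a + 0.6 * m + rng.standard_normal(n)
    return a, m, plain_cohort(y, weights=rng.uniform(0.5, 2.0, n))


class TestDecomposition:
    def test_te_equals_nde_plus_nie(self):
        a, m, cohort = _toy_data()
        res = mediate_pair(a, m, cohort)
        assert res.te == pytest.approx(res.beta_a + res.nie, abs=1e-10)
        assert res.nie == res.alpha_a * res.beta_m

    def test_product_method_equals_difference_method(self):
        # exact algebraic identity for nested WLS with identical weights
        a, m, cohort = _toy_data()
        covs, _ = cohort.covariate_design()
        est = _estimate(a, m, cohort.outcome_continuous, covs, cohort.ipw_weight, "continuous")
        assert est["nie"] == pytest.approx(est["te_difference"], abs=1e-8)

    def test_null_alpha_gives_null_nie(self):
        rng = np.random.default_rng(3)
        n = 5000
        a = rng.standard_normal(n)
        m = rng.standard_normal(n)  # independent of exposure
        y = 0.4 * a + 0.5 * m + rng.standard_normal(n)
        res = mediate_pair(a, m, plain_cohort(y))
        assert abs(res.nie) < 3 * res.se_nie

    def test_ci_brackets_point_estimate(self):
        a, m, cohort = _toy_data(4)
        for method in ("sobel", "bootstrap"):
            res = mediate_pair(a, m, cohort, se_method=method, n_boot=200)
            assert res.ci_low <= res.nie <= res.ci_high


class TestSobel:
    def test_sobel_arithmetic(self):
        assert _sobel_se(0.5, 0.4, 0.0, 0.0) == 0.0
        assert _sobel_se(0.5, 0.4, 0.1, 0.2) == pytest.approx(
            np.sqrt(0.25 * 0.04 + 0.16 * 0.01)
        )

    def test_bootstrap_and_sobel_agree_on_well_behaved_data(self):
        rng = np.random.default_rng(9)
        n = 1000
        a = rng.standard_normal(n)
        m = 0.6 * a + rng.standard_normal(n)
        y = 0.3 * a + 0.5 * m + rng.standard_normal(n)
        cohort = plain_cohort(y)
        sob = mediate_pair(a, m, cohort, se_method="sobel")
        boot = mediate_pair(a, m, cohort, se_method="bootstrap", n_boot=1000, seed=1)
        assert abs(boot.se_nie - sob.se_nie) / sob.se_nie < 0.15


class TestProportionMediated:
    @pytest.mark.parametrize("nie,te,expected", [(0.0, 1.0, 0.0), (0.7, 0.7, 1.0), (0.278, 1.07, 0.26)])
    def test_ratio(self, nie, te, expected):
        res = MediationResult(
            exposure_id="e", mediator_id="m", alpha_a=0, beta_m=0, beta_a=te - nie,
            nie=nie, te=te, prop_mediated=np.nan, se_nie=0, ci_low=0, ci_high=0,
            p_nie=1, p_te=1, p_nde=1,
        )
        out = proportion_mediated(res)
        assert out["value"] == pytest.approx(expected, abs=0.005)

    def test_zero_te_returns_flagged_sentinel(self):
        res = MediationResult(
            exposure_id="e", mediator_id="m", alpha_a=0, beta_m=0, beta_a=0,
            nie=0.1, te=0.0, prop_mediated=np.nan, se_nie=0, ci_low=0, ci_high=0,
            p_nie=1, p_te=1, p_nde=1,
        )
        out = proportion_mediated(res)
        assert np.isnan(out["value"])
        assert "prop_mediated_undefined_te_zero" in out["flags"]

    def test_inconsistent_mediation_flagged(self):
        res = MediationResult(
            exposure_id="e", mediator_id="m", alpha_a=0, beta_m=0, beta_a=-1.0,
            nie=0.3, te=-0.7, prop_mediated=np.nan, se_nie=0, ci_low=0, ci_high=0,
            p_nie=1, p_te=1, p_nde=1,
        )
        assert "inconsistent_mediation" in proportion_mediated(res)["flags"]


class TestScreen:
    def test_single_pair_screen(self):
        cfg = single_pathway_config(2, n=300)
        cohort, exposures, mediators, _ = generate_cohort(cfg, full_cohort=True)
        table = run_pairwise_screen(exposures.log(), mediators.log(), cohort)
        assert len(table) == 1
        assert table.status.iloc[0] == "ok"

    def test_screen_count_is_p_times_q(self):
        cfg = SimConfig(
            n_cohort=300, n_cases_sampled=5, n_controls_sampled=50,
            class_sizes={"phthalate": 3, "metal": 2}, group_sizes={"cox": 4, "inflam": 2},
            seed=6,
        )
        cohort, exposures, mediators, _ = generate_cohort(cfg)
        table = run_pairwise_screen(exposures.log(), mediators.log(), cohort)
        assert len(table) == 5 * 6
        assert (table.status == "ok").all()
        # deterministic ordering follows the panel partitions
        assert list(table.exposure_class[:6]) == ["phthalate"] * 6
        assert table.q_nie.notna().all()

    def test_zero_variance_mediator_becomes_flagged_row(self):
        cfg = single_pathway_config(3, n=200)
        cohort, exposures, mediators, _ = generate_cohort(cfg, full_cohort=True)
        bad = mediators.values.copy()
        bad.iloc[:, 0] = 1.0
        broken = type(mediators)(values=bad, group_map=mediators.group_map)
        table = run_pairwise_screen(exposures.log(), broken.log(), cohort)
        assert table.status.str.startswith("error").all()

    def test_binary_outcome_screen_flags_scale(self):
        cfg = SimConfig(
            n_cohort=600, n_cases_sampled=40, n_controls_sampled=100,
            class_sizes={"phthalate": 2}, group_sizes={"cox": 2}, seed=9,
        )
        cohort, exposures, mediators, _ = generate_cohort(cfg)
        table = run_pairwise_screen(exposures.log(), mediators.log(), cohort, outcome_kind="binary")
        assert (table.status == "ok").all()
        assert table["flags"].str.contains("log_odds_scale").all()


class TestRecovery:
    def test_active_pair_recovery_and_coverage(self):
        """Mean NIE within 5% of truth; Sobel CI coverage in [0.90, 0.98].

        Scaled-down version of the full recovery study (the acceptance
        suite runs 500 replicates).
        """
        nies, covered = [], []
        for seed in range(100):
            cfg = single_pathway_config(seed, n=1000)
            cohort, exposures, mediators, _ = generate_cohort(cfg, full_cohort=True)
            res = mediate_pair(
                np.log(exposures.matrix()[:, 0]), np.log(mediators.matrix()[:, 0]), cohort
            )
            nies.append(res.nie)
            covered.append(res.ci_low <= 1.0 <= res.ci_high)
        assert abs(np.mean(nies) - 1.0) < 0.05
        assert 0.88 <= np.mean(covered) <= 0.99
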