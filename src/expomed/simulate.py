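"""Synthetic cohort generator with known mediation ground truth.

Emulates a nested case-control pregnancy cohort: four classes of correlated
urinary/blood exposure analytes (phthalates, phenols, PAHs, metals), seven
groups of plasma biomarker mediators (eicosanoid enzymatic pathways, parent
lipids, inflammation, oxidative stress, protein damage), six covariates, a
continuous gestational-age outcome and preterm indicators, plus case-control
subsampling with recorded selection probabilities.

The structural model is linear on the log scale:

    log A   ~ block-correlated Gaussian (exchangeable correlation per class)
    log M   = alpha_matrix . log A + covariate effects + correlated noise
    Y       = intercept + beta_a . log A + beta_m . log M + cov effects + noise
    preterm = 1{Y < preterm_threshold}

Because log-exposures are drawn with unit variance, the log scale and the
log-standardized scale coincide in the full cohort and the ground-truth
natural indirect effect for pair (j, l) is exactly
``alpha_matrix[l, j] * beta_m[l]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CohortTable, ExposurePanel, MediatorPanel

DEFAULT_CLASS_SIZES = {"phthalate": 9, "phenol": 9, "pah": 8, "metal": 12}
DEFAULT_GROUP_SIZES = {
    "cox": 14,
    "cyp450": 18,
    "lox": 14,
    "parent": 5,
    "inflam": 5,
    "oxstress": 2,
    "protein": 3,
}

#: Fixed per-covariate effect pattern (scaled by ``SimConfig.covariate_effects``)
#: on the continuous outcome; mediators receive half of it. Columns follow the
#: dummy-coded design of :meth:`CohortTable.covariate_design` minus intercept.
_COVARIATE_PATTERN = {
    "age_z": -0.10,
    "specific_gravity": 0.05,
    "bmi_cat_25-29.9": -0.15,
    "bmi_cat_>=30": -0.25,
    "education_technical": 0.05,
    "education_some_college": 0.10,
    "education_college_grad": 0.15,
    "insurance_private": 0.10,
    "tobacco_use": -0.30,
}


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the analytic structure of the motivating study: a source
    cohort of 1600 with ~8-9% preterm prevalence, an analytic subset of 52
    cases and 109 controls, p = 38 analytes in 4 classes, q = 61 mediators in
    7 groups, and 6 covariates.
    """

    n_cohort: int = 1600
    n_cases_sampled: int = 52
    n_controls_sampled: int = 109
    class_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    within_class_rho: float = 0.6
    within_group_rho: float = 0.3
    alpha_matrix: np.ndarray | None = None  # q x p, exposure -> mediator
    beta_m: np.ndarray | None = None  # length q, mediator -> outcome
    beta_a: np.ndarray | None = None  # length p, direct exposure -> outcome
    covariate_effects: float = 0.3
    noise_sd_mediator: float = 1.0
    noise_sd_outcome: float = 1.2
    outcome_intercept: float = 39.0
    preterm_threshold: float = 37.0
    seed: int = 0

    @property
    def p(self) -> int:
        return sum(self.class_sizes.values())

    @property
    def q(self) -> int:
        return sum(self.group_sizes.values())

    def validate(self) -> None:
        if self.n_cases_sampled + self.n_controls_sampled > self.n_cohort:
            raise ValueError("analytic subset larger than the cohort")
        for name, rho in (("within_class_rho", self.within_class_rho), ("within_group_rho", self.within_group_rho)):
            if not 0.0 <= rho < 1.0:
                raise ValueError(f"{name} must lie in [0, 1); got {rho}")
        for label, sizes, rho in (
            ("class", self.class_sizes, self.within_class_rho),
            ("group", self.group_sizes, self.within_group_rho),
        ):
            for block, size in sizes.items():
                if size < 1:
                    raise ValueError(f"{label} {block!r} has non-positive size")
                # exchangeable correlation is PD iff rho > -1/(m-1); rho >= 0
                # always passes, but keep the named check for clarity
                if size > 1 and rho <= -1.0 / (size - 1):
                    raise ValueError(
                        f"correlation {rho} makes the {label} block {block!r} "
                        f"(size {size}) non-positive-definite"
                    )
        if self.noise_sd_mediator <= 0 or self.noise_sd_outcome <= 0:
            raise ValueError("noise SDs must be positive")

    def effects(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Resolve (alpha_matrix, beta_m, beta_a), filling in defaults.

        The default scenario routes a modest phthalate signal through the
        first four cytochrome-p450 mediators: alpha = 0.25 for the first
        three phthalates, beta_m = -0.15 on those mediators (lowering
        gestational age), and a small direct effect beta_a = -0.1.
        """
        p, q = self.p, self.q
        if self.alpha_matrix is not None:
            alpha = np.asarray(self.alpha_matrix, float)
            if alpha.shape != (q, p):
                raise ValueError(f"alpha_matrix must be q x p = {(q, p)}; got {alpha.shape}")
        else:
            alpha = np.zeros((q, p))
        if self.beta_m is not None:
            beta_m = np.asarray(self.beta_m, float)
        else:
            beta_m = np.zeros(q)
        if self.beta_a is not None:
            beta_a = np.asarray(self.beta_a, float)
        else:
            beta_a = np.zeros(p)
        if self.alpha_matrix is None and self.beta_m is None and self.beta_a is None:
            med_names = _feature_names(self.group_sizes, "med")
            exp_names = _feature_names(self.class_sizes, "exp")
            cyp = [i for i, n in enumerate(med_names) if n.startswith("med_cyp450")][:4]
            phth = [i for i, n in enumerate(exp_names) if n.startswith("exp_phthalate")][:3]
            for l in cyp:
                for j in phth:
                    alpha[l, j] = 0.25
                beta_m[l] = -0.15
            for j in phth:
                beta_a[j] = -0.1
        if len(beta_m) != q or len(beta_a) != p:
            raise ValueError("beta_m / beta_a lengths must match q / p")
        return alpha, beta_m, beta_a


@dataclass
class SimTruth:
    """Ground-truth effects on the log-standardized analysis scale.

    ``true_nie[l, j] = alpha[l, j] * beta_m[l]``; the total effect of exposure
    j pools the direct path and every mediator path, and the pair-level
    direct effect is the remainder, so ``te = nde + nie`` holds for every
    pair by construction.
    """

    true_nie: np.ndarray  # q x p
    true_nde: np.ndarray  # q x p
    true_te: np.ndarray  # length p (shared by all pairs of an exposure)
    active_pairs: list[tuple[str, str]]
    exposure_names: list[str]
    mediator_names: list[str]


def _feature_names(sizes: dict[str, int], prefix: str) -> list[str]:
    return [f"{prefix}_{block}_{i + 1}" for block, m in sizes.items() for i in range(m)]


def _block_normal(rng: np.random.Generator, n: int, sizes: dict[str, int], rho: float) -> np.ndarray:
    """Draw n x total Gaussians with exchangeable correlation rho per block.

    Uses the one-factor construction sqrt(rho)*shared + sqrt(1-rho)*own, which
    is exact for exchangeable correlation and never needs a Cholesky.
    """
    cols = []
    for _block, m in sizes.items():
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, m))
        cols.append(np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own)
    return np.concatenate(cols, axis=1)


def _covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    bmi_levels = np.array(["<25", "25-29.9", ">=30"])
    edu_levels = np.array(["high_school", "technical", "some_college", "college_grad"])
    frame = pd.DataFrame(
        {
            "age_z": rng.standard_normal(n),
            "specific_gravity": rng.normal(1.015, 0.005, n),
            "bmi_cat": pd.Categorical(
                bmi_levels[rng.choice(3, n, p=[0.52, 0.29, 0.19])], categories=bmi_levels
            ),
            "education": pd.Categorical(
                edu_levels[rng.choice(4, n, p=[0.115, 0.093, 0.346, 0.446])],
                categories=edu_levels,
            ),
            "insurance_private": rng.binomial(1, 0.91, n),
            "tobacco_use": rng.binomial(1, 0.054, n),
        }
    )
    return frame


def _covariate_effect_vector(names: list[str], scale: float) -> np.ndarray:
    return np.array([_COVARIATE_PATTERN.get(n, 0.0) for n in names]) * scale


def generate_cohort(
    config: SimConfig, full_cohort: bool = False
) -> tuple[CohortTable, ExposurePanel, MediatorPanel, SimTruth]:
    """Simulate the full cohort, then draw the nested case-control subset.

    Returns the analytic subset by default (with IPW weights reflecting the
    case-control sampling); pass ``full_cohort=True`` to keep every subject
    (all weights 1).  Identical config and seed give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cohort
    exp_names = _feature_names(config.class_sizes, "exp")
    med_names = _feature_names(config.group_sizes, "med")
    alpha, beta_m, beta_a = config.effects()

    log_a = _block_normal(rng, n, config.class_sizes, config.within_class_rho)
    covars = _covariates(rng, n)

    # dummy design (no intercept column) shared by mediator and outcome models
    dummies = pd.get_dummies(covars, drop_first=True, dtype=float)
    cov_design = dummies.to_numpy(float)
    cov_eff = _covariate_effect_vector(list(dummies.columns), config.covariate_effects)

    med_noise = config.noise_sd_mediator * _block_normal(
        rng, n, config.group_sizes, config.within_group_rho
    )
    log_m = log_a @ alpha.T + np.outer(cov_design @ cov_eff, np.full(len(med_names), 0.5)) + med_noise

    y = (
        config.outcome_intercept
        + log_a @ beta_a
        + log_m @ beta_m
        + cov_design @ cov_eff
        + config.noise_sd_outcome * rng.standard_normal(n)
    )
    preterm = (y < config.preterm_threshold).astype(int)
    # spontaneous preterm: a random ~60% subset of cases, mirroring 30 of 52
    spontaneous = preterm * rng.binomial(1, 0.6, n)

    case_idx = np.flatnonzero(preterm == 1)
    control_idx = np.flatnonzero(preterm == 0)
    if len(case_idx) == 0:
        raise ValueError("simulated cohort contains no preterm cases")

    if full_cohort:
        selected = np.arange(n)
        weights = np.ones(n)
    else:
        n_cases = min(config.n_cases_sampled, len(case_idx))
        n_controls = min(config.n_controls_sampled, len(control_idx))
        sel_cases = rng.choice(case_idx, n_cases, replace=False)
        sel_controls = rng.choice(control_idx, n_controls, replace=False)
        selected = np.sort(np.concatenate([sel_cases, sel_controls]))
        p_case = n_cases / len(case_idx)
        p_control = n_controls / len(control_idx)
        weights = np.where(preterm[selected] == 1, 1.0 / p_case, 1.0 / p_control)

    status = np.where(preterm[selected] == 1, "case", "control")
    cohort = CohortTable(
        subject_id=selected,
        covariates=covars.iloc[selected].reset_index(drop=True),
        outcome_continuous=y[selected],
        outcome_binary=preterm[selected],
        outcome_binary_spontaneous=spontaneous[selected],
        case_status=status,
        ipw_weight=weights,
    )
    exposures = ExposurePanel(
        values=pd.DataFrame(np.exp(log_a[selected]), columns=exp_names),
        class_map={name: name.split("_")[1] for name in exp_names},
    )
    mediators = MediatorPanel(
        values=pd.DataFrame(np.exp(log_m[selected]), columns=med_names),
        group_map={name: name.split("_")[1] for name in med_names},
    )

    true_nie = alpha * beta_m[:, None]
    true_te = beta_a + alpha.T @ beta_m
    true_nde = true_te[None, :] - true_nie
    active = [
        (exp_names[j], med_names[l])
        for l in range(config.q)
        for j in range(config.p)
        if true_nie[l, j] != 0.0
    ]
    truth = SimTruth(
        true_nie=true_nie,
        true_nde=true_nde,
        true_te=true_te,
        active_pairs=active,
        exposure_names=exp_names,
        mediator_names=med_names,
    )
    return cohort, exposures, mediators, truth


def selection_probabilities(
    n_cohort_cases: int, n_cohort_controls: int, n_cases_sampled: int, n_controls_sampled: int
) -> dict[str, float]:
    """Per-stratum probability that a cohort subject enters the subset."""
    if n_cohort_cases <= 0:
        raise ValueError("cohort contains no cases")
    if n_cohort_controls <= 0:
        raise ValueError("cohort contains no controls")
    if n_cases_sampled > n_cohort_cases or n_controls_sampled > n_cohort_controls:
        raise ValueError("sampled counts exceed cohort stratum counts")
    if n_cases_sampled <= 0 or n_controls_sampled <= 0:
        raise ValueError("both sampled strata must be non-empty")
    return {
        "case": n_cases_sampled / n_cohort_cases,
        "control": n_controls_sampled / n_cohort_controls,
    }
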