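"""Core data containers: cohort spine, exposure and mediator panels.

Conventions: subjects in rows, features in columns. Raw analyte and biomarker
values are strictly positive; analyses run on log (optionally z-scored)
values, and each panel records its transform state so a stage can assert it
received the scale it expects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

EXPOSURE_CLASSES = ("phthalate", "phenol", "pah", "metal")
MEDIATOR_GROUPS = ("cox", "cyp450", "lox", "parent", "inflam", "oxstress", "protein")


@dataclass
class CohortTable:
    """Subject-level spine: covariates, outcomes, case status, IPW weights.

    ``covariates`` holds the raw (undummied) covariate columns; use
    :meth:`covariate_design` for a regression-ready design matrix with an
    intercept and first-level-reference dummy coding.
    """

    subject_id: np.ndarray
    covariates: pd.DataFrame
    outcome_continuous: np.ndarray  # gestational age at delivery, weeks
    outcome_binary: np.ndarray  # overall preterm (1 = case)
    outcome_binary_spontaneous: np.ndarray
    case_status: np.ndarray  # "case" / "control"
    ipw_weight: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.ipw_weight <= 0):
            raise ValueError("ipw_weight must be strictly positive")
        if self.covariates.isna().any().any():
            raise ValueError("covariates contain missing values")
        is_case = self.case_status == "case"
        if not np.array_equal(is_case.astype(int), self.outcome_binary.astype(int)):
            raise ValueError("outcome_binary must equal (case_status == 'case')")

    @property
    def n(self) -> int:
        return len(self.subject_id)

    def covariate_design(self) -> tuple[np.ndarray, list[str]]:
        """Intercept + dummy-coded covariates (first level is the reference).

        Dummy columns for levels unobserved in this sample (zero variance)
        are dropped — they are inestimable and would only make the design
        singular.
        """
        dummied = pd.get_dummies(self.covariates, drop_first=True, dtype=float)
        keep = [c for c in dummied.columns if dummied[c].nunique() > 1]
        names = ["intercept"] + keep
        design = np.column_stack([np.ones(self.n), dummied[keep].to_numpy(float)])
        return design, names

    def outcome(self, kind: str) -> np.ndarray:
        if kind in ("continuous", "gestage"):
            return np.asarray(self.outcome_continuous, float)
        if kind in ("binary", "preterm"):
            return np.asarray(self.outcome_binary, float)
        if kind in ("binary_spontaneous", "spontaneous"):
            return np.asarray(self.outcome_binary_spontaneous, float)
        raise ValueError(f"unknown outcome kind: {kind!r}")


def _check_panel(values: pd.DataFrame, mapping: dict[str, str], labels: tuple[str, ...]) -> None:
    if set(mapping) != set(values.columns):
        raise ValueError("feature map must cover exactly the panel columns")
    unknown = set(mapping.values()) - set(labels)
    if unknown:
        raise ValueError(f"unknown labels in feature map: {sorted(unknown)}")


@dataclass
class _Panel:
    values: pd.DataFrame
    transform_state: str = "raw"  # raw | log | log-z

    def __post_init__(self) -> None:
        if self.transform_state == "raw" and (self.values.to_numpy(float) <= 0).any():
            raise ValueError("raw panel values must be strictly positive (log must be defined)")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(float)

    def log(self):
        """Return a log-transformed copy (idempotent beyond ``raw``)."""
        if self.transform_state != "raw":
            return self
        return replace(self, values=np.log(self.values), transform_state="log")

    def log_z(self):
        """Log then z-score each column (mean 0, sd 1)."""
        logged = self.log()
        vals = logged.values
        z = (vals - vals.mean()) / vals.std(ddof=0)
        return replace(self, values=z, transform_state="log-z")


@dataclass
class ExposurePanel(_Panel):
    """Analyte matrix A with a partition of columns into exposure classes."""

    class_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        _check_panel(self.values, self.class_map, EXPOSURE_CLASSES)

    def classes(self) -> list[str]:
        seen: list[str] = []
        for col in self.columns:
            if self.class_map[col] not in seen:
                seen.append(self.class_map[col])
        return seen

    def columns_of(self, class_k: str) -> list[str]:
        return [c for c in self.columns if self.class_map[c] == class_k]


@dataclass
class MediatorPanel(_Panel):
    """Biomarker matrix M with a partition of columns into biological groups."""

    group_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        _check_panel(self.values, self.group_map, MEDIATOR_GROUPS)

    def groups(self) -> list[str]:
        seen: list[str] = []
        for col in self.columns:
            if self.group_map[col] not in seen:
                seen.append(self.group_map[col])
        return seen

    def columns_of(self, group_g: str) -> list[str]:
        return [c for c in self.columns if self.group_map[c] == group_g]


def write_cohort_csv(
    path: str,
    manifest_path: str,
    cohort: CohortTable,
    exposures: ExposurePanel,
    mediators: MediatorPanel,
) -> None:
    """Write one wide CSV plus a YAML manifest mapping columns to roles."""
    frame = pd.concat(
        [
            pd.DataFrame({"subject_id": cohort.subject_id}),
            cohort.covariates.reset_index(drop=True),
            pd.DataFrame(
                {
                    "gestational_age": cohort.outcome_continuous,
                    "preterm": cohort.outcome_binary,
                    "spontaneous_preterm": cohort.outcome_binary_spontaneous,
                    "case_status": cohort.case_status,
                    "ipw_weight": cohort.ipw_weight,
                }
            ),
            exposures.values.reset_index(drop=True),
            mediators.values.reset_index(drop=True),
        ],
        axis=1,
    )
    frame.to_csv(path, index=False)
    manifest = {
        "covariates": list(cohort.covariates.columns),
        "outcomes": {
            "continuous": "gestational_age",
            "binary": "preterm",
            "binary_spontaneous": "spontaneous_preterm",
        },
        "selection": {"case_status": "case_status", "ipw_weight": "ipw_weight"},
        "exposures": {col: exposures.class_map[col] for col in exposures.columns},
        "mediators": {col: mediators.group_map[col] for col in mediators.columns},
        "transform_state": {
            "exposures": exposures.transform_state,
            "mediators": mediators.transform_state,
        },
    }
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_cohort_csv(path: str, manifest_path: str) -> tuple[CohortTable, ExposurePanel, MediatorPanel]:
    """Inverse of :func:`write_cohort_csv`."""
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh) if manifest_path.endswith((".yml", ".yaml")) else json.load(fh)
    frame = pd.read_csv(path)
    cohort = CohortTable(
        subject_id=frame["subject_id"].to_numpy(),
        covariates=frame[manifest["covariates"]].copy(),
        outcome_continuous=frame[manifest["outcomes"]["continuous"]].to_numpy(float),
        outcome_binary=frame[manifest["outcomes"]["binary"]].to_numpy(int),
        outcome_binary_spontaneous=frame[manifest["outcomes"]["binary_spontaneous"]].to_numpy(int),
        case_status=frame[manifest["selection"]["case_status"]].to_numpy(str),
        ipw_weight=frame[manifest["selection"]["ipw_weight"]].to_numpy(float),
    )
    exposures = ExposurePanel(
        values=frame[list(manifest["exposures"])].copy(),
        transform_state=manifest["transform_state"]["exposures"],
        class_map=dict(manifest["exposures"]),
    )
    mediators = MediatorPanel(
        values=frame[list(manifest["mediators"])].copy(),
        transform_state=manifest["transform_state"]["mediators"],
        group_map=dict(manifest["mediators"]),
    )
    return cohort, exposures, mediators
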