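"""Framework orchestration: run stages in dependency order from one config.

Stage order: simulate (or load) -> pairwise -> ers -> ers_pairwise ->
bayes -> groups -> select -> sensitivity -> report. Every artifact lands in
a run directory with a manifest (config, seeds, versions) that allows exact
re-execution; a stage failure halts its dependents while independent stages
continue.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import run_shrinkage_over_exposures
from .data import read_cohort_csv, write_cohort_csv
from .groups import run_group_mediation
from .pairwise import run_pairwise_screen
from .penalized import mcp_joint_significance, pathway_lasso_fit
from .risk_scores import build_risk_scores, ers_mediation_screen
from .sensitivity import covariate_combination_scan, evalue_continuous, rho_sensitivity
from .simulate import SimConfig, generate_cohort

ALL_STAGES = (
    "simulate",
    "pairwise",
    "ers",
    "ers_pairwise",
    "bayes",
    "groups",
    "select",
    "sensitivity",
    "report",
)

STAGE_DEPS = {
    "pairwise": ("simulate",),
    "ers": ("simulate",),
    "ers_pairwise": ("simulate", "ers"),
    "bayes": ("simulate", "ers"),
    "groups": ("simulate", "ers"),
    "select": ("simulate", "ers"),
    "sensitivity": ("simulate", "ers", "groups"),
    "report": (),
}


@dataclass
class RunConfig:
    stages: tuple[str, ...] = ("simulate", "pairwise")
    sim: SimConfig = field(default_factory=SimConfig)
    input_csv: str | None = None  # load instead of simulating
    input_manifest: str | None = None
    outcome: str = "continuous"
    seed: int = 0
    ers_folds: int = 5
    bayes_iterations: int = 2000
    bayes_burnin: int = 1000
    bayes_grouping: str = "by_group"
    se_method: str = "sobel"
    out_dir: str = "runs"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        cfg.sim = SimConfig(**sim_raw)
        if "stages" in raw:
            cfg.stages = tuple(raw["stages"])
        return cfg

    def to_manifest(self) -> dict:
        sim = dataclasses.asdict(self.sim)
        for key, val in sim.items():
            if isinstance(val, np.ndarray):
                sim[key] = val.tolist()
        return {
            "stages": list(self.stages),
            "sim": sim,
            "input_csv": self.input_csv,
            "input_manifest": self.input_manifest,
            "outcome": self.outcome,
            "seed": self.seed,
            "ers_folds": self.ers_folds,
            "bayes_iterations": self.bayes_iterations,
            "bayes_burnin": self.bayes_burnin,
            "bayes_grouping": self.bayes_grouping,
            "se_method": self.se_method,
            "version": __version__,
        }


def _config_hash(manifest: dict) -> str:
    return hashlib.sha256(json.dumps(manifest, sort_keys=True).encode()).hexdigest()[:12]


def _stamp(table: pd.DataFrame, stage: str, seed: int, cfg_hash: str) -> pd.DataFrame:
    table = table.copy()
    table["stage"] = stage
    table["seed"] = seed
    table["config_hash"] = cfg_hash
    return table


def run_framework(config: RunConfig, run_name: str | None = None) -> Path:
    """Execute the requested stages; returns the run directory."""
    manifest = config.to_manifest()
    cfg_hash = _config_hash(manifest)
    name = run_name if run_name is not None else f"run_{cfg_hash}"
    run_dir = Path(config.out_dir) / name
    run_dir.mkdir(parents=True, exist_ok=True)
    with open(run_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    log_path = run_dir / "run.log"
    statuses: dict[str, str] = {}

    def log(msg: str) -> None:
        with open(log_path, "a") as fh:
            fh.write(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} {msg}\n")

    def ready(stage: str) -> bool:
        return all(statuses.get(dep) == "ok" for dep in STAGE_DEPS.get(stage, ()))

    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        if not ready(stage):
            statuses[stage] = "skipped: failed dependency"
            log(f"{stage} skipped (dependency failed)")
            continue
        t0 = time.time()
        try:
            _run_stage(stage, config, state, run_dir, cfg_hash)
            statuses[stage] = "ok"
        except Exception as exc:  # pragma: no cover - defensive
            statuses[stage] = f"error: {exc}"
        log(f"{stage} {statuses[stage]} ({time.time() - t0:.2f}s)")

    with open(run_dir / "status.json", "w") as fh:
        json.dump(statuses, fh, indent=2)
    if any(s != "ok" for s in statuses.values()):
        raise RuntimeError(f"stage failures in {run_dir}: {statuses}")
    return run_dir


def _run_stage(stage: str, config: RunConfig, state: dict, run_dir: Path, cfg_hash: str) -> None:
    seed = config.seed
    if stage == "simulate":
        if config.input_csv is not None:
            cohort, exposures, mediators = read_cohort_csv(config.input_csv, config.input_manifest)
            truth = None
        else:
            sim = dataclasses.replace(config.sim, seed=config.sim.seed or seed)
            cohort, exposures, mediators, truth = generate_cohort(sim)
        state.update(cohort=cohort, exposures=exposures, mediators=mediators, truth=truth)
        write_cohort_csv(
            str(run_dir / "cohort.csv"), str(run_dir / "cohort_manifest.yaml"),
            cohort, exposures, mediators,
        )
    elif stage == "pairwise":
        table = run_pairwise_screen(
            state["exposures"].log(), state["mediators"].log(), state["cohort"],
            outcome_kind=config.outcome, se_method=config.se_method,
        )
        state["pairwise"] = table
        _stamp(table, stage, seed, cfg_hash).to_csv(run_dir / "pairwise.csv", index=False)
    elif stage == "ers":
        ers_panel, models = build_risk_scores(
            state["exposures"], state["cohort"], folds=config.ers_folds, seed=seed,
        )
        # degenerate (all-zero-weight) classes yield constant scores that no
        # downstream stage can use as an exposure; keep the model JSON but
        # drop the score from the working panel
        active = [c for c in ers_panel.columns if not models[c.removeprefix("ers_")].degenerate]
        state["ers_panel"] = ers_panel[active]
        state["ers_models"] = models
        ers_panel.to_csv(run_dir / "ers_scores.csv", index=False)
        for k, model in models.items():
            payload = {
                "class": k,
                "features": model.feature_names,
                "gamma": model.gamma_k.tolist(),
                "lambda1": model.lambda1,
                "lambda2": model.lambda2,
                "cv_folds": model.cv_folds,
                "seed": seed,
                "degenerate": model.degenerate,
            }
            with open(run_dir / f"ers_model_{k}.json", "w") as fh:
                json.dump(payload, fh, indent=2)
    elif stage == "ers_pairwise":
        table = ers_mediation_screen(
            state["ers_panel"], state["mediators"], state["cohort"], se_method=config.se_method
        )
        state["ers_pairwise"] = table
        _stamp(table, stage, seed, cfg_hash).to_csv(run_dir / "ers_pairwise.csv", index=False)
    elif stage == "bayes":
        table, posts = run_shrinkage_over_exposures(
            state["ers_panel"], state["mediators"], state["cohort"],
            grouping=config.bayes_grouping,
            iterations=config.bayes_iterations, burnin=config.bayes_burnin, seed=seed,
        )
        state["bayes"] = table
        _stamp(table, stage, seed, cfg_hash).to_csv(run_dir / "bayes.csv", index=False)
    elif stage == "groups":
        table, directions = run_group_mediation(
            state["ers_panel"], state["mediators"], state["cohort"], seed=seed
        )
        state["groups"] = table
        state["directions"] = directions
        _stamp(table, stage, seed, cfg_hash).to_csv(run_dir / "groups.csv", index=False)
        payload = [
            {"exposure": e, "group": g, "loadings": d.w_g.tolist(),
             "objective": d.objective_value, "status": d.status}
            for (e, g), d in directions.items()
        ]
        with open(run_dir / "directions.json", "w") as fh:
            json.dump(payload, fh, indent=2)
    elif stage == "select":
        med_z = state["mediators"].log_z()
        y = state["cohort"].outcome("continuous")
        y_std = (y - y.mean()) / y.std(ddof=0)
        covs, _ = state["cohort"].covariate_design()
        w = state["cohort"].ipw_weight
        frames = []
        for score_name in state["ers_panel"].columns:
            a = state["ers_panel"][score_name].to_numpy(float)
            _, chosen = pathway_lasso_fit(
                a, med_z.matrix(), y_std, covs, weights=w, seed=seed,
                exposure_id=score_name, mediator_names=med_z.columns,
            )
            frames.append(pd.DataFrame({
                "method": "pathway_lasso", "exposure": score_name,
                "mediator": chosen.selected or ["<none>"],
            }))
            js = mcp_joint_significance(
                a, med_z.matrix(), y_std, covs, weights=w,
                exposure_id=score_name, mediator_names=med_z.columns,
            )
            js.insert(0, "exposure", score_name)
            js.insert(0, "method", "mcp_joint")
            frames.append(js)
        table = pd.concat(frames, ignore_index=True)
        state["select"] = table
        _stamp(table, stage, seed, cfg_hash).to_csv(run_dir / "selection.csv", index=False)
    elif stage == "sensitivity":
        # final-model sensitivity: phthalate ERS through the all-mediators MGE
        directions = state["directions"]
        score_name = state["ers_panel"].columns[0]
        for cand in state["ers_panel"].columns:
            if "phthalate" in cand:
                score_name = cand
        direction = directions[(score_name, "all")]
        a = state["ers_panel"][score_name].to_numpy(float)
        mge = direction.mge
        mge_std = (mge - mge.mean()) / mge.std(ddof=0)
        profile = rho_sensitivity(a, mge_std, state["cohort"])
        y = state["cohort"].outcome("continuous")
        y_std = (y - y.mean()) / y.std(ddof=0)
        covs, _ = state["cohort"].covariate_design()
        from .inference import fit_weighted_linear

        fit = fit_weighted_linear(
            y_std, np.column_stack([a, covs]), state["cohort"].ipw_weight
        )
        ev, ev_ci = evalue_continuous(float(fit.coefficients[0]), float(fit.standard_errors[0]))
        cov_blocks = _conceptual_blocks(state["cohort"])
        scan = covariate_combination_scan(a, mge_std, y, cov_blocks, state["cohort"].ipw_weight)
        out = {
            "model": f"{score_name} via mge_all",
            "nie_point": profile.nie_point,
            "rho_zero": profile.rho_zero,
            "r2_product_zero": profile.r2_product_zero,
            "evalue": ev,
            "evalue_ci_bound": ev_ci,
            "covariate_subsets": int(len(scan)),
            "sign_stability": scan.attrs.get("sign_stability"),
        }
        state["sensitivity"] = out
        with open(run_dir / "sensitivity.json", "w") as fh:
            json.dump(out, fh, indent=2)
        pd.DataFrame({"rho": profile.rho_grid, "nie": profile.nie_at_rho}).to_csv(
            run_dir / "sensitivity_rho.csv", index=False
        )
        _stamp(scan, stage, seed, cfg_hash).to_csv(run_dir / "sensitivity_scan.csv", index=False)
    elif stage == "report":
        render_report(run_dir)
    else:  # pragma: no cover
        raise ValueError(f"unknown stage {stage!r}")


def _conceptual_blocks(cohort) -> dict[str, np.ndarray]:
    """Each conceptual covariate's dummy block (categoricals stay together)."""
    blocks: dict[str, np.ndarray] = {}
    for col in cohort.covariates.columns:
        series = cohort.covariates[col]
        if isinstance(series.dtype, pd.CategoricalDtype) or series.dtype == object:
            dummies = pd.get_dummies(series, drop_first=True, dtype=float)
            blocks[col] = dummies.to_numpy(float)
        else:
            blocks[col] = series.to_numpy(float).reshape(-1, 1)
    return blocks


def render_report(run_dir: Path | str) -> dict[str, Path]:
    """Chart-ready tables per stage: -log10(p) tables for the screens and a
    forest (TE/NDE/NIE) table for the group-effect analysis."""
    run_dir = Path(run_dir)
    outputs: dict[str, Path] = {}
    pairwise_path = run_dir / "pairwise.csv"
    if pairwise_path.exists():
        table = pd.read_csv(pairwise_path)
        ok = table[table["status"] == "ok"].copy()
        ok["neglog10_p_nie"] = -np.log10(np.clip(ok["p_nie"], 1e-300, 1.0))
        cols = ["exposure", "exposure_class", "mediator", "mediator_group", "nie", "neglog10_p_nie"]
        out = run_dir / "report_pairwise_neglog10p.csv"
        ok[cols].to_csv(out, index=False)
        outputs["pairwise_neglog10p"] = out
    groups_path = run_dir / "groups.csv"
    if groups_path.exists():
        table = pd.read_csv(groups_path)
        ok = table[table["status"] == "ok"].copy()
        rows = []
        for _, r in ok.iterrows():
            for effect in ("te", "nde", "nie"):
                rows.append(
                    {
                        "exposure": r["exposure"],
                        "group": r["group"],
                        "effect": effect.upper(),
                        "estimate": r[effect],
                        "ci_low": r["ci_low"] if effect == "nie" else np.nan,
                        "ci_high": r["ci_high"] if effect == "nie" else np.nan,
                    }
                )
        out = run_dir / "report_groups_forest.csv"
        pd.DataFrame(rows).to_csv(out, index=False)
        outputs["groups_forest"] = out
    if not outputs:
        with open(run_dir / "report_status.txt", "w") as fh:
            fh.write("nothing to report: no stage outputs found\n")
    return outputs
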