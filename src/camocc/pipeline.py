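"""End-to-end analysis pipeline driven by a single YAML configuration.

Stages: load or simulate data -> build the detection matrix -> standardize
and prune covariates -> enumerate and fit all candidate models -> rank,
confidence set and model averaging -> goodness of fit, overdispersion and
cross-validation on the best model -> cumulative-detection (p*) survey
design curves.  The pipeline is a pure function of (inputs, config,
seeds): rerunning with identical configuration reproduces byte-identical
JSON/CSV reports.  Progress is logged with timestamps to ``run.log``
only, so report files stay deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import assessment, design as design_mod, selection
from .covariates import CollinearityPruner, CovariateStandardizer
from .detection import (
    build_matrix,
    independent_detections,
    naive_detection_rate,
    naive_occupancy,
    read_deployments,
    read_photos,
)
from .simulate import SimulationDesign, simulate, tapir_scenario

__all__ = ["RunConfig", "RunReport", "validate", "run"]


@dataclass
class RunConfig:
    """Configuration of one study-area analysis run.

    Exactly one data source is used: CSV inputs (``photos``,
    ``deployments``, ``covariates``) or a simulation (``scenario`` name or
    explicit design fields under ``simulation``).
    """

    photos: str | None = None
    deployments: str | None = None
    covariates: str | None = None
    scenario: str | None = None
    simulation: dict | None = None
    seed: int | None = None

    occasion_length: int = 4
    target_species: str | None = None
    corr_threshold: float = 0.7
    priority: list | None = None
    psi_candidates: list | None = None
    p_candidates: list | None = None
    max_terms: int | None = None
    model_budget: int = 20_000
    delta_threshold: float = 2.0
    averaging: str = "shrinkage"

    gof_B: int = 500
    gof_seed: int | None = None
    cv_k: int = 5
    cv_seed: int | None = None
    cv_prediction: str = "unconditional"

    design_baselines: list = field(default_factory=lambda: [0.2, 0.4, 0.6, 0.8])
    design_target: float = 0.95

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    """Key outputs of a pipeline run plus paths of the emitted reports."""

    outdir: Path
    summary: dict
    model_table: "selection.ModelSet"
    confidence: "selection.ModelSet"
    averaged: dict
    assessment: dict
    issues: list = field(default_factory=list)


def validate(config: RunConfig) -> list:
    """Schema and cross-field checks; returns a list of issue strings."""
    issues = []
    simulated = config.scenario is not None or config.simulation is not None
    files = [config.photos, config.deployments, config.covariates]
    if simulated and any(files):
        issues.append("config mixes simulation with CSV inputs; choose one source")
    if not simulated:
        for name, p in zip(("photos", "deployments", "covariates"), files):
            if p is None:
                issues.append(f"missing required input path: {name}")
            elif not Path(p).exists():
                issues.append(f"{name} file does not exist: {p}")
    if config.scenario is not None and config.scenario != "tapir":
        issues.append(f"unknown scenario {config.scenario!r} (available: 'tapir')")
    if config.occasion_length < 1:
        issues.append("occasion_length must be >= 1")
    if not 0 < config.corr_threshold <= 1:
        issues.append("corr_threshold must be in (0, 1]")
    if config.delta_threshold <= 0:
        issues.append("delta_threshold must be positive")
    if simulated and config.seed is None:
        issues.append("simulation requested without a seed")
    if config.gof_B >= 1 and config.gof_seed is None:
        issues.append("goodness-of-fit stage enabled without gof_seed")
    if config.cv_k >= 2 and config.cv_seed is None:
        issues.append("cross-validation stage enabled without cv_seed")

    cov_cols = _covariate_columns(config)
    if cov_cols is not None:
        n_sites = cov_cols.pop("__n_sites__")
        names = set(cov_cols["names"])
        for part, cands in (("psi", config.psi_candidates), ("p", config.p_candidates)):
            for c in cands or []:
                if c not in names:
                    issues.append(f"unknown covariate in {part}_candidates: {c!r}")
        n_psi = len(config.psi_candidates or cov_cols["names"])
        n_p = len(config.p_candidates or cov_cols["names"])
        k_max = n_psi + n_p + 2
        if n_sites <= k_max + 1:
            issues.append(
                f"largest model has K={k_max} but only {n_sites} sites; "
                f"AICc requires n > K + 1"
            )
    return issues


def _covariate_columns(config: RunConfig):
    """Covariate names and site count for validation, or None if unavailable."""
    if config.scenario == "tapir":
        d = tapir_scenario(config.seed)
        return {"names": list(d.covariates), "__n_sites__": d.n_sites}
    if config.simulation is not None:
        try:
            d = SimulationDesign(**config.simulation)
        except TypeError:
            return None
        return {"names": list(d.covariates), "__n_sites__": d.n_sites}
    if config.covariates and Path(config.covariates).exists():
        import pandas as pd

        head = pd.read_csv(config.covariates)
        return {"names": [c for c in head.columns if c != "site_id"],
                "__n_sites__": len(head)}
    return None


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")


class _Logger:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def __call__(self, stage: str, msg: str) -> None:
        stamp = time.strftime("%Y-%m-%d %H:%M:%S")
        with self.path.open("a") as fh:
            fh.write(f"{stamp} [{stage}] {msg}\n")


def run(config: RunConfig, outdir) -> RunReport:
    """Execute the full pipeline and write reports into ``outdir``."""
    issues = validate(config)
    if issues:
        raise ValueError("invalid configuration:\n- " + "\n- ".join(issues))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _Logger(outdir / "run.log")
    t0 = time.perf_counter()

    # --- data -------------------------------------------------------------
    import pandas as pd

    if config.scenario == "tapir" or config.simulation is not None:
        sim_design = (
            tapir_scenario(config.seed)
            if config.scenario == "tapir"
            else SimulationDesign(**{**config.simulation, "seed": config.seed})
        )
        dataset = simulate(sim_design)
        photos, deployments = dataset.photos, dataset.deployments
        cov_raw = dataset.covariates.copy()
        site_ids = dataset.matrix.site_ids
        log("data", f"simulated {sim_design.n_sites} sites with seed {config.seed}")
    else:
        photos = read_photos(config.photos, config.target_species)
        deployments = read_deployments(config.deployments)
        cov_table = pd.read_csv(config.covariates)
        site_ids = cov_table["site_id"].tolist()
        cov_raw = cov_table.drop(columns=["site_id"])
        log("data", f"read {len(photos)} photo records, {len(site_ids)} sites")

    # --- detection history -------------------------------------------------
    matrix = build_matrix(photos, deployments, config.occasion_length)
    if list(matrix.site_ids) != list(site_ids):
        pos = {s: i for i, s in enumerate(site_ids)}
        cov_raw = cov_raw.iloc[[pos[s] for s in matrix.site_ids]].reset_index(drop=True)
    naive = naive_occupancy(matrix)
    det_rate = naive_detection_rate(matrix)
    n_events = independent_detections(photos)
    log("history", f"{matrix.n_sites} x {matrix.n_occasions} matrix; "
                   f"naive occupancy {naive:.3f}, detection rate {det_rate:.3f}")

    # --- covariates ---------------------------------------------------------
    scaler = CovariateStandardizer().fit(cov_raw)
    cov_std = scaler.transform(cov_raw)
    pruner = CollinearityPruner(
        threshold=config.corr_threshold, priority=config.priority
    ).fit(cov_std)
    cov = pruner.transform(cov_std)
    if pruner.dropped_:
        (outdir / "covariate_drop_log.txt").write_text(
            "".join(f"{n}: dropped ({r})\n" for n, r in pruner.dropped_)
        )
    log("covariates", f"kept {list(pruner.kept_)}; dropped {pruner.dropped_}")

    # --- model set ----------------------------------------------------------
    psi_c = config.psi_candidates or list(cov.columns)
    p_c = config.p_candidates or list(cov.columns)
    specs = selection.enumerate_models(
        psi_c, p_c, max_terms=config.max_terms, budget=config.model_budget
    )
    fits = selection.fit_models(specs, matrix, cov)
    model_set = selection.rank_and_weight(fits)
    conf = selection.confidence_set(model_set, config.delta_threshold)
    model_set.to_csv(outdir / "model_table.csv")
    conf.to_csv(outdir / "confidence_set.csv")
    log("models", f"fitted {len(specs)} models; confidence set size {len(conf)}")

    averaged = {}
    for part, cands in (("psi", psi_c), ("p", p_c)):
        for term in [f"{part}:(Intercept)"] + [f"{part}:{c}" for c in cands]:
            try:
                est = selection.model_average(conf, term, mode=config.averaging)
            except KeyError:
                continue
            averaged[term] = {
                "estimate": est.estimate,
                "unconditional_se": est.unconditional_se,
                "weight_containing": est.weight_containing,
            }
    psi_pred = selection.average_predictions(conf, {}, "psi")
    p_pred = selection.average_predictions(conf, {}, "p")
    averaged_out = {
        "coefficients": averaged,
        "psi_at_means": {"point": psi_pred.point, "lower": psi_pred.lower,
                         "upper": psi_pred.upper},
        "p_at_means": {"point": p_pred.point, "lower": p_pred.lower,
                       "upper": p_pred.upper},
        "averaging": config.averaging,
    }
    _json_dump(averaged_out, outdir / "averaged_estimates.json")

    # --- assessment ---------------------------------------------------------
    best = model_set.best
    assess: dict = {}
    if config.gof_B >= 1:
        gof = assessment.bootstrap_gof(
            best, matrix, cov, B=config.gof_B, seed=config.gof_seed
        )
        assess["gof"] = gof.to_dict()
        if gof.c_hat > 1:
            best = assessment.adjust_se(best, gof.c_hat)
            assess["se_adjustment"] = {"applied": True, "c_hat": gof.c_hat}
        else:
            assess["se_adjustment"] = {"applied": False, "c_hat": gof.c_hat}
        log("gof", f"c_hat {gof.c_hat:.4f}, p-value {gof.p_value:.3f}")
    if config.cv_k >= 2:
        cv = assessment.cross_validate(
            best.spec, matrix, cov, k=config.cv_k, seed=config.cv_seed,
            prediction=config.cv_prediction,
        )
        assess["cv"] = cv.to_dict()
        log("cv", f"mean MSE {cv.mean_mse:.4f} over {cv.k} folds")
    _json_dump(assess, outdir / "assessment.json")

    # --- survey design -------------------------------------------------------
    curves = []
    baselines = list(config.design_baselines) + [round(p_pred.point, 6)]
    for b in baselines:
        curve = design_mod.p_star_curve(b, 0.0, k_max=matrix.n_occasions)
        frame = curve.to_frame()
        frame.insert(0, "baseline_p", b)
        curves.append(frame)
    fitted_curve = design_mod.p_star_curve(
        p_pred.point,
        (p_pred.upper - p_pred.lower) / (2 * 1.959963984540054),
        k_max=matrix.n_occasions,
    )
    frame = fitted_curve.to_frame()
    frame.insert(0, "baseline_p", round(p_pred.point, 6))
    pd.concat(curves, ignore_index=True).to_csv(outdir / "pstar_scenarios.csv",
                                                index=False)
    frame.to_csv(outdir / "pstar_fitted.csv", index=False)
    req = design_mod.required_surveys(max(p_pred.point, 1e-9), config.design_target)
    log("design", f"required surveys for p*>={config.design_target}: {req}")

    # --- summary and manifest -------------------------------------------------
    summary = {
        "n_sites": matrix.n_sites,
        "n_occasions": matrix.n_occasions,
        "occasion_length": matrix.occasion_length,
        "independent_detections": n_events,
        "naive_occupancy": naive,
        "naive_detection_rate": det_rate,
        "n_models": len(specs),
        "n_converged": len(model_set),
        "confidence_set_size": len(conf),
        "best_model": model_set.best.spec.label,
        "best_aicc": model_set.best.aicc,
        "psi_at_means": psi_pred.point,
        "p_at_means": p_pred.point,
        "required_surveys_at_target": req,
        "dropped_covariates": [n for n, _ in pruner.dropped_],
    }
    if "gof" in assess:
        summary["c_hat"] = assess["gof"]["c_hat"]
    if "cv" in assess:
        summary["cv_mean_mse"] = assess["cv"]["mean_mse"]
    _json_dump(summary, outdir / "summary.json")
    manifest = {
        "config": config.to_dict(),
        "stages": ["data", "history", "covariates", "models", "assessment",
                   "design"],
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "run.log"),
    }
    _json_dump(manifest, outdir / "manifest.json")
    log("done", f"finished in {time.perf_counter() - t0:.1f}s")
    return RunReport(
        outdir=outdir,
        summary=summary,
        model_table=model_set,
        confidence=conf,
        averaged=averaged_out,
        assessment=assess,
    )
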