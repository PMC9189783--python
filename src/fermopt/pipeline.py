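"""End-to-end orchestration: screening -> surface modelling -> optimum -> kinetics -> purification.

Two entry points:

* :func:`reproduce_study` re-derives every headline number of the packaged
  study tables (screening improvements, quadratic refit with ANOVA, seeded
  network fit, metric comparison, desirability optimum with its confirmation
  verdict, kinetic yield coefficients and the purification table) and returns
  them as one nested report dict, optionally written as JSON + Markdown.
* :func:`run` applies the same stages to user-supplied CSV inputs driven by a
  :class:`PipelineConfig` (stages are individually skippable).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, accounting, datasets, io as fio
from .ann import fit_ann
from .kinetics import fit_timeseries, derive_yields
from .metrics import compute_metrics, compare_models
from .optimizer import optimize_surface, validate_optimum
from .rsm import fit_quadratic, anova
from .simulate import fermentation_truth_preset, simulate_fermentation

logger = logging.getLogger("fermopt")

__all__ = ["PipelineConfig", "reproduce_study", "run"]

#: protease-activity milestones of the packaged study (U), used as printed
#: inputs to the strain-improvement arithmetic
ACTIVITY_MILESTONES = {
    "parent": 36209.54,
    "best_mutant": 85873.38,
    "factorial_screen": 188956.23,
    "steepest_ascent": 306945.52,
}

#: observed activity (U) of the triplicate confirmation run at the optimum
CONFIRMED_OPTIMUM_ACTIVITY = 418763.45


def _screening_stage() -> dict:
    table = datasets.load_fixture("strain_screening")
    report = accounting.screening_report(table)
    best = report.loc[report["activity_u"].idxmax()]
    m = ACTIVITY_MILESTONES
    return {
        "table": report.to_dict(orient="records"),
        "best_mutant": best["code"],
        "best_improvement_pct": float(best["improvement_calc"]),
        "fold_mutant_vs_parent": accounting.fold_change(m["best_mutant"], m["parent"]),
        "fold_factorial_vs_mutant": accounting.fold_change(
            m["factorial_screen"], m["best_mutant"]),
        "fold_ascent_vs_parent": accounting.fold_change(
            m["steepest_ascent"], m["parent"]),
    }


def _rsm_stage(runs, response: str = "activity_exp") -> dict:
    X = runs[datasets.CCRD_FACTOR_COLUMNS].to_numpy(float)
    y = runs[response].to_numpy(float)
    factors = datasets.ccrd_factors()
    fit = fit_quadratic(factors.code(X), y, basis="coded")
    fit.names = factors.names
    table = anova(fit, factors.code(X), y)
    return {"fit": fit.to_dict(), "anova": table.to_frame().to_dict(orient="records"),
            "r2": fit.r2, "surface": fit}


def _ann_stage(runs, response: str = "activity_exp", *, n_hidden: int = 12,
               seed: int = 7) -> dict:
    X = runs[datasets.CCRD_FACTOR_COLUMNS].to_numpy(float)
    y = runs[response].to_numpy(float)
    model = fit_ann(X, y, n_hidden=n_hidden, seed=seed)
    return {"seed": seed, "n_hidden": n_hidden, "r2": model.net.r2,
            "mse": model.net.mse, "split_sizes": [len(model.net.idx_train),
                                                  len(model.net.idx_val),
                                                  len(model.net.idx_test)],
            "model": model}


def _metrics_stage(runs) -> dict:
    out: dict = {}
    for response, rsm_col, ann_col in (
            ("total_protein", "protein_rsm", "protein_ann"),
            ("activity", "activity_rsm", "activity_ann")):
        exp_col = rsm_col.split("_")[0] + "_exp"
        y = runs[exp_col].to_numpy(float)
        reports = {"rsm": compute_metrics(y, runs[rsm_col].to_numpy(float)),
                   "ann": compute_metrics(y, runs[ann_col].to_numpy(float))}
        out[response] = {
            "rsm": reports["rsm"].as_dict(), "ann": reports["ann"].as_dict(),
            "comparison": compare_models(reports)}
    return out


def _optimum_stage() -> dict:
    surface = datasets.activity_surface()
    factors = datasets.ccrd_factors()
    result = optimize_surface(surface, bounds=(-1.0, 1.0), grid_density=5,
                              factors=factors)
    verdict = validate_optimum(result.predicted, CONFIRMED_OPTIMUM_ACTIVITY)
    return {"optimum": result.to_dict(),
            "validation": verdict.__dict__,
            "factor_names": factors.names}


def _kinetics_stage(seed: int = 11, rel_noise_sd: float = 0.01) -> dict:
    params = datasets.load_fixture("kinetic_parameters")["mutant"]
    truth = fermentation_truth_preset("mutant", rel_noise_sd=rel_noise_sd, seed=seed)
    data = simulate_fermentation(truth)
    fitted: dict = {}
    bio_fit, bio_stats = fit_timeseries(data["time"], data["biomass"], "logistic")
    fitted["biomass"] = {"params": bio_fit.__dict__, "stats": bio_stats.__dict__}
    gomp = {}
    for name in ("total_protein", "activity", "substrate"):
        p, s = fit_timeseries(data["time"], data[name], "gompertz")
        gomp[name] = p
        fitted[name] = {"params": p.__dict__, "stats": s.__dict__}
    yields = derive_yields(bio_fit, gomp["total_protein"], gomp["substrate"])
    # yield coefficients straight from the published asymptotes, for reference
    from .kinetics import GompertzParams, LogisticParams
    pub = derive_yields(
        LogisticParams(params["biomass"]["X0"], params["biomass"]["Xmax"],
                       params["biomass"]["mu_max"]),
        GompertzParams(params["total_protein"]["Pmax"], params["total_protein"]["r_max"],
                       params["total_protein"]["t_lag"]),
        GompertzParams(params["substrate"]["Pmax"], params["substrate"]["r_max"],
                       params["substrate"]["t_lag"]))
    return {"seed": seed, "rel_noise_sd": rel_noise_sd, "fitted": fitted,
            "yields_refit": yields.__dict__, "yields_published_params": pub.__dict__}


def _purification_stage() -> dict:
    table = datasets.load_fixture("atps_purification")
    steps = [accounting.PurificationStep(r.step, r.protein_mg, r.activity_u)
             for r in table.itertuples()]
    crude = next(s for s in steps if s.label == "crude")
    report = accounting.purification_report([s for s in steps if s is not crude], crude)
    best = report.iloc[1:].loc[report.iloc[1:]["yield_pct"].idxmax()]
    return {"table": report.to_dict(orient="records"),
            "best_step": best["label"],
            "best_yield_pct": float(best["yield_pct"]),
            "best_fold": float(best["fold"])}


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items() if k not in ("surface", "model")}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def reproduce_study(outdir=None, *, ann_seed: int = 7, kinetics_seed: int = 11) -> dict:
    """Recompute the full study report from the packaged tables; deterministic per seeds."""
    runs = datasets.load_fixture("ccrd_runs")
    report = {
        "package_version": __version__,
        "seeds": {"ann": ann_seed, "kinetics": kinetics_seed},
        "screening": _screening_stage(),
        "rsm": _rsm_stage(runs),
        "ann": _ann_stage(runs, seed=ann_seed),
        "metrics": _metrics_stage(runs),
        "optimization": _optimum_stage(),
        "kinetics": _kinetics_stage(seed=kinetics_seed),
        "purification": _purification_stage(),
    }
    if outdir is not None:
        _write_report(report, Path(outdir))
    return report


def _write_report(report: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    clean = _to_jsonable(report)
    (outdir / "report.json").write_text(json.dumps(clean, indent=1, sort_keys=True))
    lines = ["# Fermentation-optimization report", ""]
    scr = clean.get("screening")
    if scr:
        lines += [f"- Best mutant: {scr['best_mutant']} "
                  f"(+{scr['best_improvement_pct']:.2f}% activity, "
                  f"{scr['fold_mutant_vs_parent']:.2f}-fold over parent)"]
    if "rsm" in clean:
        lines += [f"- Quadratic surface refit r2 = {clean['rsm']['r2']:.4f}"]
    if "ann" in clean:
        lines += [f"- Network fit (seed {clean['ann']['seed']}) overall r2 = "
                  f"{clean['ann']['r2']['overall']:.4f}"]
    if "optimization" in clean:
        opt = clean["optimization"]
        lines += [f"- Optimum predicted {opt['optimum']['predicted']:.2f} U; "
                  f"confirmation difference "
                  f"{opt['validation']['percent_difference']:.2f}% "
                  f"({'pass' if opt['validation']['passed'] else 'fail'})"]
    if "purification" in clean:
        pur = clean["purification"]
        lines += [f"- Best purification step {pur['best_step']}: "
                  f"yield {pur['best_yield_pct']:.2f}%, fold {pur['best_fold']:.2f}"]
    (outdir / "report.md").write_text("\n".join(lines) + "\n")


@dataclass
class PipelineConfig:
    """Stage inputs for a user-data run; a ``None`` path disables the stage."""

    runs_csv: str | None = None
    factor_columns: list[str] = field(default_factory=list)
    response_column: str = "activity"
    kinetics_csv: str | None = None
    kinetics_series: dict = field(default_factory=dict)  # column -> model name
    purification_csv: str | None = None
    ann_seed: int = 7
    n_hidden: int = 12
    significance: float = 0.05
    validation_threshold_pct: float = 5.0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.__dict__, sort_keys=True,
                                         default=str).encode()).hexdigest()[:12]


def run(config: PipelineConfig) -> dict:
    """Run the configured stages on user data; errors are tagged by stage."""
    report: dict = {"package_version": __version__, "config_hash": config.digest(),
                    "seeds": {"ann": config.ann_seed}}
    logger.info("pipeline start (config %s)", report["config_hash"])

    if config.runs_csv is not None:
        try:
            runs = fio.read_csv_runs(config.runs_csv, config.factor_columns,
                                     [config.response_column])
            X = runs[config.factor_columns].to_numpy(float)
            y = runs[config.response_column].to_numpy(float)
            fit = fit_quadratic(X, y, basis="actual")
            result = optimize_surface(
                fit, bounds=list(zip(X.min(axis=0), X.max(axis=0))), grid_density=5)
            model = fit_ann(X, y, n_hidden=config.n_hidden, seed=config.ann_seed)
            preds = {"rsm": compute_metrics(y, fit.predict(X)),
                     "ann": compute_metrics(y, model.predict(X))}
            report["modelling"] = {
                "rsm": {"r2": fit.r2, "coef": fit.to_dict()},
                "ann": {"r2": model.net.r2},
                "metrics": {k: v.as_dict() for k, v in preds.items()},
                "comparison": compare_models(preds),
                "optimum": result.to_dict(),
            }
        except Exception as err:
            raise RuntimeError(f"[modelling stage] {err}") from err

    if config.kinetics_csv is not None:
        try:
            series = config.kinetics_series or {"biomass": "logistic"}
            data = fio.read_timeseries(config.kinetics_csv, list(series))
            fits = {}
            for col, model_name in series.items():
                p, s = fit_timeseries(data["time"], data[col], model_name)
                fits[col] = {"params": p.__dict__, "stats": s.__dict__}
            report["kinetics"] = fits
        except Exception as err:
            raise RuntimeError(f"[kinetics stage] {err}") from err

    if config.purification_csv is not None:
        try:
            table = fio.read_csv_runs(config.purification_csv, ["protein_mg"],
                                      ["activity_u"])
            steps = [accounting.PurificationStep(str(r.step), r.protein_mg, r.activity_u)
                     for r in table.itertuples()]
            crude = next((s for s in steps if s.label == "crude"), steps[0])
            rep = accounting.purification_report(steps, crude)
            report["purification"] = rep.to_dict(orient="records")
        except Exception as err:
            raise RuntimeError(f"[purification stage] {err}") from err

    if config.outdir is not None:
        _write_report(report, Path(config.outdir))
    logger.info("pipeline done")
    return report
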