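"""End-to-end orchestration: inputs -> climate match -> analysis table ->
all-subsets GLMM fits -> AICc ranking -> model averaging -> report CSVs.

Inputs are either a synthetic world (simulated in-process from a
GeneratorConfig) or a directory of files in the documented layout
(rasters/*.asc, occurrences.csv, traits.csv, jurisdictions.csv,
records.csv).  Outputs are plot-ready CSVs shaped like the publication
artifacts — a ranked model table, variance components of the best
model, model-averaged effects, and a predicted-probability-vs-climate
curve from the single top model (random effects at zero) — plus a
machine-readable run log with exclusion counts and convergence flags.
Everything is deterministic given the config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import FACTORS, assemble_dataset
from .glmm import ConvergenceWarning, FitResult, RandomStructure, fit_glmm, predict_probability
from .multimodel import (AveragedEstimates, enumerate_models,
                         model_average, rank_models, top_set)
from .rasters import RasterStack
from .simulate import GeneratorConfig, SyntheticWorld, compute_pair_covariates, simulate_all

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "report_effect_plot_data",
           "load_pipeline_config", "load_world_dir", "write_fit"]

_SIZE_FACTORS = ("body_size", "clutch_size")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str = "results"
    simulate: GeneratorConfig | None = None
    input_dir: str | None = None
    variants: tuple[str, ...] = ("with_size", "without_size")
    percentile_q: int = 90
    delta_max: float = 4.0
    candidate_factors: tuple | None = None  # None -> all applicable factors
    curve_points: int = 50
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.percentile_q not in (50, 80, 90, 95):
            raise ValueError("percentile_q must be one of 50, 80, 90, 95")
        if self.delta_max <= 0:
            raise ValueError("delta_max must be positive")
        if (self.simulate is None) == (self.input_dir is None):
            raise ValueError("exactly one of simulate / input_dir must be set")
        bad = set(self.variants) - {"with_size", "without_size"}
        if bad:
            raise ValueError(f"unknown variant(s): {sorted(bad)}")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline config; a ``simulate:`` mapping becomes a
    GeneratorConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    cfg = PipelineConfig(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in raw.items()})
    if sim is not None:
        cfg = dataclasses.replace(cfg, simulate=GeneratorConfig(**sim))
    return cfg


def load_world_dir(input_dir: str | Path, percentile_q: int = 90) -> SyntheticWorld:
    """Assemble a world container from the documented file layout."""
    d = Path(input_dir)
    stack = RasterStack.from_dir(d / "rasters")
    jurisdictions = pd.read_csv(d / "jurisdictions.csv")
    if "cells" not in jurisdictions.columns:
        raise ValueError("jurisdictions.csv needs a 'cells' column (row:col;...)")
    jur_cells = {
        row.jurisdiction_id: [tuple(map(int, c.split(":"))) for c in str(row.cells).split(";") if c]
        for row in jurisdictions.itertuples()
    }
    world = SyntheticWorld(GeneratorConfig(percentile_q=percentile_q), stack,
                           jurisdictions, jur_cells)
    world.species = pd.read_csv(d / "traits.csv")
    world.occurrences = pd.read_csv(d / "occurrences.csv")
    world.records = pd.read_csv(d / "records.csv")
    return world


def _fit_model_set(table: pd.DataFrame, candidates, delta_max: float):
    """Fit all candidate subsets; drop non-converged fits with a logged
    warning; return (fits kept, ranked table, top set, n_dropped)."""
    specs = enumerate_models(candidates)
    fits: list[FitResult] = []
    n_dropped = 0
    for spec in specs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            fit = fit_glmm(table, spec, RandomStructure())
        if not fit.converged:
            n_dropped += 1
            logger.warning("model %s did not converge; excluded from model set",
                           fit.spec_code)
            continue
        fits.append(fit)
    if not fits:
        raise RuntimeError("no candidate model converged")
    ranked = rank_models(fits)
    return fits, ranked, top_set(ranked, delta_max), n_dropped


def _climate_curve(fit: FitResult, table: pd.DataFrame, n_points: int) -> pd.DataFrame:
    """Predicted establishment probability against standardized climate
    match, other covariates at reference / zero, from one model."""
    lo = float(table["climate_match"].min()) if "climate_match" in table else -1.0
    hi = float(table["climate_match"].max()) if "climate_match" in table else 1.0
    grid = np.linspace(lo, hi, n_points)
    base = {f: ("intentional" if f == "intentionality" else 0.0)
            for f in fit.model_spec}
    probs = []
    for x in grid:
        cov = dict(base)
        if "climate_match" in fit.model_spec:
            cov["climate_match"] = x
        probs.append(predict_probability(fit, cov))
    return pd.DataFrame({"climate_match": grid, "probability": probs})


def report_effect_plot_data(avg: AveragedEstimates) -> pd.DataFrame:
    """Factor-effect rows ordered for plotting: descending relative
    importance, ties broken by |estimate| (intercept omitted)."""
    t = avg.table
    if t.empty:
        raise ValueError("empty averaged-estimate table")
    t = t[t["coefficient"] != "(Intercept)"].copy()
    t["_abs"] = t["estimate"].abs()
    t = t.sort_values(["importance", "_abs"], ascending=[False, False],
                      kind="mergesort").drop(columns="_abs")
    return t.reset_index(drop=True)


def write_fit(fit: FitResult, prefix: str | Path) -> None:
    """Serialize one fit: coefficients + variance components CSV and a
    JSON sidecar with the scalar diagnostics."""
    prefix = Path(prefix)
    coef = fit.to_frame().reset_index(names="coefficient")
    coef["kind"] = "fixed"
    vc = fit.variance_components.rename(columns={"term": "coefficient",
                                                 "sd": "se"})
    vc = vc.assign(coef=vc["variance"], kind="random")[["coefficient", "coef", "se", "kind"]]
    pd.concat([coef, vc], ignore_index=True).to_csv(f"{prefix}.csv", index=False)
    with open(f"{prefix}.json", "w") as fh:
        json.dump({"model_spec": list(fit.model_spec), "spec_code": fit.spec_code,
                   "loglik": fit.loglik, "k": fit.k, "n": fit.n,
                   "aicc": fit.aicc, "converged": fit.converged,
                   "n_outer_iter": fit.n_outer_iter}, fh, indent=1)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the results
    (per-variant fits, model tables, averages) keyed by variant."""
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s %(message)s")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.simulate is not None:
        sim = dataclasses.replace(cfg.simulate, percentile_q=cfg.percentile_q)
        world = simulate_all(sim)
    else:
        world = load_world_dir(cfg.input_dir, cfg.percentile_q)

    pairs = world.records[["species_id", "jurisdiction_id"]]
    scores, dists = compute_pair_covariates(world, pairs)
    scores.to_csv(out / "climate_scores.csv", index=False)

    results: dict = {"world": world, "variants": {}}
    log: dict = {"config": _config_dict(cfg), "variants": {}}
    for variant in cfg.variants:
        include_size = variant == "with_size"
        table, excl = assemble_dataset(world.records, world.species, scores, dists,
                                       world.jurisdictions,
                                       include_size_traits=include_size)
        excl.to_csv(out / f"exclusions_{variant}.csv", index=False)
        table.to_csv(out / f"analysis_table_{variant}.csv", index=False)

        candidates = cfg.candidate_factors
        if candidates is None:
            candidates = tuple(FACTORS.values())
        candidates = tuple(f for f in candidates
                           if include_size or f not in _SIZE_FACTORS)
        fits, ranked, top, n_dropped = _fit_model_set(table, candidates, cfg.delta_max)
        avg = model_average(top, fits)
        best = next(f for f in fits
                    if f.model_spec == tuple(top.entries["spec"].iloc[0]))

        ranked.entries.drop(columns="spec").to_csv(
            out / f"model_table_{variant}.csv", index=False)
        best.variance_components.to_csv(
            out / f"variance_components_{variant}.csv", index=False)
        avg.table.to_csv(out / f"averaged_estimates_{variant}.csv", index=False)
        report_effect_plot_data(avg).to_csv(
            out / f"effect_plot_{variant}.csv", index=False)
        _climate_curve(best, table, cfg.curve_points).to_csv(
            out / f"climate_curve_{variant}.csv", index=False)
        write_fit(best, out / f"best_fit_{variant}")

        results["variants"][variant] = {
            "table": table, "fits": fits, "ranked": ranked, "top": top,
            "averaged": avg, "best": best,
        }
        log["variants"][variant] = {
            "n_rows": int(len(table)),
            "n_species": int(table["species_id"].nunique()),
            "n_genera": int(table["genus"].nunique()),
            "n_excluded": int(len(excl)),
            "n_models_fit": len(fits),
            "n_models_nonconverged": n_dropped,
            "n_top_set": len(top),
            "best_model": best.spec_code,
            "best_aicc": best.aicc,
        }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    results["log"] = log
    return results


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if cfg.simulate is not None:
        d["simulate"] = dataclasses.asdict(cfg.simulate)
    return d
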