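"""End-to-end orchestration: cohort -> fit -> prune -> refit -> indices -> effects.

The pipeline mirrors the published analysis flow: build (or generate) the
analysis table, check sample-size adequacy, fit the hypothetical model,
prune paths at the significance threshold (default P < 0.1), refit the
pruned model, compute global fit indices, and decompose histology effects
on the eGFR slope.  A coefficient-injection file bypasses estimation and
feeds the decomposition directly (used to reproduce the published tables
from their printed coefficients).

All artifacts are delimited text or JSON; the run log captures the
configuration, seed, package versions, stage counters, and the
elimination-bias flag, so a run is reproducible from the log alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (CohortTable, build_analysis_table, read_cohort_csv,
                     write_analysis_table)
from .effects import decompose_all, discrepancy_report
from .fitindex import check_sample_size, fit_indices
from .model import (PathFitResult, PathModelSpec, final_spec, fit,
                    hypothetical_spec, parse_model, prune, to_model_syntax)
from .synth import GeneratorConfig, generate_realistic, generate_standardized

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "render_tables",
           "read_coefficient_file", "write_coefficient_file"]

logger = logging.getLogger("iganpath")

#: number of dummy-level variables in the published sample-size rule
SAMPLE_SIZE_VARIABLE_COUNT = 19


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Exactly one of ``cohort_path`` (with ``series_path``), ``generate``,
    or ``coefficients_path`` drives the coefficient stage.
    """

    output_dir: str = "iganpath_run"
    seed: int = 0
    cohort_path: Optional[str] = None
    series_path: Optional[str] = None
    generate: Optional[str] = None        # generator mode, e.g. "realistic"
    n: int = 946
    coefficients_path: Optional[str] = None
    model: str = "hypothetical"           # "hypothetical" | "final" | file path
    alpha: float = 0.1
    effect_mode: str = "full_enumeration"  # | "as_published"
    allow_small_sample: bool = False
    min_series_points: int = 3

    def validate(self) -> None:
        drivers = [self.cohort_path is not None, self.generate is not None,
                   self.coefficients_path is not None]
        if sum(drivers) != 1:
            raise ValueError(
                "exactly one of cohort_path, generate, coefficients_path "
                "must be set")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def _resolve_spec(name: str) -> PathModelSpec:
    if name == "hypothetical":
        return hypothetical_spec()
    if name == "final":
        return final_spec()
    return parse_model(Path(name).read_text())


def read_coefficient_file(path) -> Dict[Tuple[str, str], float]:
    """Read a delimited edge-coefficient file (columns parent, child, SC)."""
    df = pd.read_csv(path)
    return {(row["parent"], row["child"]): float(row["SC"])
            for _, row in df.iterrows()}


def write_coefficient_file(coefficients: Dict[Tuple[str, str], float],
                           path) -> None:
    rows = [{"parent": a, "child": b, "SC": v}
            for (a, b), v in coefficients.items()]
    pd.DataFrame(rows, columns=["parent", "child", "SC"]).to_csv(
        path, index=False)


def render_tables(
    fitresult: Optional[PathFitResult],
    decomposition: Dict,
    out_dir: Path,
) -> Dict[str, Path]:
    """Write coefficient-table and decomposition-table artifacts.

    The coefficient table mirrors the published reporting columns
    (SC, SE, z, P, CI low/high, plus the raw-scale intercept per
    equation); the decomposition table mirrors the published
    direct/indirect/via/total layout.  Values are rounded to 3 decimals
    in the delimited files; JSON keeps full precision.
    """
    paths: Dict[str, Path] = {}
    if fitresult is not None:
        frame = fitresult.to_frame()
        coef_csv = out_dir / "coefficients.csv"
        frame.round(3).to_csv(coef_csv, index=False)
        coef_json = out_dir / "coefficients.json"
        coef_json.write_text(json.dumps(
            json.loads(frame.to_json(orient="records")), indent=1,
            sort_keys=True))
        paths["coefficients_csv"] = coef_csv
        paths["coefficients_json"] = coef_json

    rows = []
    for source in sorted(decomposition):
        dec = decomposition[source]
        block = []
        if dec.direct_coefficient != 0.0:
            block.append({"source": source,
                          "direct_coefficient": round(dec.direct_coefficient, 3),
                          "indirect_coefficient": "", "via": "",
                          "total_coefficient": ""})
        for p in dec.indirect_paths:
            block.append({"source": source, "direct_coefficient": "",
                          "indirect_coefficient": round(p.coefficient, 3),
                          "via": p.via(), "total_coefficient": ""})
        if not block:
            block.append({"source": source, "direct_coefficient": "",
                          "indirect_coefficient": "", "via": "",
                          "total_coefficient": ""})
        block[0]["total_coefficient"] = round(dec.total_coefficient, 3)
        rows.extend(block)
    eff_csv = out_dir / "effects.csv"
    pd.DataFrame(rows, columns=["source", "direct_coefficient",
                                "indirect_coefficient", "via",
                                "total_coefficient"]).to_csv(eff_csv,
                                                             index=False)
    eff_json = out_dir / "effects.json"
    eff_json.write_text(json.dumps({
        src: {
            "direct": dec.direct_coefficient,
            "indirect": [{"via": list(p.mediators), "coefficient": p.coefficient}
                         for p in dec.indirect_paths],
            "total": dec.total_coefficient,
        } for src, dec in sorted(decomposition.items())
    }, indent=1, sort_keys=True))
    paths["effects_csv"] = eff_csv
    paths["effects_json"] = eff_json
    return paths


def run_pipeline(config: RunConfig) -> Dict[str, Path]:
    """Execute the full analysis; returns a map of artifact names to paths."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, Path] = {}
    log: Dict = {"config": asdict(config), "seed": config.seed,
                 "versions": {"iganpath": __version__,
                              "numpy": np.__version__,
                              "pandas": pd.__version__},
                 "stages": {}}

    # --- coefficient-injection short-circuit -----------------------------
    if config.coefficients_path is not None:
        try:
            coefficients = read_coefficient_file(config.coefficients_path)
        except Exception as exc:
            raise PipelineError("coefficients", str(exc)) from exc
        spec = _resolve_spec(
            config.model if config.model != "hypothetical" else "final")
        decomposition = decompose_all(spec, coefficients,
                                      mode=config.effect_mode)
        artifacts.update(render_tables(None, decomposition, out_dir))
        disc = discrepancy_report(spec, coefficients)
        disc_path = out_dir / "effects_discrepancy.csv"
        disc.round(4).to_csv(disc_path)
        artifacts["effects_discrepancy"] = disc_path
        log["stages"]["effects"] = {"mode": config.effect_mode,
                                    "sources": len(decomposition)}
        _write_log(out_dir, log, artifacts)
        return artifacts

    # --- cohort ----------------------------------------------------------
    try:
        if config.generate is not None:
            gen = GeneratorConfig(n=config.n, seed=config.seed,
                                  mode=config.generate)
            if config.generate == "realistic":
                records = generate_realistic(gen)
                table = build_analysis_table(
                    records, min_series_points=config.min_series_points)
            else:
                table = generate_standardized(gen)
        else:
            records = read_cohort_csv(config.cohort_path, config.series_path)
            table = build_analysis_table(
                records, min_series_points=config.min_series_points)
    except Exception as exc:
        raise PipelineError("cohort", str(exc)) from exc
    logger.info("cohort: %d retained, %d excluded", table.n, table.n_excluded)
    log["stages"]["cohort"] = {"retained": table.n,
                               "excluded": table.n_excluded}
    table_path = out_dir / "analysis_table.csv"
    write_analysis_table(table, table_path, out_dir / "exclusions.csv")
    artifacts["analysis_table"] = table_path
    artifacts["exclusions"] = out_dir / "exclusions.csv"

    # --- sample size ------------------------------------------------------
    ok, minimum = check_sample_size(table.n, SAMPLE_SIZE_VARIABLE_COUNT)
    log["stages"]["sample_size"] = {"n": table.n, "minimum": minimum,
                                    "pass": bool(ok)}
    if not ok:
        if not config.allow_small_sample:
            raise PipelineError(
                "sample_size",
                f"cohort of {table.n} below minimum {minimum}; "
                "set allow_small_sample to continue")
        logger.warning("sample size %d below minimum %d; continuing on "
                       "explicit override", table.n, minimum)

    # --- fit, prune, refit -----------------------------------------------
    spec = _resolve_spec(config.model)
    try:
        first_fit = fit(spec, table)
        pruned, bias_free = prune(spec, first_fit, alpha=config.alpha)
        refit = fit(pruned, table)
    except Exception as exc:
        raise PipelineError("fit", str(exc)) from exc
    n_removed = len(spec.directed_edges) - len(pruned.directed_edges)
    logger.info("prune: removed %d of %d edges (alpha=%g); "
                "elimination-bias-free=%s", n_removed,
                len(spec.directed_edges), config.alpha, bias_free)
    log["stages"]["prune"] = {"alpha": config.alpha,
                              "edges_removed": n_removed,
                              "elimination_bias_free": bool(bias_free)}
    model_path = out_dir / "pruned_model.txt"
    model_path.write_text(to_model_syntax(pruned))
    artifacts["pruned_model"] = model_path

    # --- fit indices ------------------------------------------------------
    try:
        indices = fit_indices(pruned, refit)
    except Exception as exc:
        raise PipelineError("indices", str(exc)) from exc
    idx_path = out_dir / "fit_indices.json"
    idx_path.write_text(json.dumps({
        "chi2": indices.chi2, "df": indices.df, "p_chi2": indices.p_chi2,
        "rmsea": indices.rmsea, "rmsea_ci90": list(indices.rmsea_ci90),
        "cfi": indices.cfi, "srmsr": indices.srmsr,
        "baseline_chi2": indices.baseline_chi2,
        "baseline_df": indices.baseline_df,
        "saturated": indices.saturated,
        "meets_published_thresholds": indices.meets_published_thresholds(),
    }, indent=1, sort_keys=True))
    (out_dir / "fit_indices.txt").write_text(indices.summary() + "\n")
    artifacts["fit_indices"] = idx_path
    log["stages"]["indices"] = {"summary": indices.summary()}

    # --- effects ----------------------------------------------------------
    try:
        decomposition = decompose_all(pruned, refit.coefficient_map(),
                                      mode=config.effect_mode)
    except Exception as exc:
        raise PipelineError("effects", str(exc)) from exc
    artifacts.update(render_tables(refit, decomposition, out_dir))
    log["stages"]["effects"] = {"mode": config.effect_mode,
                                "sources": len(decomposition)}

    _write_log(out_dir, log, artifacts)
    return artifacts


def _write_log(out_dir: Path, log: Dict, artifacts: Dict[str, Path]) -> None:
    log["artifacts"] = {k: str(v) for k, v in artifacts.items()}
    path = out_dir / "run_log.json"
    path.write_text(json.dumps(log, indent=1, sort_keys=True))
    artifacts["run_log"] = path
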