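"""End-to-end pipeline: design → simulate/load → fit → rank → validate.

One root seed is expanded into independent per-stage child seeds through
``numpy.random.SeedSequence.spawn`` (order: design, responses, calibration,
matrix study), so any stage can be rerun in isolation and identical
config + seed gives byte-identical outputs.  All interchange is CSV (UTF-8,
'.' decimal separator); non-detects are an explicit boolean column, never a
zero or a blank.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import (
    Condition,
    Design,
    FactorSpace,
    ModelSpec,
    FULL_MODEL_TERMS,
    d_criterion,
    d_optimal_design,
)
from .modeling import FittedModel, backward_eliminate, fit_model
from .optimization import (
    consensus_select,
    predict_grid,
    rank_top3_counts,
    rank_total_area,
    ranking_report,
)
from .synthetic import (
    SyntheticStudyConfig,
    generate_calibration_samples,
    generate_design_responses,
    generate_matrix_study,
    make_random_truths,
)
from .validation import fit_calibration, precision, recovery

logger = logging.getLogger("dllmeopt")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "stage_seeds",
    "run_pipeline",
    "write_design_csv",
    "read_design_csv",
    "write_responses_csv",
    "read_responses_csv",
]

_STAGES = ("design", "responses", "calibration", "matrix")


def stage_seeds(root_seed: int) -> dict[str, int]:
    """Deterministic child seed per stage, spawned from one root seed."""
    children = np.random.SeedSequence(root_seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(_STAGES, children)
    }


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; round-trips through YAML unchanged."""

    seed: int = 0
    n_runs: int = 60
    n_starts: int = 20
    n_replicates: int = 3
    alpha: float = 0.05
    top_k: int = 10
    top_m: int = 3
    noise_cv: float = 0.05
    response: str = "peak_area"  # or "area_ratio"
    model_terms: tuple[str, ...] = FULL_MODEL_TERMS
    run_validation: bool = True
    responses_csv: str | None = None  # load measured data instead of simulating
    synthetic: bool = True

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["model_terms"] = list(self.model_terms)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["model_terms"] = tuple(d.get("model_terms", FULL_MODEL_TERMS))
        return cls(**d)


@dataclass
class PipelineResult:
    design: Design
    responses: pd.DataFrame
    fitted: dict[str, FittedModel]
    reduced: dict[str, FittedModel]
    excluded_analytes: list[str]
    grid_report: pd.DataFrame
    by_total: list[Condition]
    by_counts: list[tuple[Condition, int]]
    consensus: Condition
    calibration: pd.DataFrame | None = None
    recovery_report: pd.DataFrame | None = None


# ---------------------------------------------------------------- CSV I/O

def write_design_csv(design: Design, path: str | Path) -> None:
    rows = []
    for rid, cond in zip(design.run_ids, design.runs):
        for rep in range(1, design.n_replicates + 1):
            rows.append((rid, cond.x1, int(cond.x2), cond.x3, int(cond.x4), rep))
    pd.DataFrame(
        rows,
        columns=["run_id", "ext_solvent", "ext_volume_ul", "disp_solvent", "disp_volume_ul", "replicate"],
    ).to_csv(path, index=False)


def read_design_csv(path: str | Path) -> Design:
    df = pd.read_csv(path)
    n_replicates = int(df["replicate"].max()) if "replicate" in df.columns else 1
    first = df.drop_duplicates("run_id", keep="first").sort_values("run_id")
    runs = tuple(
        Condition(r.ext_solvent, float(r.ext_volume_ul), r.disp_solvent, float(r.disp_volume_ul))
        for r in first.itertuples()
    )
    return Design(runs=runs, n_replicates=n_replicates)


def write_responses_csv(responses: pd.DataFrame, path: str | Path) -> None:
    responses.to_csv(path, index=False)


def read_responses_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["non_detect"] = df["non_detect"].astype(bool)
    return df


# ---------------------------------------------------------------- pipeline

def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full optimization (and optional validation) pipeline.

    Stages: D-optimal design → simulate (or load) responses → per-analyte OLS
    fit + backward elimination → full-grid prediction → dual ranking →
    consensus → calibration/recovery validation.  Analytes with no detected
    observations are excluded from ranking and reported as such.
    """
    space = FactorSpace()
    spec = ModelSpec(tuple(config.model_terms))
    seeds = stage_seeds(config.seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    logger.info("stage design: n_runs=%d seed=%d", config.n_runs, seeds["design"])
    design = d_optimal_design(
        space, spec, config.n_runs,
        seed=seeds["design"], n_starts=config.n_starts,
        n_replicates=config.n_replicates,
    )

    study = SyntheticStudyConfig(seed=seeds["responses"], n_replicates=config.n_replicates)
    truths = make_random_truths(seed=seeds["responses"], noise_cv=config.noise_cv)
    if config.responses_csv is not None:
        responses = read_responses_csv(config.responses_csv)
        logger.info("stage responses: loaded %s", config.responses_csv)
    elif config.synthetic:
        responses = generate_design_responses(design, truths, study, space)
        logger.info("stage responses: simulated, seed=%d", seeds["responses"])
    else:
        raise FileNotFoundError(
            "stage responses: no response table configured and synthetic "
            "generation is disabled (set responses_csv or synthetic: true)"
        )

    fitted: dict[str, FittedModel] = {}
    reduced: dict[str, FittedModel] = {}
    excluded: list[str] = []
    for analyte in responses["analyte"].unique():
        try:
            full = fit_model(responses, design, spec, analyte=analyte,
                             space=space, response=config.response)
        except ValueError as exc:
            logger.warning("stage fit: excluding %s (%s)", analyte, exc)
            excluded.append(str(analyte))
            continue
        fitted[analyte] = full
        reduced[analyte] = backward_eliminate(full, alpha=config.alpha)

    grid = predict_grid(list(reduced.values()), space)
    by_total = rank_total_area(grid, k=config.top_k)
    by_counts = rank_top3_counts(grid, top_m=config.top_m, k=config.top_k)
    consensus = consensus_select(by_total, by_counts, space)
    report = ranking_report(grid, top_m=config.top_m, k=config.top_k)

    calib_df = None
    recov_df = None
    if config.run_validation:
        calib_df = _validation_calibration(truths, seeds["calibration"])
        recov_df = _validation_recovery(truths, seeds["matrix"], config.n_replicates)

    if out is not None:
        write_design_csv(design, out / "design.csv")
        write_responses_csv(responses, out / "responses.csv")
        _write_model_summary(reduced, excluded, out / "models.csv")
        report.to_csv(out / "ranking.csv", index=False)
        pred_long = grid.predicted.copy()
        pred_long.insert(0, "condition_index", range(len(grid.conditions)))
        pred_long.to_csv(out / "predictions.csv", index=False)
        if calib_df is not None:
            calib_df.to_csv(out / "calibration_report.csv", index=False)
        if recov_df is not None:
            recov_df.to_csv(out / "recovery_report.csv", index=False)
        log = {
            "package_version": __version__,
            "root_seed": config.seed,
            "stage_seeds": seeds,
            "n_runs": config.n_runs,
            "consensus": dataclasses.asdict(consensus),
            "excluded_analytes": excluded,
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2))

    return PipelineResult(
        design=design,
        responses=responses,
        fitted=fitted,
        reduced=reduced,
        excluded_analytes=excluded,
        grid_report=report,
        by_total=by_total,
        by_counts=by_counts,
        consensus=consensus,
        calibration=calib_df,
        recovery_report=recov_df,
    )


def _write_model_summary(models: dict[str, FittedModel], excluded: list[str], path: Path) -> None:
    rows = [
        (
            a,
            ";".join(t for t in m.spec.terms if t != "intercept"),
            m.residual_sd,
            m.r_squared,
            m.n_obs,
        )
        for a, m in models.items()
    ]
    rows += [(a, "EXCLUDED", np.nan, np.nan, 0) for a in excluded]
    pd.DataFrame(
        rows, columns=["analyte", "retained_terms", "residual_sd", "r_squared", "n_obs"]
    ).to_csv(path, index=False)


def _validation_calibration(truths, seed: int) -> pd.DataFrame:
    """Six-level duplicate calibration per modeled analyte; Table-2-style report."""
    rng = np.random.default_rng(seed)
    rows = []
    levels = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0)
    for truth in truths:
        if truth.failing_solvents:  # never-detected analytes have no curve
            continue
        slope = float(rng.uniform(0.5, 3.0))
        sigma = slope * float(rng.uniform(0.1, 0.4))
        pts = generate_calibration_samples(
            slope, 0.0, sigma, levels,
            seed=int(rng.integers(2**31)), analyte=truth.analyte,
        )
        curve = fit_calibration(pts)
        rows.append(
            (
                truth.analyte,
                curve.r_squared,
                curve.linear_range[0],
                curve.linear_range[1],
                curve.lod,
                curve.loq,
            )
        )
    return pd.DataFrame(
        rows, columns=["analyte", "r_squared", "range_min", "range_max", "LOD", "LOQ"]
    )


def _validation_recovery(truths, seed: int, n_replicates: int) -> pd.DataFrame:
    """Spiked/unspiked matrix study with a drawn matrix-effect factor per matrix."""
    rng = np.random.default_rng(seed)
    analytes = [t.analyte for t in truths if not t.failing_solvents]
    baselines = {a: float(rng.uniform(2.0, 20.0)) for a in analytes}
    # spike at 1×/3×/10× the baseline so the spike dominates baseline noise
    spike_mult = {"low": 1.0, "medium": 3.0, "high": 10.0}
    rows = []
    for matrix_id in ("sauvignon_blanc", "pinot_noir", "syrah"):
        factor = float(rng.uniform(0.8, 1.2))
        mseed = int(rng.integers(2**31))
        for ai, analyte in enumerate(analytes):
            cb_true = baselines[analyte]
            spikes = {lv: mult * cb_true for lv, mult in spike_mult.items()}
            tab = generate_matrix_study(
                {analyte: cb_true}, spikes, factor,
                noise_cv=0.03, seed=(mseed + ai) % 2**31,
                n_replicates=n_replicates, matrix_id=matrix_id,
            )
            for (analyte_, level), sub in tab.groupby(["analyte", "level"], sort=False):
                unspiked = sub[~sub["spiked"]]["area_ratio"].to_numpy()
                spiked = sub[sub["spiked"]]["area_ratio"].to_numpy()
                cb, co = float(unspiked.mean()), float(spiked.mean())
                r = recovery(co, cb, spikes[level])
                prec = precision({"day1": spiked}, analyte=analyte_, level=level)
                rows.append((matrix_id, analyte_, level, co, cb, spikes[level], r,
                             prec.intra_day_rsd, factor * 100.0))
    return pd.DataFrame(
        rows,
        columns=["matrix_id", "analyte", "level", "Co", "Cb", "Cs",
                 "recovery_pct", "rsd_pct", "true_recovery_pct"],
    )
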