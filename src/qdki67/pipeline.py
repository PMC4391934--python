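"""End-to-end orchestration: simulate/ingest -> unmix -> quantify -> grade ->
survival statistics, with deterministic, file-based outputs.

A single config (dict or YAML file) drives the run.  Recognized sections:

``seed``
    master seed; every stochastic stage derives from it.
``imaging``
    ``scene`` (SceneParams fields), ``n_fields`` (default 6), ``n_cores``
    (default 1) to simulate cores, or ``cubes`` (list of per-core lists of
    cube paths) to ingest acquired stacks; ``threshold`` for quantification.
``cohort``
    CohortParams fields for a synthetic cohort, or ``table``/``column_map``
    to ingest a per-patient file.
``grading``
    ``min_group_frac`` (default 0.10).
``survival``
    ``covariates`` for the multivariate Cox model (defaults to the five
    classical factors).

Identical config + seed yields byte-identical output tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortTable, read_cohort_table, write_cohort_table
from .errors import QDKi67Error
from .grading import assign_grade, optimal_cutpoint
from .quantify import aggregate_core, quantify_field
from .simulate import CohortParams, SceneParams, simulate_cohort, simulate_core
from .spectral import build_default_library, read_cube
from .survival import cox_fit, km_fit, logrank_test, roc_auc
from .unmixing import drop_autofluorescence, unmix_cube

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_config", "DEFAULT_COX_COVARIATES"]

DEFAULT_COX_COVARIATES = ("t_stage", "n_stage", "histo_grade", "er", "her2")


class StageError(QDKi67Error):
    """Wraps a failure with the pipeline stage where it occurred."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as handle:
        config = yaml.safe_load(handle)
    if not isinstance(config, dict):
        raise QDKi67Error(f"config {path} must be a mapping")
    return config


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _imaging_stage(section: dict, seed: int) -> pd.DataFrame:
    """Quantify cores from simulated or ingested cubes; returns one row per core."""
    library = build_default_library()
    threshold = float(section.get("threshold", 0.0))
    rows = []
    if "cubes" in section:
        for core_id, paths in enumerate(section["cubes"]):
            cubes = [read_cube(p) for p in paths]
            fields = [
                quantify_field(drop_autofluorescence(unmix_cube(c, library)), threshold)
                for c in cubes
            ]
            core = aggregate_core(fields)
            rows.append({"core_id": core_id, **asdict(core)})
    else:
        scene_kwargs = dict(section.get("scene", {}))
        n_fields = int(section.get("n_fields", 6))
        n_cores = int(section.get("n_cores", 1))
        base_seed = int(scene_kwargs.pop("seed", seed))
        for core_id in range(n_cores):
            params = SceneParams(seed=base_seed + 1000 * core_id, **scene_kwargs)
            cubes, truth = simulate_core(params, library, n_fields=n_fields)
            fields = [
                quantify_field(drop_autofluorescence(unmix_cube(c, library)), threshold)
                for c in cubes
            ]
            core = aggregate_core(fields)
            rows.append(
                {
                    "core_id": core_id,
                    **asdict(core),
                    "true_ki67_sum": truth.true_ki67_sum,
                    "true_ck_sum": truth.true_ck_sum,
                    "true_ratio": truth.true_ratio,
                    "ratio_rel_error": (
                        abs(core.ratio - truth.true_ratio) / truth.true_ratio
                        if truth.true_ratio > 0
                        else float("nan")
                    ),
                }
            )
    return pd.DataFrame(rows)


def _cohort_stage(section: dict, seed: int) -> CohortTable:
    if "table" in section:
        return read_cohort_table(section["table"], section.get("column_map"))
    params = CohortParams(seed=int(section.get("seed", seed)), **{
        k: v for k, v in section.items() if k != "seed"
    })
    return CohortTable(records=simulate_cohort(params), source=f"simulate_cohort(seed={params.seed})")


def _survival_block(frame: pd.DataFrame, marker: str, min_group_frac: float, covariates):
    """Cut-point, grades, KM/log-rank, Cox and ROC for one biomarker column."""
    values = frame[marker].to_numpy()
    times = frame["dfs_months"].to_numpy()
    events = frame["event"].to_numpy()
    cut = optimal_cutpoint(values, times, events, min_group_frac)
    grades = np.array([assign_grade(v, cut.cutoff).label for v in values])
    high = grades == "II"

    km_curves = {
        label: km_fit(times[grades == label], events[grades == label])
        for label in ("I", "II")
    }
    logrank = logrank_test(times, events, grades)

    usable = [c for c in covariates if c in frame.columns and frame[c].notna().all()]
    design = frame[usable].astype(float).copy()
    design[f"{marker}_grade"] = high.astype(float)
    cox = cox_fit(design, times, events)

    # recurrence-within-follow-up outcome; censored-before-horizon excluded
    horizon = float(times.max())
    case = (events == 1)
    control = (events == 0) & (times >= horizon - 1e-9)
    keep = case | control
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("ROC for %s: excluded %d records censored before %.0f months",
                    marker, n_excluded, horizon)
    roc = roc_auc(high[keep].astype(float), case[keep].astype(int))

    return {
        "cutpoint": cut,
        "grades": grades,
        "km": km_curves,
        "logrank": logrank,
        "cox": cox,
        "roc": roc,
        "roc_n_excluded": n_excluded,
    }


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns a dict with the in-memory results (imaging table, cohort frame
    with grades, per-marker survival blocks, summary) and writes CSV/JSON
    artifacts plus a run manifest to ``output_dir`` when given.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    report: dict = {"summary": {}}

    if "imaging" in config:
        try:
            report["imaging"] = _imaging_stage(config["imaging"], seed)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise StageError("imaging", exc) from exc

    cohort = None
    if "cohort" in config:
        try:
            cohort = _cohort_stage(config["cohort"], seed)
        except Exception as exc:
            raise StageError("cohort", exc) from exc
        frame = cohort.to_dataframe()
        report["cohort"] = frame
        report["summary"]["n_patients"] = len(frame)

        has_outcome = frame["dfs_months"].notna().all() and frame["event"].notna().all()
        if has_outcome:
            min_frac = float(config.get("grading", {}).get("min_group_frac", 0.10))
            covariates = config.get("survival", {}).get("covariates", DEFAULT_COX_COVARIATES)
            report["markers"] = {}
            for marker in ("ki67_sum", "ratio"):
                try:
                    block = _survival_block(frame, marker, min_frac, covariates)
                except Exception as exc:
                    raise StageError(f"survival[{marker}]", exc) from exc
                report["markers"][marker] = block
                frame[f"{marker}_grade"] = block["grades"]
                report["summary"][marker] = {
                    "cutoff": block["cutpoint"].cutoff,
                    "chi_square": block["cutpoint"].chi_square,
                    "p_raw": block["cutpoint"].p_raw,
                    "p_corrected": block["cutpoint"].p_corrected,
                    "n_grade_i": block["cutpoint"].n_low,
                    "n_grade_ii": block["cutpoint"].n_high,
                    "logrank_p": block["logrank"].p,
                    "cox_hr_grade": float(block["cox"].hazard_ratio[-1]),
                    "cox_p_grade": float(block["cox"].p[-1]),
                    "roc_auc": block["roc"].auc,
                    "roc_ci": list(block["roc"].ci),
                }
        else:
            logger.info("cohort lacks complete follow-up; survival stages skipped")

    if output_dir is not None:
        _write_bundle(report, cohort, config, seed, Path(output_dir))
    return report


def _write_bundle(report, cohort, config, seed, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if "imaging" in report:
        report["imaging"].to_csv(outdir / "imaging_quant.csv", index=False)
    if "cohort" in report:
        report["cohort"].to_csv(outdir / "cohort_with_grades.csv", index=False)
    for marker, block in report.get("markers", {}).items():
        block["cutpoint"].scan_table().to_csv(
            outdir / f"cutpoint_scan_{marker}.csv", index=False
        )
        block["cox"].to_dataframe().to_csv(outdir / f"cox_{marker}_grade.csv", index=False)
        for label, curve in block["km"].items():
            curve.to_dataframe().to_csv(
                outdir / f"km_{marker}_grade_{label}.csv", index=False
            )
    with open(outdir / "summary.json", "w") as handle:
        json.dump(report["summary"], handle, indent=2, sort_keys=True)
    manifest = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "qdki67_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
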