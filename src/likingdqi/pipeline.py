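"""End-to-end orchestration: configuration, simulation to CSV, full analysis
runs, and report files.

This module is the programmatic face of the whole pipeline; the command-line
interface in :mod:`likingdqi.cli` is a thin wrapper around it.  All outputs
are tidy CSV plus a JSON manifest recording the configuration, seed and every
fitted quantity a reader needs to audit the run (selected penalties, retained
measures, merge map, orientation signs).
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

from .cohort import Cohort, CohortSpec, generate_cohort
from .crfs import build_crfs
from .dqi import (DQIConfig, empirical_dqi, hybrid_dqi, standardize_hybrid,
                  theoretical_dqi)
from .errors import ConfigurationError
from .survey import GroupSchema, load_biomarker_csv, load_survey_csv
from .validation import CVSpec, Dataset, compare_dqis, describe_dqi

__all__ = ["RunConfig", "simulate_to_csv", "load_dataset", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one analysis run.

    Exactly one input source must be given: either ``simulate_n`` (synthetic
    cohort of that size) or the survey/biomarker/covariate CSV paths.
    """

    seed: int
    simulate_n: int | None = None
    survey_csv: str | None = None
    biomarker_csv: str | None = None
    covariate_csv: str | None = None
    schema_path: str | None = None
    methods: tuple[str, ...] = ("theoretical", "empirical", "hybrid")
    cv_folds: tuple[int, ...] = (2, 5)
    n_repeats: int = 1
    loading_threshold: float = 0.4
    merge_threshold: float = 0.5
    merge_strategy: str = "average"
    lambda_grid: tuple[float, ...] | None = None
    out_dir: str = "results"

    def __post_init__(self) -> None:
        have_sim = self.simulate_n is not None
        have_data = all(p is not None for p in
                        (self.survey_csv, self.biomarker_csv, self.covariate_csv))
        if have_sim == have_data:
            raise ConfigurationError(
                "provide exactly one of simulate_n or the three data CSVs")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("methods", "cv_folds", "lambda_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def dqi_config(self, seed_offset: int = 0) -> DQIConfig:
        return DQIConfig(
            lambda_grid=self.lambda_grid,
            seed=self.seed + seed_offset,
            merge_threshold=self.merge_threshold,
            merge_strategy=self.merge_strategy,
        )


def _spec_manifest(spec: CohortSpec) -> dict:
    """Serializable view of the scalar cohort-spec fields (matrix targets are
    the shipped defaults unless the caller persisted them separately)."""
    return {
        "n": spec.n, "seed": spec.seed, "diet_variance": spec.diet_variance,
        "sex_effect": spec.sex_effect, "patient_effect": spec.patient_effect,
        "female_rate": spec.female_rate, "patient_rate": spec.patient_rate,
        "planted_weights": dict(spec.planted_weights),
        "patient_liking_shift": dict(spec.patient_liking_shift),
        "bp_coupling": spec.bp_coupling, "bp_shared": spec.bp_shared,
    }


def simulate_to_csv(spec: CohortSpec, out_dir) -> dict[str, str]:
    """Generate a cohort and write survey/biomarker/covariate CSVs plus a
    manifest that regenerates the identical cohort."""
    cohort = generate_cohort(spec)
    out = Path(out_dir)
    written = cohort.to_csv_dir(out)
    manifest = {"kind": "simulated-cohort", "spec": _spec_manifest(spec)}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["manifest"] = str(manifest_path)
    logger.info("simulated cohort of n=%d written to %s", spec.n, out)
    return written


def spec_from_manifest(path) -> CohortSpec:
    raw = json.loads(Path(path).read_text())["spec"]
    return CohortSpec(**raw)


def load_dataset(config: RunConfig) -> Dataset:
    """Materialize the analysis dataset from CSVs or by simulation."""
    schema = (GroupSchema.from_yaml(config.schema_path)
              if config.schema_path else GroupSchema.default())
    if config.simulate_n is not None:
        spec = dataclasses.replace(
            CohortSpec(), n=config.simulate_n, seed=config.seed)
        cohort = generate_cohort(spec, schema=schema)
        return Dataset(survey=cohort.survey, biomarkers=cohort.biomarkers,
                       covariates=cohort.covariates, schema=schema)
    survey = load_survey_csv(config.survey_csv)
    biomarkers = load_biomarker_csv(config.biomarker_csv)
    covariates = pd.read_csv(config.covariate_csv).set_index("subject_id")
    return Dataset(survey=survey, biomarkers=biomarkers,
                   covariates=covariates, schema=schema)


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the full analysis and write machine- and human-readable
    outputs.

    Stages: group scoring -> risk-score construction -> requested index
    builders -> 0-100 standardization (hybrid only) -> cross-validated
    comparison -> descriptives.  Returns the written file paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = load_dataset(config)
    views_cov = dataset.covariate_table()
    groups = dataset.group_table()
    food_groups = dataset.food_group_table()

    crfs_model, crfs_scores = build_crfs(
        dataset.biomarkers, threshold=config.loading_threshold)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "crfs": {
            "retained": list(crfs_model.retained),
            "excluded": list(crfs_model.screen.excluded),
            "explained_fraction": crfs_model.explained_fraction,
            "orientation": crfs_model.orientation,
        },
    }

    written: dict[str, str] = {}
    scores_out = pd.DataFrame({"crfs": crfs_scores})
    weight_tables = []
    ridge_used = False
    for method in config.methods:
        if method == "theoretical":
            result = theoretical_dqi(groups)
        elif method == "empirical":
            ridge_used = True
            result = empirical_dqi(dataset.survey, crfs_scores, views_cov,
                                   config.dqi_config())
        elif method == "hybrid":
            ridge_used = True
            result = hybrid_dqi(food_groups, crfs_scores, views_cov,
                                config.dqi_config())
        else:
            raise ConfigurationError(f"unknown method {method!r}")
        scores_out[f"dqi_{method}"] = result.scores
        weight_tables.append(pd.DataFrame({
            "method": method,
            "predictor": list(result.weights),
            "weight": list(result.weights.values()),
        }))
        manifest.setdefault("dqi", {})[method] = {
            "lambda": result.lam, "orientation": result.orientation,
            "merged_groups": ({k: list(v) for k, v in result.merged_groups.items()}
                              if result.merged_groups else None),
        }
        if method == "hybrid":
            scale = standardize_hybrid(result)
            scores_out["dqi_hybrid_0_100"] = scale.score(food_groups)
            scale_table = pd.DataFrame({
                "component": list(scale.components),
                "role": ["adequacy" if c in scale.adequacy else "moderation"
                         for c in scale.components],
                "normalized_weight": scale.normalized_weights.to_numpy(),
                "max_points": scale.max_points.to_numpy(),
            }).sort_values("max_points", ascending=False)
            p = out / "standardized_scale.csv"
            scale_table.to_csv(p, index=False)
            written["standardized_scale"] = str(p)
    if not ridge_used:
        logger.info("no ridge fitting performed (methods=%s)", config.methods)
    manifest["ridge_fitting_performed"] = ridge_used

    p = out / "scores.csv"
    scores_out.to_csv(p, index_label="subject_id")
    written["scores"] = str(p)
    p = out / "weights.csv"
    pd.concat(weight_tables, ignore_index=True).to_csv(p, index=False)
    written["weights"] = str(p)

    comparisons = []
    for k in config.cv_folds:
        spec = CVSpec(k=k, seed=config.seed, n_repeats=config.n_repeats)
        table = compare_dqis(dataset, spec, methods=tuple(config.methods),
                             config=config.dqi_config())
        comparisons.append(table.assign(method=table.index))
    comparison = pd.concat(comparisons, ignore_index=True)
    p = out / "comparison.csv"
    comparison.to_csv(p, index=False)
    written["comparison"] = str(p)

    desc_rows = {}
    patient = dataset.covariates["patient"]
    for col in scores_out.columns:
        if col == "crfs":
            continue
        desc_rows[col] = describe_dqi(scores_out[col], patient)
    descriptives = pd.DataFrame.from_dict(desc_rows, orient="index")
    p = out / "descriptives.csv"
    descriptives.to_csv(p, index_label="index")
    written["descriptives"] = str(p)

    report = _text_report(manifest, comparison, descriptives)
    p = out / "report.txt"
    p.write_text(report)
    written["report"] = str(p)
    p = out / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    written["manifest"] = str(p)
    return written


def _text_report(manifest, comparison: pd.DataFrame,
                 descriptives: pd.DataFrame) -> str:
    lines = ["Liking-based diet quality analysis", "=" * 40, ""]
    crfs = manifest["crfs"]
    lines += [
        "Cardiometabolic risk factor score:",
        f"  retained measures: {', '.join(crfs['retained'])}",
        f"  excluded measures: {', '.join(crfs['excluded']) or '(none)'}",
        f"  PC1 explained fraction: {crfs['explained_fraction']:.3f}",
        "",
        "Index descriptives (per-subject scores):",
        descriptives.round(4).to_string(),
        "",
        "Out-of-sample comparison (mean held-out R^2):",
        comparison.round(4).to_string(index=False),
        "",
    ]
    for method, info in manifest.get("dqi", {}).items():
        if info.get("merged_groups"):
            lines.append(f"{method} merged groups:")
            for name, members in info["merged_groups"].items():
                if len(members) > 1:
                    lines.append(f"  {name} <- {', '.join(members)}")
    return "\n".join(lines) + "\n"
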