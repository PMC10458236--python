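"""End-to-end orchestration: load -> prune -> split -> GA-VSS -> validation
-> model ranking -> full-model recalibration -> applicability domain ->
read-across / q-RASAR -> reliability scoring.

Every stage draws its randomness from a seed derived deterministically from
one global seed, so a study re-run with the same configuration is
numerically identical, and each stage can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import ad as ad_mod
from .dataset import DescriptorTable, assemble_modeling_sets, prune_descriptors
from .errors import QsarError
from .mcdm import rank_models
from .read_across import (
    RAConfig,
    default_hyperparameter_grid,
    fit_qrasar,
    optimize_ra_hyperparameters,
)
from .regression import GAConfig, MLRModel, SubsetResult, fit_ols, ga_vss
from .reliability import reliability_scores
from .splitting import SCHEMES, split
from .synthetic_data import default_mgmt_like_spec, generate
from .validation import ValidationReport, validate_model

_STAGE_OFFSETS = {
    "split": 1,
    "ga": 2,
    "lmo": 3,
    "scramble": 4,
    "ra": 5,
    "synth": 6,
}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from one global seed."""
    return (seed * 10007 + _STAGE_OFFSETS[stage] * 101) % (2**31)


@dataclasses.dataclass
class PipelineConfig:
    """Study configuration; defaults give a desk-scale but complete run."""

    input_csv: str | None = None  # None -> generate the default synthetic table
    schemes: Sequence[str] = SCHEMES
    outlier_ids: Sequence[str] = ()
    max_subset_size: int = 3
    ga_generations: int = 30
    ga_population: int = 40
    ga_mutation_pct: float = 20.0
    quik_delta: float = 0.05
    lmo_iterations: int = 2000
    yscr_iterations: int = 2000
    optimize_ra: bool = False
    ra_config: RAConfig = dataclasses.field(default_factory=RAConfig)
    qrasar_extra_descriptors: int = 2
    out_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        ra = raw.pop("ra_config", None)
        cfg = cls(**raw)
        if ra:
            cfg.ra_config = RAConfig(**ra)
        return cfg


@dataclasses.dataclass
class SchemeResult:
    scheme: str
    assignment: object
    best_subset: SubsetResult
    report: ValidationReport


@dataclasses.dataclass
class StudyResult:
    """Artifact bundle of one full study run."""

    modeling: DescriptorTable
    true_external: DescriptorTable
    removal_log: list[dict]
    scheme_results: dict[str, SchemeResult]
    ranking: pd.DataFrame
    best_scheme: str
    full_model: MLRModel
    full_report: ValidationReport
    williams: pd.DataFrame
    insubria: pd.DataFrame
    insubria_coverage: float
    qrasar_model: MLRModel
    qrasar_report: ValidationReport
    qrasar_full_model: MLRModel
    qrasar_full_report: ValidationReport
    reliability: pd.DataFrame
    log: list[str]


def _best_subset(results: dict[int, list[SubsetResult]]) -> SubsetResult:
    """Highest Q2_LOO across sizes; ties go to the smaller model."""
    candidates = [
        (res.q2_loo, -size, res)
        for size, items in results.items()
        for res in items[:1]
    ]
    if not candidates:
        raise QsarError("descriptor search produced no valid model")
    candidates.sort(key=lambda t: (t[0], t[1]), reverse=True)
    return candidates[0][2]


def run_full_study(config: PipelineConfig) -> StudyResult:
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(f"{datetime.datetime.now().isoformat(timespec='seconds')} {msg}")

    # -- load or synthesise --------------------------------------------------
    if config.input_csv is not None:
        table = DescriptorTable.read_csv(config.input_csv)
        outliers = list(config.outlier_ids)
        note(f"loaded {len(table)} compounds from {config.input_csv}")
    else:
        spec = default_mgmt_like_spec(seed=stage_seed(config.seed, "synth"))
        table, truth = generate(spec)
        outliers = truth.cliff_ids
        note(
            f"generated synthetic table: {len(table)} compounds, "
            f"{spec.n_censored} censored, {spec.n_cliff_outliers} cliffs"
        )

    pruned, removal_log = prune_descriptors(table)
    note(
        f"pruned descriptors: {len(table.descriptor_names)} -> "
        f"{len(pruned.descriptor_names)}"
    )
    modeling, true_external = assemble_modeling_sets(pruned, outliers)
    note(f"modeling set {len(modeling)}, true external set {len(true_external)}")

    # -- per-scheme split + descriptor search + validation -------------------
    scheme_results: dict[str, SchemeResult] = {}
    for scheme in config.schemes:
        assignment = split(modeling, scheme, seed=stage_seed(config.seed, "split"))
        train = modeling.subset(assignment.training_ids)
        pred = modeling.subset(assignment.prediction_ids)
        ga_cfg = GAConfig(
            max_subset_size=config.max_subset_size,
            generations_per_size=config.ga_generations,
            population_size=config.ga_population,
            mutation_rate_pct=config.ga_mutation_pct,
            quik_delta=config.quik_delta,
            rng_seed=stage_seed(config.seed, "ga"),
        )
        search = ga_vss(train.descriptors, train.y(), ga_cfg)
        best = _best_subset(search)
        model = fit_ols(
            train.descriptors[list(best.names)],
            train.y(),
            descriptor_names=list(best.names),
            training_ids=train.ids,
        )
        report = validate_model(
            model,
            X_pred=pred.descriptors[list(best.names)],
            y_pred=pred.y(),
            lmo_iterations=config.lmo_iterations,
            yscr_iterations=config.yscr_iterations,
            seed=stage_seed(config.seed, "lmo"),
        )
        scheme_results[scheme] = SchemeResult(scheme, assignment, best, report)
        note(
            f"{scheme}: {assignment.n_train}/{assignment.n_pred} split, "
            f"best subset {best.names} (Q2_LOO={best.q2_loo:.4f})"
        )

    ranking = rank_models(
        [r.report for r in scheme_results.values()], list(scheme_results)
    )
    best_scheme = str(ranking.iloc[0]["model_id"])
    note(f"best scheme by external MCDM: {best_scheme}")
    best = scheme_results[best_scheme]
    subset_names = list(best.best_subset.names)

    # -- full-model recalibration on the whole modeling set ------------------
    full_model = fit_ols(
        modeling.descriptors[subset_names],
        modeling.y(),
        descriptor_names=subset_names,
        training_ids=modeling.ids,
    )
    full_report = validate_model(
        full_model,
        lmo_iterations=config.lmo_iterations,
        yscr_iterations=config.yscr_iterations,
        seed=stage_seed(config.seed, "lmo"),
    )
    note(f"full model recalibrated on {full_model.n_train} compounds")

    # -- applicability domain ------------------------------------------------
    train_tbl = modeling.subset(best.assignment.training_ids)
    pred_tbl = modeling.subset(best.assignment.prediction_ids)
    split_model = fit_ols(
        train_tbl.descriptors[subset_names],
        train_tbl.y(),
        descriptor_names=subset_names,
        training_ids=train_tbl.ids,
    )
    williams = ad_mod.williams(split_model, train_tbl, pred_tbl)
    ext_X = true_external.descriptors[subset_names]
    insubria_tbl, coverage = ad_mod.insubria(full_model, ext_X)
    note(f"Insubria coverage of true externals: {coverage:.3f}")

    # -- read-across / q-RASAR ----------------------------------------------
    ra_cfg = config.ra_config
    if config.optimize_ra:
        ra_cfg, _ = optimize_ra_hyperparameters(
            train_tbl,
            default_hyperparameter_grid(ra_cfg.similarity),
            subset_names,
            seed=stage_seed(config.seed, "ra"),
        )
        note(f"optimised RA config: {ra_cfg}")
    configs = {
        "ED": dataclasses.replace(ra_cfg, similarity="ED"),
        "GK": dataclasses.replace(ra_cfg, similarity="GK"),
        "LK": dataclasses.replace(ra_cfg, similarity="LK"),
    }
    extra = [n for n in subset_names][: config.qrasar_extra_descriptors]
    qres = fit_qrasar(
        train_tbl,
        pred_tbl,
        descriptor_names=subset_names,
        feature_descriptors=extra,
        configs=configs,
        lmo_iterations=config.lmo_iterations,
        yscr_iterations=config.yscr_iterations,
        seed=stage_seed(config.seed, "ra"),
    )
    qres_full = fit_qrasar(
        modeling,
        None,
        descriptor_names=subset_names,
        feature_descriptors=extra,
        configs=configs,
        lmo_iterations=config.lmo_iterations,
        yscr_iterations=config.yscr_iterations,
        seed=stage_seed(config.seed, "ra"),
    )
    note("q-RASAR and q-RASAR-full models fitted")

    # -- reliability of true-external predictions ----------------------------
    reliability = reliability_scores(full_model, modeling, true_external)
    note(
        "reliability of true externals: "
        + ", ".join(
            f"{label}={int((reliability['score'] == s).sum())}"
            for s, label in ((3, "good"), (2, "moderate"), (1, "bad"))
        )
    )

    result = StudyResult(
        modeling=modeling,
        true_external=true_external,
        removal_log=removal_log,
        scheme_results=scheme_results,
        ranking=ranking,
        best_scheme=best_scheme,
        full_model=full_model,
        full_report=full_report,
        williams=williams,
        insubria=insubria_tbl,
        insubria_coverage=coverage,
        qrasar_model=qres.model,
        qrasar_report=qres.report,
        qrasar_full_model=qres_full.model,
        qrasar_full_report=qres_full.report,
        reliability=reliability,
        log=log,
    )
    if config.out_dir is not None:
        _write_artifacts(result, config, Path(config.out_dir))
    return result


def _write_artifacts(result: StudyResult, config: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for scheme, res in result.scheme_results.items():
        res.assignment.write_csv(out / f"split_{scheme}.csv")
        res.best_subset.model.write_json(out / f"model_{scheme}.json")
        res.report.write_json(out / f"validation_{scheme}.json")
    result.full_model.write_json(out / "model_full.json")
    result.full_report.write_json(out / "validation_full.json")
    result.qrasar_model.write_json(out / "model_qrasar.json")
    result.qrasar_report.write_json(out / "validation_qrasar.json")
    result.qrasar_full_model.write_json(out / "model_qrasar_full.json")
    result.qrasar_full_report.write_json(out / "validation_qrasar_full.json")
    result.ranking.to_csv(out / "mcdm_ranking.csv", index=False)
    result.williams.to_csv(out / "williams.csv", index=False)
    result.insubria.to_csv(out / "insubria.csv", index=False)
    result.reliability.to_csv(out / "reliability.csv")
    (out / "removal_log.json").write_text(json.dumps(result.removal_log, indent=2))
    (out / "study.log").write_text("\n".join(result.log) + "\n")
    (out / "config.json").write_text(
        json.dumps(
            {
                k: v
                for k, v in dataclasses.asdict(config).items()
                if not isinstance(v, (RAConfig,))
            },
            default=str,
            indent=2,
        )
    )
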