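"""End-to-end pipeline: simulate/extract → select → cross-validate → evaluate.

A run is driven by a :class:`PipelineConfig` (loadable from YAML).  One
base seed governs every stochastic stage through a documented derivation
(base seed + CRC32 of the stage name, modulo 2³¹), so stages are
independently reproducible.  Every JSON artifact is stamped with the
catalog version, the config hash and the seed; CSV artifacts carry the
same stamp as a leading ``#`` comment line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .catalog import CATALOG_VERSION
from .evaluation import evaluate_predictions
from .exceptions import ParameterError, StageError
from .model import (CrossValidationPlan, aggregate_predictions,
                    cross_validate_signature, roc_cutoff, stratify)
from .selection import select_features
from .synthetic import (FeatureCohortSpec, generate_feature_cohort,
                        replicate_feature_table)

log = logging.getLogger("vpiradiomics")


@dataclass
class PipelineConfig:
    """All knobs of a full run, with the study's default thresholds."""

    features_csv: str | None = None      # existing cases×features table …
    replicates_csv: str | None = None
    cohort: FeatureCohortSpec | None = None  # … or a synthetic cohort spec
    replicate_noise_scale: float = 0.05
    ccc_threshold: float = 0.9
    ccc_cap: int = 100
    redundancy_threshold: float = 0.05
    rfe_stop: float = 0.80
    n_repeats: int = 10
    n_folds: int = 10
    seed: int = 0
    out_dir: str = "pipeline_out"

    def __post_init__(self):
        if not (0 < self.ccc_threshold <= 1):
            raise ParameterError("ccc_threshold must be in (0, 1]")
        if not (0 <= self.redundancy_threshold < 1):
            raise ParameterError("redundancy_threshold must be in [0, 1)")
        if not (0 < self.rfe_stop <= 1):
            raise ParameterError("rfe_stop must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "cohort" in raw and raw["cohort"] is not None:
            raw["cohort"] = FeatureCohortSpec(**raw["cohort"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # where artifacts land is not a run parameter
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def stage_seed(base_seed: int, stage: str) -> int:
    """Per-stage seed: (base + CRC32(stage name)) mod 2³¹."""
    return (int(base_seed) + zlib.crc32(stage.encode())) % (2 ** 31)


def _stamp(config: PipelineConfig) -> dict:
    return {"catalog_version": CATALOG_VERSION,
            "config_hash": config.config_hash(), "seed": config.seed}


def _write_csv(df: pd.DataFrame, path: Path, config: PipelineConfig,
               index: bool = True) -> None:
    stamp = _stamp(config)
    header = (f"# catalog_version={stamp['catalog_version']} "
              f"config_hash={stamp['config_hash']} seed={stamp['seed']}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=index)


def read_artifact_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the stamp comment line."""
    return pd.read_csv(path, comment="#", **kwargs)


def _write_json(obj: dict, path: Path, config: PipelineConfig) -> None:
    obj = {**_stamp(config), **obj}
    path.write_text(json.dumps(obj, indent=2, default=float))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write artifacts; returns the evaluation report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> dict:
    # ---- stage: inputs -------------------------------------------------
    stage = "inputs"
    try:
        if config.features_csv:
            table = read_artifact_csv(config.features_csv, index_col="case_id")
            if config.replicates_csv is None:
                raise ParameterError("replicates_csv required with features_csv")
            replicate = read_artifact_csv(config.replicates_csv, index_col="case_id")
        else:
            spec = config.cohort or FeatureCohortSpec(
                seed=stage_seed(config.seed, "cohort"))
            table = generate_feature_cohort(spec)
            replicate = replicate_feature_table(
                table, noise_scale=config.replicate_noise_scale,
                seed=stage_seed(config.seed, "replicate"))
        labels = table["label"].to_numpy()
    except Exception as e:  # noqa: BLE001 - stage-named re-raise
        raise StageError(stage, str(e)) from e
    n_features = table.shape[1] - 1
    log.info("inputs: %d cases, %d features", len(table), n_features)
    _write_csv(table, out / "features.csv", config)
    _write_csv(replicate, out / "replicates.csv", config)

    # ---- stage: selection ---------------------------------------------
    stage = "selection"
    try:
        report = select_features(
            table.drop(columns="label"), replicate, labels,
            ccc_threshold=config.ccc_threshold, ccc_cap=config.ccc_cap,
            redundancy_threshold=config.redundancy_threshold,
            stop=config.rfe_stop)
    except Exception as e:
        raise StageError(stage, str(e)) from e
    log.info("selection: %d -> %d (CCC) -> %d (redundancy) -> %d (RFE, Σω=%.3f)",
             n_features, len(report.kept_after_ccc),
             len(report.kept_after_redundancy), len(report.selected),
             report.cumulative_weight)
    _write_json({"selection": report.as_dict()},
                out / "selection_report.json", config)

    # ---- stage: cross-validation ---------------------------------------
    stage = "crossval"
    try:
        plan = CrossValidationPlan(n_repeats=config.n_repeats,
                                   n_folds=config.n_folds,
                                   seed=stage_seed(config.seed, "crossval"))
        cv_table = table[["label"] + report.kept_after_redundancy]
        predictions = cross_validate_signature(
            cv_table, plan=plan, select=True, rfe_stop=config.rfe_stop)
        aggregated = aggregate_predictions(predictions)
    except Exception as e:
        raise StageError(stage, str(e)) from e
    log.info("crossval: %d out-of-fold predictions over %d repeats",
             len(predictions), plan.n_repeats)

    # ---- stage: cutoff + evaluation ------------------------------------
    stage = "evaluate"
    try:
        cut = roc_cutoff(aggregated["pi"], aggregated["label"])
        aggregated = aggregated.assign(
            risk_group=stratify(aggregated["pi"], cut.pi_cutoff))
        predictions = predictions.assign(
            risk_group=stratify(predictions["pi"], cut.pi_cutoff))
        evaluation = evaluate_predictions(aggregated, cut.pi_cutoff)
        evaluation["roc_cutoff"] = cut.roc_cutoff
        evaluation["youden"] = cut.youden
    except Exception as e:
        raise StageError(stage, str(e)) from e
    log.info("evaluate: AUC %.3f, cutoff Pi %.3f",
             evaluation["auc"]["auc"], cut.pi_cutoff)
    _write_csv(predictions, out / "predictions.csv", config, index=False)
    _write_csv(aggregated, out / "predictions_aggregated.csv", config, index=False)
    _write_json({"evaluation": evaluation}, out / "evaluation_report.json", config)
    return evaluation


def demo_config(out_dir: str = "demo_out", seed: int = 7) -> PipelineConfig:
    """A small bundled synthetic run that finishes in well under a minute."""
    cohort = FeatureCohortSpec(n_vpi_neg=60, n_vpi_pos=45, n_noise_features=10,
                               seed=stage_seed(seed, "cohort"))
    return PipelineConfig(cohort=cohort, n_repeats=2, n_folds=10,
                          seed=seed, out_dir=out_dir)
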