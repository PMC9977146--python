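"""End-to-end experiment orchestration.

One config drives the feature-set comparison protocol: for each named run
(a feature family plus classifier settings), assemble the cohort feature
table, evaluate it by leave-one-out cross-validation, optionally rerun the
whole pipeline on shuffled labels, and write all artifacts (per-run
predictions, metrics with CIs, selected features, null distributions and a
comparison table) under one output directory.  Every number in the report
is a deterministic function of the config and the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify, features, shm
from .airr_io import Cohort, load_cohort

logger = logging.getLogger(__name__)

#: named feature-set runs (mirrors the standard feature-family comparison)
RUN_PRESETS: dict[str, dict] = {
    "cdr3_3mer": {"families": ("cdr3_kmers",)},
    "v_usage": {"families": ("v_usage",)},
    "vj_usage": {"families": ("vj_usage",)},
    "vjl_clusters": {"families": ("vjl_clusters",)},
    "cdr3_identity_clusters": {"families": ("cdr3_identity_clusters",)},
    "shm_5mer_all": {"families": ("shm_5mer",)},
    "shm_wa_tw": {"families": ("shm_wa_tw",)},
    "shm_wrc_gyw": {"families": ("shm_wrc_gyw",)},
    "shm_synonymous": {"families": ("shm_synonymous",)},
    "shm_3mer": {"families": ("shm_3mer",)},
}

_SHM_FAMILIES = {"shm_5mer", "shm_3mer", "shm_wa_tw", "shm_wrc_gyw"}


def derive_seed(master_seed: int, name: str) -> int:
    """Deterministic named sub-seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class ExperimentConfig:
    """Everything one experiment needs; loadable from YAML."""

    manifest: str | None = None
    runs: list[str] = field(default_factory=lambda: ["v_usage", "shm_5mer_all"])
    top_k: int = 30
    selection_scope: str = "per_fold"
    n_permutations: int = 0
    min_background: int = 10
    master_seed: int = 0
    out_dir: str = "experiment_out"
    tuning: classify.ElasticNetTuning = field(
        default_factory=classify.ElasticNetTuning
    )

    def __post_init__(self) -> None:
        if len(set(self.runs)) != len(self.runs):
            raise ValueError("run names must be unique")
        unknown = [r for r in self.runs if r not in RUN_PRESETS]
        if unknown:
            raise ValueError(f"unknown run(s) {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        tuning = classify.ElasticNetTuning(**data.pop("tuning", {}))
        return cls(tuning=tuning, **data)

    def to_dict(self) -> dict:
        return {
            "manifest": self.manifest,
            "runs": list(self.runs),
            "top_k": self.top_k,
            "selection_scope": self.selection_scope,
            "n_permutations": self.n_permutations,
            "min_background": self.min_background,
            "master_seed": self.master_seed,
            "out_dir": self.out_dir,
            "tuning": self.tuning.__dict__,
        }


@dataclass
class ExperimentReport:
    """Per-run results plus a cross-run comparison table."""

    results: dict[str, classify.CVResult]
    nulls: dict[str, pd.DataFrame]
    failures: dict[str, str]
    comparison: pd.DataFrame


def shm_models_for_cohort(
    cohort: Cohort, min_background: int = 10
) -> dict[str, shm.TargetingModel]:
    """Per-subject all-mutation targeting models, estimated once."""
    return {
        rep.subject_id: shm.estimate_targeting_model(
            rep, min_background=min_background
        )
        for rep in cohort.repertoires
    }


def assemble_run_table(
    cohort: Cohort,
    run: str,
    min_background: int = 10,
    shm_models: dict[str, shm.TargetingModel] | None = None,
) -> features.FeatureTable:
    preset = RUN_PRESETS[run]
    return features.assemble_feature_table(
        cohort,
        families=preset["families"],
        min_background=min_background,
        shm_models=shm_models,
        **{k: v for k, v in preset.items() if k != "families"},
    )


def run_experiment(
    config: ExperimentConfig, cohort: Cohort | None = None
) -> ExperimentReport:
    """Execute every configured run; failures are recorded, not fatal."""
    if cohort is None:
        if config.manifest is None:
            raise ValueError("config needs a manifest when no cohort is given")
        cohort = load_cohort(config.manifest)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    shared_models = None
    if any(set(RUN_PRESETS[r]["families"]) & _SHM_FAMILIES for r in config.runs):
        t0 = time.perf_counter()
        shared_models = shm_models_for_cohort(cohort, config.min_background)
        logger.info("estimated %d targeting models in %.1fs",
                    len(shared_models), time.perf_counter() - t0)

    results: dict[str, classify.CVResult] = {}
    nulls: dict[str, pd.DataFrame] = {}
    failures: dict[str, str] = {}
    for run in config.runs:
        t0 = time.perf_counter()
        try:
            table = assemble_run_table(
                cohort, run, config.min_background, shared_models
            )
            result = classify.loo_cross_validate(
                table,
                cohort.labels,
                top_k=config.top_k,
                tuning=config.tuning,
                selection_scope=config.selection_scope,
                seed=derive_seed(config.master_seed, f"loo:{run}"),
            )
            results[run] = result
            with open(out_dir / f"{run}_cv.json", "w") as fh:
                json.dump(result.to_json_dict(), fh, indent=1)
            if config.n_permutations > 0:
                null = classify.shuffled_label_null(
                    table,
                    cohort.labels,
                    n_permutations=config.n_permutations,
                    top_k=config.top_k,
                    tuning=config.tuning,
                    selection_scope=config.selection_scope,
                    seed=derive_seed(config.master_seed, f"null:{run}"),
                )
                nulls[run] = null
                null.to_csv(out_dir / f"{run}_null.tsv", sep="\t")
            logger.info("run %s: %d features, F1=%s (%.1fs)", run,
                        table.values.shape[1], result.metrics["f1"]["value"],
                        time.perf_counter() - t0)
        except Exception as exc:  # noqa: BLE001 - per-run isolation
            logger.exception("run %s failed", run)
            failures[run] = f"{type(exc).__name__}: {exc}"

    rows = []
    for run, result in results.items():
        row = {"run": run}
        for m in ("f1", "accuracy", "sensitivity", "specificity"):
            entry = result.metrics[m]
            row[m] = entry["value"]
            if entry["ci95"]:
                row[f"{m}_ci_low"], row[f"{m}_ci_high"] = entry["ci95"]
        if run in nulls:
            row["null_f1_median"] = float(nulls[run]["f1"].median())
        rows.append(row)
    comparison = pd.DataFrame(rows).set_index("run") if rows else pd.DataFrame()
    if len(comparison):
        comparison.to_csv(out_dir / "comparison.tsv", sep="\t")
    if failures:
        with open(out_dir / "failures.json", "w") as fh:
            json.dump(failures, fh, indent=1)
    return ExperimentReport(results, nulls, failures, comparison)


def run_transfer(
    train_cohort: Cohort,
    test_cohort: Cohort,
    run: str = "shm_5mer_all",
    top_k: int = 30,
    tuning: classify.ElasticNetTuning | None = None,
    min_background: int = 10,
    master_seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Train on one cohort, score another; returns the four headline metrics."""
    tuning = tuning or classify.ElasticNetTuning()
    train_table = assemble_run_table(train_cohort, run, min_background)
    test_table = assemble_run_table(test_cohort, run, min_background)
    metrics, coef_report, predictions = classify.cross_cohort_transfer(
        train_table,
        train_cohort.labels,
        test_table,
        test_cohort.labels,
        top_k=top_k,
        tuning=tuning,
        seed=derive_seed(master_seed, f"transfer:{run}"),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        coef_report.to_tsv(out_dir / f"transfer_{run}_coefficients.tsv")
        predictions.to_csv(out_dir / f"transfer_{run}_predictions.tsv", sep="\t")
        with open(out_dir / f"transfer_{run}_metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=1)
    return metrics
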