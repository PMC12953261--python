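"""End-to-end study runner and report rendering.

``run_study`` ties the stages together on one synthetic cohort: base-model
nested cross-validation (model-table style CSV), stacked models, the
sequential cascade with its traffic-light report, the PHQ-9 cutoff baseline,
and the depressed-subgroup GMM subtyping (cluster-profile CSV).  Every
rendered number is re-derivable from the serialized intermediate artifacts in
the output bundle, percentages are rendered to one decimal, and a single
global seed fans out to per-stage seeds through a documented hash so stages
can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import clustering as clus
from . import evaluation as ev
from . import models as _models
from . import preprocessing as prep
from . import sequential as seq
from .cohort import CohortTable, GeneratorSpec, sample_cohort


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: first four little-endian bytes of
    sha256(f"{global_seed}:{stage}"), mod 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class ExperimentConfig:
    """Serializable configuration of one full study run."""

    seed: int = 0
    n_total: int = 581
    n_depressed: int = 90
    missing_rate: float = 0.05
    base_models: Sequence[str] | None = ("Somatic metrics", "HRV", "Clinical 15")
    stack_members: Sequence[str] = ("Somatic metrics", "HRV", "Clinical 15")
    tau_grid: Sequence[float] = seq.DEFAULT_TAU_GRID
    phq9_cutoff: float = 8
    clustering_enabled: bool = True
    cluster_k_grid: Sequence[int] = tuple(range(2, 9))
    cluster_cov_grid: Sequence[str] = clus.COVARIANCE_STRUCTURES
    cluster_n_init: int = 10
    output_dir: str = "study_output"
    verbosity: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["base_models"] = list(self.base_models) if self.base_models else None
        d["stack_members"] = list(self.stack_members)
        d["tau_grid"] = [float(t) for t in self.tau_grid]
        d["cluster_k_grid"] = list(self.cluster_k_grid)
        d["cluster_cov_grid"] = list(self.cluster_cov_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)


@dataclass
class StudyBundle:
    output_dir: Path
    artifacts: dict[str, Path] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return all(v == "ok" for v in self.status.values())


def base_model_table(reports: Sequence[ev.CVReport],
                     registry: dict[str, _models.ModalityModelSpec]) -> pd.DataFrame:
    """Model-table style summary: one row per base model with mean nested-CV
    BAC / sensitivity / specificity as one-decimal percentages."""
    rows = []
    for rep in reports:
        spec = registry[rep.model_name]
        rows.append({
            "model": spec.name,
            "model_type": spec.model_type,
            "modalities": spec.modalities,
            "features": spec.feature_count,
            "pipeline": spec.pipeline,
            "BAC": round(100 * rep.mean_balanced_accuracy, 1),
            "Sens": round(100 * rep.mean_sensitivity, 1),
            "Spec": round(100 * rep.mean_specificity, 1),
        })
    return pd.DataFrame(rows)


def evaluate_stack_nested(
    cohort: CohortTable,
    plan: ev.FoldPlan,
    member_specs: Sequence[_models.ModalityModelSpec],
    seed: int,
) -> ev.CVReport:
    """Nested-CV evaluation of a stacked model: per outer fold, the logistic
    meta-learner is trained on out-of-fold member probabilities computed
    inside the outer-training split only."""
    y = cohort.labels
    fold_metrics = []
    for k in range(plan.n_outer):
        tr_idx, te_idx = plan.outer_split(k)
        train_tab = CohortTable(df=cohort.df.iloc[tr_idx].reset_index(drop=True),
                                dictionary=cohort.dictionary, item_scales=cohort.item_scales)
        test_tab = CohortTable(df=cohort.df.iloc[te_idx].reset_index(drop=True),
                               dictionary=cohort.dictionary, item_scales=cohort.item_scales)
        oof = seq.member_oof_probabilities(member_specs, train_tab, seed=seed + k)
        stack = seq.train_stacker(seq.StackSpec(tuple(s.name for s in member_specs)),
                                  oof, train_tab.labels, seed=seed + k)
        test_probs = np.column_stack([
            _models.predict_proba(
                _models.train_base_model(s, train_tab, seed=seed + k + 29 * j), test_tab
            ).probabilities
            for j, s in enumerate(member_specs)
        ])
        pred = (stack.predict_proba(test_probs) > 0.5).astype(int)
        fold_metrics.append(ev.metric_triple(y[te_idx], pred))
    return ev.CVReport(model_name="Stack(" + ", ".join(s.name for s in member_specs) + ")",
                       seed=seed, fold_metrics=fold_metrics)


def cluster_depressed(
    cohort: CohortTable,
    k_grid: Sequence[int] = tuple(range(2, 9)),
    cov_grid: Sequence[str] = clus.COVARIANCE_STRUCTURES,
    seed: int = 0,
    n_init: int = 10,
    knn_k: int = 7,
):
    """Impute + transform the depressed biomarker block, select and fit the
    mixture, profile and name the clusters.

    Returns (selection, solution, profile_table, labels, depressed_df).
    """
    dep_df = cohort.df[cohort.df["diagnosis"] == 1].reset_index(drop=True)
    feats = clus.biomarker_features(cohort)
    raw = dep_df[feats]
    imputed = prep.fit_apply_knn_impute(raw, raw, k=min(knn_k, len(raw)))
    transformed, _ = prep.fit_apply_yeo_johnson(imputed, imputed)
    selection = clus.select_gmm(transformed, k_grid=k_grid, cov_grid=cov_grid,
                                seed=seed, n_init=n_init)
    solution = clus.fit_assign(transformed, k=selection.chosen.k,
                               covariance=selection.chosen.covariance,
                               seed=seed, n_init=n_init)
    # profiling and naming use imputed but untransformed values (plus age)
    profile_df = imputed.copy()
    profile_df["age_years"] = dep_df["age_years"].to_numpy()
    profile = clus.profile_clusters(solution.assignments, profile_df)
    labels = clus.label_clusters(solution.assignments, profile_df)
    return selection, solution, profile, labels, dep_df


def run_study(config: ExperimentConfig) -> StudyBundle:
    """Run the full study on a synthetic cohort and write the report bundle.

    A failing stage marks the bundle incomplete but preserves the artifacts
    of the stages that already ran.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = StudyBundle(output_dir=out)
    log: list[str] = [f"config: {json.dumps(config.to_dict())}",
                      f"python: {platform.python_version()}"]

    gen_spec = GeneratorSpec(n_total=config.n_total, n_depressed=config.n_depressed,
                             missing_rate=config.missing_rate,
                             seed=stage_seed(config.seed, "generate"))
    cohort = sample_cohort(gen_spec)
    cohort.write(out / "cohort.csv")
    bundle.artifacts["cohort"] = out / "cohort.csv"
    bundle.status["generate"] = "ok"
    log.append(f"generate: n={cohort.n}, depressed={int(cohort.labels.sum())}, "
               f"seed={gen_spec.seed}")

    registry = _models.load_registry()
    plan = ev.make_fold_plan(cohort.labels, seed=stage_seed(config.seed, "folds"))

    def _stage(name, fn):
        try:
            fn()
            bundle.status[name] = "ok"
        except Exception as exc:  # keep earlier artifacts on partial failure
            bundle.status[name] = f"failed: {exc}"
            log.append(f"{name} FAILED:\n{traceback.format_exc()}")

    def _base():
        names = list(config.base_models) if config.base_models else list(registry)
        reports = [ev.evaluate_nested(registry[n], cohort, plan,
                                      seed=stage_seed(config.seed, f"base:{n}"))
                   for n in names]
        table = base_model_table(reports, registry)
        table.to_csv(out / "base_models.csv", index=False)
        (out / "base_models.json").write_text(json.dumps(
            [r.to_json_dict() for r in reports], indent=1))
        bundle.artifacts["base_models"] = out / "base_models.csv"
        log.append("base models:\n" + table.to_string(index=False))

    def _stack():
        members = [registry[n] for n in config.stack_members]
        rep = evaluate_stack_nested(cohort, plan, members,
                                    seed=stage_seed(config.seed, "stack"))
        (out / "stacked_models.json").write_text(json.dumps(rep.to_json_dict(), indent=1))
        bundle.artifacts["stacked_models"] = out / "stacked_models.json"
        log.append(f"stack mean BAC {rep.mean_balanced_accuracy:.3f}")

    def _sequential():
        rep, routing, light, policies = seq.evaluate_sequential_nested(
            cohort, plan, registry["Clinical 15"], tau_grid=config.tau_grid,
            seed=stage_seed(config.seed, "sequential"))
        payload = {
            "cv": rep.to_json_dict(),
            "propagated_fraction": routing.propagated_fraction,
            "policies": [{"steps": list(p.step_names), "taus": list(p.taus)}
                         for p in policies],
            "traffic_light": light.to_json_dict(),
        }
        (out / "sequential.json").write_text(json.dumps(payload, indent=1))
        (out / "traffic_light.md").write_text(
            seq.render_traffic_table({"Clinical 15 (including second step)": light}))
        bundle.artifacts["sequential"] = out / "sequential.json"
        bundle.artifacts["traffic_light"] = out / "traffic_light.md"
        log.append(f"sequential mean BAC {rep.mean_balanced_accuracy:.3f}, "
                   f"propagated {routing.propagated_fraction[0]:.2f}")

    def _phq9():
        # the cutoff rule needs an observed total; score the complete cases
        observed = cohort.df["phq9_total"].notna().to_numpy()
        sub = CohortTable(df=cohort.df[observed].reset_index(drop=True),
                          dictionary=cohort.dictionary, item_scales=cohort.item_scales)
        m = ev.phq9_cutoff_baseline(sub, cutoff=config.phq9_cutoff)
        payload = {"cutoff": config.phq9_cutoff,
                   "n_scored": int(observed.sum()),
                   "balanced_accuracy": m.balanced_accuracy,
                   "sensitivity": m.sensitivity, "specificity": m.specificity,
                   "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn}
        (out / "phq9_baseline.json").write_text(json.dumps(payload, indent=1))
        bundle.artifacts["phq9_baseline"] = out / "phq9_baseline.json"
        log.append(f"PHQ-9 > {config.phq9_cutoff} baseline BAC {m.balanced_accuracy:.3f}")

    _stage("base_models", _base)
    _stage("stacked_models", _stack)
    _stage("sequential", _sequential)
    _stage("phq9_baseline", _phq9)

    if config.clustering_enabled:
        def _cluster():
            selection, solution, profile, labels, _dep = cluster_depressed(
                cohort, k_grid=config.cluster_k_grid, cov_grid=config.cluster_cov_grid,
                seed=stage_seed(config.seed, "cluster"), n_init=config.cluster_n_init)
            profile.as_dataframe().to_csv(out / "cluster_profiles.csv", index=False)
            payload = {
                "chosen": {"k": selection.chosen.k,
                           "covariance": selection.chosen.covariance,
                           "bic": selection.chosen.bic},
                "cluster_sizes": profile.cluster_sizes,
                "labels": {str(k): v for k, v in labels.labels.items()},
                "diagnostics": labels.diagnostics,
                "candidates": [{"k": c.k, "cov": c.covariance, "bic": c.bic,
                                "aic": c.aic, "silhouette": c.silhouette}
                               for c in selection.candidates],
            }
            (out / "cluster_summary.json").write_text(json.dumps(payload, indent=1))
            bundle.artifacts["cluster_profiles"] = out / "cluster_profiles.csv"
            bundle.artifacts["cluster_summary"] = out / "cluster_summary.json"
            log.append(f"clustering: k={selection.chosen.k} "
                       f"({selection.chosen.covariance}), sizes {profile.cluster_sizes}")
        _stage("clustering", _cluster)

    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    manifest = {"config": config.to_dict(),
                "status": bundle.status,
                "complete": bundle.complete,
                "artifacts": {k: str(v) for k, v in bundle.artifacts.items()}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle.artifacts["manifest"] = out / "manifest.json"
    return bundle
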