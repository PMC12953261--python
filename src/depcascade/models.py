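"""Training pipelines and the modality base-model registry.

Four pipelines cover the modality-specific base models:

* **P1** — gradient-boosted trees only, for small feature sets; no
  preprocessing or selection stages.
* **P2** — Boruta all-relevant selection, then boosted trees.
* **P3** — Boruta, then the greedy forward wrapper, then boosted trees;
  trades a little accuracy for far fewer features.
* **P4** — standardization, principal-component projection (components kept
  until 80% of training variance is explained) and a linear-kernel
  maximum-margin classifier whose decision scores are calibrated to
  probabilities with a held-in logistic fit, for highly collinear blocks
  (HRV, blood panel).

Booster hyperparameters are fixed (300 rounds, depth 3, learning rate 0.1,
subsample 0.8): no tuning grid keeps the nested cross-validation honest and
cheap.  A tie at probability exactly 0.5 predicts non-depressed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC
from xgboost import XGBClassifier

from . import preprocessing as prep
from .cohort import CohortTable
from .exceptions import SchemaError
from .selection import boruta_importance_ranking, boruta_select, greedy_forward_select

PIPELINE_IDS = ("P1", "P2", "P3", "P4")

_REGISTRY_FILE = importlib.resources.files("depcascade.data") / "model_registry.yaml"


@dataclass(frozen=True)
class ModalityModelSpec:
    """One registry row: a named feature set bound to a pipeline."""

    name: str
    modalities: str
    features: tuple[str, ...]
    feature_count: int          # printed count (registry metadata)
    pipeline: str
    model_type: str = "Base"

    def __post_init__(self) -> None:
        if self.pipeline not in PIPELINE_IDS:
            raise ValueError(f"unknown pipeline id '{self.pipeline}'")


@dataclass(frozen=True)
class PipelineBlueprint:
    pipeline: str
    stages: tuple[str, ...]

    @property
    def selection_stages(self) -> tuple[str, ...]:
        return tuple(s for s in self.stages if s in ("boruta", "greedy"))


@dataclass
class TrainedModel:
    spec: ModalityModelSpec
    pipeline: str
    seed: int
    merge_map: dict = field(repr=False, default_factory=dict)
    impute_plan: object = field(repr=False, default=None)
    encoded_columns: list[str] = field(default_factory=list)
    selected_features: list[str] = field(default_factory=list)
    importances: dict[str, float] = field(default_factory=dict)
    predictor: object = field(repr=False, default=None)
    std_plan: object = field(repr=False, default=None)
    pca: object = field(repr=False, default=None)
    calibrator: object = field(repr=False, default=None)
    cat_levels: dict[str, list[str]] = field(repr=False, default_factory=dict)


@dataclass
class PredictionSet:
    case_ids: list[str]
    probabilities: np.ndarray

    @property
    def labels(self) -> np.ndarray:
        # tie at exactly 0.5 -> non-depressed (screening favours specificity)
        return (self.probabilities > 0.5).astype(int)


def default_booster(seed: int = 0) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=300, max_depth=3, learning_rate=0.1, subsample=0.8,
        tree_method="hist", n_jobs=1, random_state=seed,
        eval_metric="logloss", verbosity=0,
    )


def build_pipeline(pipeline_id: str) -> PipelineBlueprint:
    """The stage sequence of one training pipeline."""
    stages = {
        "P1": ("boost",),
        "P2": ("boruta", "boost"),
        "P3": ("boruta", "greedy", "boost"),
        "P4": ("standardize", "pca", "svm_calibrated"),
    }
    if pipeline_id not in stages:
        raise ValueError(f"unknown pipeline id '{pipeline_id}'")
    return PipelineBlueprint(pipeline=pipeline_id, stages=stages[pipeline_id])


def load_registry(path=None) -> dict[str, ModalityModelSpec]:
    """The nine-model registry keyed by model name, in table order."""
    text = _REGISTRY_FILE.read_text() if path is None else open(path).read()
    raw = yaml.safe_load(text)
    registry = {}
    for row in raw["models"]:
        spec = ModalityModelSpec(
            name=row["name"],
            modalities=row["modalities"],
            features=tuple(row["features"]),
            feature_count=int(row["feature_count"]),
            pipeline=row["pipeline"],
            model_type=row.get("model_type", "Base"),
        )
        registry[spec.name] = spec
    return registry


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------


def _split_types(spec: ModalityModelSpec, table: CohortTable) -> tuple[list[str], list[str]]:
    missing = [f for f in spec.features if f not in table.df.columns]
    if missing:
        raise SchemaError(f"model '{spec.name}' is missing features: {missing}")
    cat = [f for f in spec.features if table.dictionary.get(f, {}).get("vtype") == "categorical"]
    num = [f for f in spec.features if f not in cat]
    return num, cat


def _encode(df: pd.DataFrame, num: list[str], cat: list[str],
            cat_levels: dict[str, list[str]]) -> pd.DataFrame:
    parts = [df[num].astype(float)] if num else []
    for c in cat:
        for lev in cat_levels[c]:
            parts.append((df[c].astype(str) == lev).astype(float).rename(f"{c}={lev}"))
    return pd.concat(parts, axis=1)


def train_base_model(
    spec: ModalityModelSpec,
    train: CohortTable,
    weights: np.ndarray | None = None,
    seed: int = 0,
    inner_fold_ids: np.ndarray | None = None,
    rare_threshold: float = 0.05,
    knn_k: int = 7,
) -> TrainedModel:
    """Fit one registry model on a training split only.

    Rare-category aggregation, KNN imputation, selection and the classifier
    are all fitted on ``train``; the returned model carries every fitted
    plan so :func:`predict_proba` can replay it on raw held-out rows.
    """
    y = train.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training split contains a single class")
    if weights is None:
        from .evaluation import balanced_weights
        weights = balanced_weights(y)
    num, cat = _split_types(spec, train)
    raw = train.df[list(spec.features)]

    merge_map = prep.fit_rare_aggregator(raw[cat], rare_threshold) if cat else {}
    X = prep.apply_rare_aggregator(raw, merge_map)
    knn_k_eff = min(knn_k, len(X))
    impute_plan = prep.fit_knn_imputer(X, k=knn_k_eff, categorical=cat)
    X = prep.apply_knn_imputer(impute_plan, X)
    cat_levels = {c: sorted(X[c].dropna().astype(str).unique()) for c in cat}
    Xe = _encode(X, num, cat, cat_levels)

    model = TrainedModel(
        spec=spec, pipeline=spec.pipeline, seed=seed,
        merge_map=merge_map, impute_plan=impute_plan,
        encoded_columns=list(Xe.columns), cat_levels=cat_levels,
    )

    if spec.pipeline == "P4":
        std = prep.fit_standardizer(Xe)
        Z = prep.apply_standardizer(std, Xe).to_numpy()
        n_comp = min(Z.shape[0] - 1, Z.shape[1])
        pca = PCA(n_components=n_comp, random_state=seed).fit(Z)
        keep = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_), 0.80) + 1)
        keep = min(keep, n_comp)
        pca = PCA(n_components=keep, random_state=seed).fit(Z)
        P = pca.transform(Z)
        svm = LinearSVC(C=1.0, random_state=seed, max_iter=20000)
        svm.fit(P, y, sample_weight=weights)
        scores = svm.decision_function(P)
        calib = LogisticRegression(random_state=seed)
        calib.fit(scores.reshape(-1, 1), y, sample_weight=weights)
        model.std_plan, model.pca, model.predictor, model.calibrator = std, pca, svm, calib
        model.selected_features = list(Xe.columns)
        raw_imp = np.abs(pca.components_.T @ svm.coef_.ravel())
        model.importances = {f: float(v) for f, v in zip(Xe.columns, raw_imp)}
        return model

    selected = list(Xe.columns)
    if spec.pipeline in ("P2", "P3"):
        res = boruta_select(Xe, y, seed=seed)
        selected = res.confirmed or boruta_importance_ranking(res)[:1]
        if spec.pipeline == "P3":
            trace = greedy_forward_select(Xe, y, candidate_features=selected, seed=seed)
            selected = trace.selected
    booster = default_booster(seed)
    booster.fit(Xe[selected].to_numpy(), y, sample_weight=weights)
    gains = booster.get_booster().get_score(importance_type="gain")
    imp = {f: float(gains.get(f"f{j}", 0.0)) for j, f in enumerate(selected)}
    model.predictor = booster
    model.selected_features = selected
    model.importances = imp
    return model


def predict_proba(model: TrainedModel, cases: CohortTable) -> PredictionSet:
    """Apply the fitted plans and predictor to raw (pre-selection) cases."""
    spec = model.spec
    num, cat = _split_types(spec, cases)
    raw = cases.df[list(spec.features)]
    X = prep.apply_rare_aggregator(raw, model.merge_map)
    X = prep.apply_knn_imputer(model.impute_plan, X)
    Xe = _encode(X, num, cat, model.cat_levels)
    for col in model.encoded_columns:       # unseen level columns -> 0
        if col not in Xe:
            Xe[col] = 0.0
    Xe = Xe[model.encoded_columns]
    if model.pipeline == "P4":
        Z = prep.apply_standardizer(model.std_plan, Xe).to_numpy()
        scores = model.predictor.decision_function(model.pca.transform(Z))
        p = model.calibrator.predict_proba(scores.reshape(-1, 1))[:, 1]
    else:
        p = model.predictor.predict_proba(Xe[model.selected_features].to_numpy())[:, 1]
    ids = list(cases.df.get("participant_id", pd.RangeIndex(len(cases.df)).astype(str)))
    return PredictionSet(case_ids=ids, probabilities=np.asarray(p, dtype=float))


def top_k_features(model: TrainedModel, k: int) -> list[str]:
    """The k most important selected features, importance descending, ties by
    name ascending."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(model.selected_features):
        raise ValueError(f"k={k} exceeds the {len(model.selected_features)} selected features")
    order = sorted(model.selected_features, key=lambda f: (-model.importances[f], f))
    return order[:k]


def derive_clinical15(cohort: CohortTable, seed: int = 0) -> list[str]:
    """One Boruta importance pass over the 26 WHO-5 + PHQ-9 + WHODAS items;
    the top 15 by median importance.  Used once to freeze the shipped
    registry list."""
    pool = [c for c in cohort.df.columns
            if c.startswith(("who5_i", "phq9_i", "whodas_i"))]
    res = boruta_select(cohort.df[pool], cohort.labels, seed=seed)
    return boruta_importance_ranking(res)[:15]
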