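"""Nested cross-validation, class-balanced weighting, and screening metrics.

All models are scored with balanced accuracy (BAC), sensitivity and
specificity, with the depression diagnosis as the positive class.  Model
selection and threshold tuning happen strictly inside the outer-training
split (inner folds); each outer-test split is predicted exactly once.  The
engine hashes every outer-test block before and after fitting and raises if
a fitting stage modified held-out cells.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .exceptions import LeakageError
from . import cohort as _cohort

MIN_CLASS_COUNT = 10  # each of 5 stratified folds must hold both classes


@dataclass(frozen=True)
class MetricTriple:
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass(frozen=True)
class FoldPlan:
    """Stratified 5x5 fold assignments: outer folds over all cases, inner
    folds over each outer-training split."""

    outer: np.ndarray                      # (n,) outer fold id per case
    inner: tuple[np.ndarray, ...]          # per outer fold: inner ids over outer-train rows
    seed: int
    n_outer: int = 5
    n_inner: int = 5

    def outer_split(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.where(self.outer == k)[0]
        train = np.where(self.outer != k)[0]
        return train, test


@dataclass
class CVReport:
    model_name: str
    seed: int
    fold_metrics: list[MetricTriple]
    fold_details: list[dict] = field(default_factory=list)

    @property
    def mean_balanced_accuracy(self) -> float:
        return float(np.mean([m.balanced_accuracy for m in self.fold_metrics]))

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean([m.sensitivity for m in self.fold_metrics]))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean([m.specificity for m in self.fold_metrics]))

    def pooled_confusion(self) -> MetricTriple:
        """Alternative aggregation: metrics from the summed confusion counts."""
        tp = sum(m.tp for m in self.fold_metrics)
        fp = sum(m.fp for m in self.fold_metrics)
        tn = sum(m.tn for m in self.fold_metrics)
        fn = sum(m.fn for m in self.fold_metrics)
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        return MetricTriple((sens + spec) / 2, sens, spec, tp, fp, tn, fn)

    def to_json_dict(self) -> dict:
        return {
            "model": self.model_name,
            "seed": self.seed,
            "mean": {
                "balanced_accuracy": self.mean_balanced_accuracy,
                "sensitivity": self.mean_sensitivity,
                "specificity": self.mean_specificity,
            },
            "folds": [
                {
                    "balanced_accuracy": m.balanced_accuracy,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
                }
                for m in self.fold_metrics
            ],
        }


def balanced_weights(labels: np.ndarray) -> np.ndarray:
    """Per-case weights n_total / (2 * n_class): each class contributes the
    same total weight."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to balance weights")
    n = len(labels)
    w = {c: n / (2.0 * k) for c, k in zip(classes, counts)}
    return np.array([w[c] for c in labels], dtype=float)


def metric_triple(y_true: np.ndarray, y_pred: np.ndarray) -> MetricTriple:
    """Balanced accuracy, sensitivity and specificity (depression = positive)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if len(np.unique(y_true)) < 2:
        raise ValueError("y_true must contain both classes")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return MetricTriple((sens + spec) / 2.0, sens, spec, tp, fp, tn, fn)


def make_fold_plan(labels: np.ndarray, seed: int, n_outer: int = 5, n_inner: int = 5) -> FoldPlan:
    """Stratified outer folds plus per-outer-fold stratified inner folds."""
    labels = np.asarray(labels, dtype=int)
    _, counts = np.unique(labels, return_counts=True)
    if len(counts) < 2 or counts.min() < MIN_CLASS_COUNT:
        raise ValueError(
            f"each class needs at least {MIN_CLASS_COUNT} cases for stratified "
            f"{n_outer}x{n_inner} folds; got class counts {counts.tolist()}"
        )
    outer = np.empty(len(labels), dtype=int)
    okf = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed)
    for k, (_, test) in enumerate(okf.split(np.zeros(len(labels)), labels)):
        outer[test] = k
    inner = []
    for k in range(n_outer):
        tr = np.where(outer != k)[0]
        inner_ids = np.empty(len(tr), dtype=int)
        ikf = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=seed + 1 + k)
        for j, (_, test) in enumerate(ikf.split(np.zeros(len(tr)), labels[tr])):
            inner_ids[test] = j
        inner.append(inner_ids)
    return FoldPlan(outer=outer, inner=tuple(inner), seed=seed,
                    n_outer=n_outer, n_inner=n_inner)


def _hash_rows(df: pd.DataFrame) -> str:
    payload = df.to_csv(index=True).encode()
    return hashlib.sha256(payload).hexdigest()


def evaluate_nested(
    spec,
    cohort: "_cohort.CohortTable",
    plan: FoldPlan,
    seed: int | None = None,
) -> CVReport:
    """Nested-CV evaluation of one registry model (or composite spec).

    For every outer fold, imputation / selection / tuning are fitted on the
    outer-training rows only (with the plan's inner folds available to the
    pipeline), and the outer-test rows are predicted once.  Outer-test cells
    are hash-checked around the fit; a mutated byte raises
    :class:`~depcascade.exceptions.LeakageError`.
    """
    from . import models as _models

    seed = plan.seed if seed is None else seed
    labels = cohort.labels
    fold_metrics: list[MetricTriple] = []
    details: list[dict] = []
    for k in range(plan.n_outer):
        tr_idx, te_idx = plan.outer_split(k)
        train_tab = _cohort.CohortTable(
            df=cohort.df.iloc[tr_idx].reset_index(drop=True),
            dictionary=cohort.dictionary,
            item_scales=cohort.item_scales,
        )
        test_df = cohort.df.iloc[te_idx]
        before = _hash_rows(test_df)
        weights = balanced_weights(labels[tr_idx])
        model = _models.train_base_model(
            spec, train_tab, weights=weights, seed=seed + 101 * k,
            inner_fold_ids=plan.inner[k],
        )
        after = _hash_rows(cohort.df.iloc[te_idx])
        if before != after:
            raise LeakageError(f"outer-test rows of fold {k} changed during fitting")
        test_tab = _cohort.CohortTable(
            df=test_df.reset_index(drop=True),
            dictionary=cohort.dictionary,
            item_scales=cohort.item_scales,
        )
        pred = _models.predict_proba(model, test_tab)
        fold_metrics.append(metric_triple(labels[te_idx], pred.labels))
        details.append({"fold": k, "n_test": len(te_idx),
                        "selected_features": list(model.selected_features)})
    name = getattr(spec, "name", str(spec))
    return CVReport(model_name=name, seed=seed, fold_metrics=fold_metrics,
                    fold_details=details)


def phq9_cutoff_baseline(cohort: "_cohort.CohortTable", cutoff: float = 8) -> MetricTriple:
    """Screening baseline: positive iff the PHQ-9 total is strictly above the
    cutoff (default > 8), scored against the diagnosis label on the full
    cohort."""
    totals = cohort.df["phq9_total"]
    if totals.isna().any():
        missing = list(cohort.df.loc[totals.isna(), _cohort.ID_COLUMN])
        raise ValueError(f"PHQ-9 totals missing for cases: {missing}")
    screen = (totals.to_numpy(dtype=float) > cutoff).astype(int)
    return metric_triple(cohort.labels, screen)
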