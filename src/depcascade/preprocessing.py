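"""Fold-safe feature engineering.

Every transform here follows the fit-on-train / apply-anywhere contract: the
fit step sees only the training split, and the fitted plan is applied
unchanged to held-out rows.  This is what keeps the nested cross-validation
in :mod:`depcascade.evaluation` leakage-free.

Stages:

* rare-category aggregation — categories below a training-frequency threshold
  collapse into a single ``"other"`` level (default threshold 5%),
* k-nearest-neighbour imputation (default k=7) under a nan-aware Euclidean
  distance with standardized continuous coordinates and one-hot categorical
  coordinates of unit weight per feature,
* standardization,
* Yeo-Johnson power transformation (maximum-likelihood lambda per feature,
  standardized output) used before clustering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances
from sklearn.preprocessing import PowerTransformer

RARE_LEVEL = "other"


# ---------------------------------------------------------------------------
# rare-category aggregation
# ---------------------------------------------------------------------------


def fit_rare_aggregator(
    train_columns: pd.DataFrame, threshold: float = 0.05
) -> dict[str, dict[str, str]]:
    """Merge map for categorical columns: level -> retained level.

    A category observed on strictly less than ``threshold`` of the training
    rows maps to :data:`RARE_LEVEL`; categories at or above the threshold map
    to themselves.  Unseen categories at apply time also map to
    :data:`RARE_LEVEL`.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    merge_map: dict[str, dict[str, str]] = {}
    for col in train_columns.columns:
        s = train_columns[col]
        if pd.api.types.is_numeric_dtype(s):
            raise TypeError(f"column '{col}' is not categorical")
        freq = s.dropna().value_counts(normalize=True)
        merge_map[col] = {
            str(cat): (str(cat) if frac >= threshold else RARE_LEVEL)
            for cat, frac in freq.items()
        }
    return merge_map


def apply_rare_aggregator(columns: pd.DataFrame, merge_map: Mapping[str, Mapping[str, str]]) -> pd.DataFrame:
    out = columns.copy()
    for col, mapping in merge_map.items():
        if col not in out:
            continue
        s = out[col].astype(object)
        out[col] = s.where(s.isna(), s.map(lambda v: mapping.get(str(v), RARE_LEVEL)))
    return out


# ---------------------------------------------------------------------------
# KNN imputation (mixed types)
# ---------------------------------------------------------------------------


@dataclass
class KNNImputePlan:
    """Fitted state of the mixed-type KNN imputer."""

    k: int
    continuous: list[str]
    categorical: list[str]
    means: np.ndarray
    sds: np.ndarray
    cat_levels: dict[str, list[str]]
    train_design: np.ndarray = field(repr=False)
    train_cont: np.ndarray = field(repr=False)
    train_cat: pd.DataFrame = field(repr=False)


def fit_knn_imputer(train: pd.DataFrame, k: int = 7,
                    categorical: list[str] | None = None) -> KNNImputePlan:
    """Fit the imputation reference set on a training split.

    Distances are nan-aware Euclidean over standardized continuous
    coordinates plus one-hot categorical coordinates scaled so one feature
    mismatch contributes 1 to the squared distance.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(train):
        raise ValueError(f"k={k} exceeds the {len(train)} training rows")
    categorical = list(categorical or [c for c in train.columns
                                       if not pd.api.types.is_numeric_dtype(train[c])])
    continuous = [c for c in train.columns if c not in categorical]
    cont = train[continuous].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan columns
        means = np.nanmean(cont, axis=0) if cont.size else np.empty(0)
        sds = np.nanstd(cont, axis=0) if cont.size else np.empty(0)
    means = np.nan_to_num(means)
    sds = np.where(np.isfinite(sds) & (sds > 0), sds, 1.0)
    cat_levels = {c: sorted(train[c].dropna().astype(str).unique()) for c in categorical}
    plan = KNNImputePlan(
        k=k, continuous=continuous, categorical=categorical,
        means=means, sds=sds, cat_levels=cat_levels,
        train_design=np.empty(0), train_cont=cont, train_cat=train[categorical].copy(),
    )
    plan.train_design = _design(train, plan)
    return plan


def _design(df: pd.DataFrame, plan: KNNImputePlan) -> np.ndarray:
    parts = []
    if plan.continuous:
        cont = df[plan.continuous].to_numpy(dtype=float)
        parts.append((cont - plan.means) / plan.sds)
    for c in plan.categorical:
        levels = plan.cat_levels[c]
        col = df[c].astype(object)
        onehot = np.full((len(df), max(len(levels), 1)), np.nan)
        observed = col.notna().to_numpy()
        vals = col.astype(str).to_numpy()
        for j, lev in enumerate(levels):
            onehot[observed, j] = (vals[observed] == lev).astype(float)
        # scale so a single categorical mismatch contributes 1, not 2
        parts.append(onehot / np.sqrt(2.0))
    return np.hstack(parts) if parts else np.empty((len(df), 0))


def apply_knn_imputer(plan: KNNImputePlan, apply_to: pd.DataFrame) -> pd.DataFrame:
    """Replace missing cells by the mean (continuous) or mode (categorical,
    ties to the lexicographically first level) of the k nearest training rows.
    Observed cells are untouched."""
    out = apply_to.copy()
    design = _design(apply_to, plan)
    fully_missing = np.all(np.isnan(design), axis=1) if design.shape[1] else np.zeros(len(out), bool)
    if fully_missing.any():
        rows = list(apply_to.index[fully_missing])
        raise ValueError(f"rows with every feature missing cannot be imputed: {rows}")
    has_missing = apply_to.isna().any(axis=1).to_numpy()
    if not has_missing.any():
        return out
    dist = nan_euclidean_distances(design[has_missing], plan.train_design)
    # nearest k training rows per apply row (self-distance 0 is fine when
    # apply_to is the training split: the row's own observed values win)
    nn = np.argsort(dist, axis=1, kind="stable")[:, : plan.k]
    rows = np.where(has_missing)[0]
    for r_local, r in enumerate(rows):
        neigh = nn[r_local]
        for j, c in enumerate(plan.continuous):
            if np.isnan(out.iloc[r, out.columns.get_loc(c)]):
                vals = plan.train_cont[neigh, j]
                vals = vals[~np.isnan(vals)]
                fill = vals.mean() if vals.size else plan.means[j]
                out.iloc[r, out.columns.get_loc(c)] = fill
        for c in plan.categorical:
            if pd.isna(out.iloc[r, out.columns.get_loc(c)]):
                vals = plan.train_cat[c].iloc[neigh].dropna().astype(str)
                if len(vals):
                    counts = vals.value_counts()
                    top = counts.max()
                    fill = sorted(counts[counts == top].index)[0]
                else:
                    fill = None
                out.iloc[r, out.columns.get_loc(c)] = fill
    return out


def fit_apply_knn_impute(train: pd.DataFrame, apply_to: pd.DataFrame, k: int = 7,
                         categorical: list[str] | None = None) -> pd.DataFrame:
    """Convenience wrapper: fit on ``train``, impute ``apply_to``."""
    plan = fit_knn_imputer(train, k=k, categorical=categorical)
    return apply_knn_imputer(plan, apply_to)


# ---------------------------------------------------------------------------
# standardization & Yeo-Johnson
# ---------------------------------------------------------------------------


@dataclass
class StandardizePlan:
    columns: list[str]
    means: np.ndarray
    sds: np.ndarray


def fit_standardizer(train: pd.DataFrame) -> StandardizePlan:
    X = train.to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    return StandardizePlan(list(train.columns), means, sds)


def apply_standardizer(plan: StandardizePlan, df: pd.DataFrame) -> pd.DataFrame:
    X = df[plan.columns].to_numpy(dtype=float)
    return pd.DataFrame((X - plan.means) / plan.sds, index=df.index, columns=plan.columns)


@dataclass
class YeoJohnsonPlan:
    """Per-feature maximum-likelihood power-transform parameters."""

    columns: list[str]
    lambdas: np.ndarray
    post_means: np.ndarray
    post_sds: np.ndarray
    constant: np.ndarray  # flags features returned as identity


def yeo_johnson(x: np.ndarray, lam: float) -> np.ndarray:
    """The Yeo-Johnson transform, defined for all real x and monotone in x."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    if abs(lam) > 1e-12:
        out[pos] = ((x[pos] + 1.0) ** lam - 1.0) / lam
    else:
        out[pos] = np.log1p(x[pos])
    if abs(lam - 2.0) > 1e-12:
        out[~pos] = -(((-x[~pos] + 1.0) ** (2.0 - lam)) - 1.0) / (2.0 - lam)
    else:
        out[~pos] = -np.log1p(-x[~pos])
    return out


def fit_yeo_johnson(train: pd.DataFrame) -> YeoJohnsonPlan:
    """Fit lambda per feature by maximum likelihood on the training split.

    Constant features cannot identify a lambda; they are flagged and passed
    through as identity (lambda = 1) with a warning.
    """
    if train.isna().any().any():
        raise ValueError("Yeo-Johnson requires complete data; impute first")
    cols = list(train.columns)
    X = train.to_numpy(dtype=float)
    constant = X.std(axis=0) == 0
    lambdas = np.ones(len(cols))
    if (~constant).any():
        pt = PowerTransformer(method="yeo-johnson", standardize=False)
        pt.fit(X[:, ~constant])
        lambdas[~constant] = pt.lambdas_
    if constant.any():
        warnings.warn(
            f"constant features passed through untransformed: "
            f"{[c for c, f in zip(cols, constant) if f]}"
        )
    transformed = np.column_stack([yeo_johnson(X[:, j], lambdas[j]) for j in range(len(cols))])
    post_means = transformed.mean(axis=0)
    post_sds = transformed.std(axis=0)
    post_sds = np.where(post_sds > 0, post_sds, 1.0)
    return YeoJohnsonPlan(cols, lambdas, post_means, post_sds, constant)


def apply_yeo_johnson(plan: YeoJohnsonPlan, df: pd.DataFrame) -> pd.DataFrame:
    X = df[plan.columns].to_numpy(dtype=float)
    T = np.column_stack([yeo_johnson(X[:, j], plan.lambdas[j]) for j in range(len(plan.columns))])
    T = (T - plan.post_means) / plan.post_sds
    return pd.DataFrame(T, index=df.index, columns=plan.columns)


def fit_apply_yeo_johnson(train: pd.DataFrame, apply_to: pd.DataFrame) -> tuple[pd.DataFrame, YeoJohnsonPlan]:
    plan = fit_yeo_johnson(train)
    return apply_yeo_johnson(plan, apply_to), plan


# ---------------------------------------------------------------------------
# serialization (audit)
# ---------------------------------------------------------------------------


def plan_to_json(merge_map=None, yj_plan: YeoJohnsonPlan | None = None,
                 std_plan: StandardizePlan | None = None) -> str:
    payload = {}
    if merge_map is not None:
        payload["rare_merge_map"] = {k: dict(v) for k, v in merge_map.items()}
    if std_plan is not None:
        payload["standardize"] = {
            "columns": std_plan.columns,
            "means": std_plan.means.tolist(),
            "sds": std_plan.sds.tolist(),
        }
    if yj_plan is not None:
        payload["yeo_johnson"] = {
            "columns": yj_plan.columns,
            "lambdas": yj_plan.lambdas.tolist(),
            "post_means": yj_plan.post_means.tolist(),
            "post_sds": yj_plan.post_sds.tolist(),
            "constant": yj_plan.constant.astype(bool).tolist(),
        }
    return json.dumps(payload, indent=1)
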