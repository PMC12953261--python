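"""Data-driven subtyping of the depressed group.

A Gaussian mixture model is fitted to the biomarker block only — laboratory
values, HRV indices and anthropometrics; questionnaire data are excluded by a
modality-tag filter.  Features are KNN-imputed and Yeo-Johnson-transformed
before clustering; the number of components and covariance structure are
selected over a grid by BIC (AIC and silhouette reported alongside).
Clusters are profiled on the imputed but untransformed data with a
normality-gated test battery (Shapiro-Wilk at alpha=0.05: one-way ANOVA +
Tukey HSD when normal, Kruskal-Wallis with rank eta-squared + Dunn's
Bonferroni post hoc otherwise; chi-square with pairwise Bonferroni
chi-squares for categoricals) and named post hoc by a biomarker ruleset
(autonomic dysregulation + inflammation -> Immuno-Metabolic, high BMI
without inflammation -> Overweight Non-Inflammatory, oldest remaining ->
Late Depression, remainder -> Adaptive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from .cohort import CohortTable

BIOMARKER_MODALITIES = ("lab", "physiological", "anthropometric")
COVARIANCE_STRUCTURES = ("full", "tied", "diag", "spherical")


def biomarker_features(cohort: CohortTable) -> list[str]:
    """Clustering consumes only lab, HRV and anthropometric columns; no
    questionnaire data."""
    return cohort.feature_columns(modalities=list(BIOMARKER_MODALITIES))


# ---------------------------------------------------------------------------
# model selection and fitting
# ---------------------------------------------------------------------------


@dataclass
class GMMCandidate:
    k: int
    covariance: str
    aic: float
    bic: float
    silhouette: float | None
    n_parameters: int
    converged: bool
    log_likelihood: float


@dataclass
class GMMSelection:
    candidates: list[GMMCandidate]
    chosen: GMMCandidate

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.candidates])


@dataclass
class ClusterSolution:
    k: int
    covariance: str
    weights: np.ndarray
    means: np.ndarray
    assignments: np.ndarray
    responsibilities: np.ndarray
    seed: int
    n_init: int
    converged: bool
    log_likelihood: float
    bic: float
    model: GaussianMixture = field(repr=False, default=None)


def _fit_gmm(X: np.ndarray, k: int, covariance: str, seed: int, n_init: int) -> GaussianMixture:
    gm = GaussianMixture(
        n_components=k, covariance_type=covariance, n_init=n_init,
        random_state=seed, reg_covar=1e-6, max_iter=500,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(X)
    return gm


def select_gmm(
    X: np.ndarray | pd.DataFrame,
    k_grid: Sequence[int] = tuple(range(2, 9)),
    cov_grid: Sequence[str] = COVARIANCE_STRUCTURES,
    seed: int = 0,
    n_init: int = 10,
) -> GMMSelection:
    """Scan (k, covariance) candidates; choose the BIC minimizer (ties go to
    the candidate with fewer free parameters).

    Every candidate is fitted by EM with ``n_init`` restarts.  Candidates
    whose EM did not converge are flagged, not dropped.  Silhouette is
    reported on hard assignments (defined only for k >= 2).
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("clustering input must be complete; impute first")
    if X.shape[0] <= max(k_grid):
        raise ValueError("need more samples than the largest candidate k")
    candidates = []
    for cov in cov_grid:
        for k in k_grid:
            gm = _fit_gmm(X, k, cov, seed, n_init)
            labels = gm.predict(X)
            sil = None
            if k >= 2 and len(np.unique(labels)) >= 2:
                sil = float(silhouette_score(X, labels))
            candidates.append(GMMCandidate(
                k=k, covariance=cov, aic=float(gm.aic(X)), bic=float(gm.bic(X)),
                silhouette=sil, n_parameters=int(gm._n_parameters()),
                converged=bool(gm.converged_),
                log_likelihood=float(gm.score(X) * X.shape[0]),
            ))
    chosen = min(candidates, key=lambda c: (c.bic, c.n_parameters))
    return GMMSelection(candidates=candidates, chosen=chosen)


def fit_assign(
    X: np.ndarray | pd.DataFrame,
    k: int = 4,
    covariance: str = "full",
    seed: int = 0,
    n_init: int = 10,
) -> ClusterSolution:
    """Fit the chosen mixture (best of ``n_init`` restarts) and hard-assign
    cases by maximum responsibility."""
    X = np.asarray(X, dtype=float)
    gm = _fit_gmm(X, k, covariance, seed, n_init)
    resp = gm.predict_proba(X)
    return ClusterSolution(
        k=k, covariance=covariance, weights=gm.weights_.copy(), means=gm.means_.copy(),
        assignments=np.argmax(resp, axis=1), responsibilities=resp,
        seed=seed, n_init=n_init, converged=bool(gm.converged_),
        log_likelihood=float(gm.score(X) * X.shape[0]), bic=float(gm.bic(X)), model=gm,
    )


# ---------------------------------------------------------------------------
# post-hoc profiling
# ---------------------------------------------------------------------------


def dunn_posthoc(values: np.ndarray, groups: np.ndarray) -> list[dict]:
    """Dunn's rank-based pairwise test with Bonferroni correction."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ranks = stats.rankdata(values)
    n = len(values)
    # tie correction for the rank variance
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    labels = np.unique(groups)
    pairs = list(combinations(labels, 2))
    out = []
    for a, b in pairs:
        ra, rb = ranks[groups == a], ranks[groups == b]
        na, nb = len(ra), len(rb)
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        z = (ra.mean() - rb.mean()) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        out.append({"pair": (a, b), "statistic": float(z),
                    "p_adjusted": float(min(1.0, p * len(pairs)))})
    return out


def _pairwise_chi2(series: pd.Series, groups: np.ndarray) -> list[dict]:
    labels = np.unique(groups)
    pairs = list(combinations(labels, 2))
    out = []
    for a, b in pairs:
        sel = (groups == a) | (groups == b)
        tab = pd.crosstab(series[sel], groups[sel])
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            continue
        chi2, p, _, _ = stats.chi2_contingency(tab)
        out.append({"pair": (a, b), "statistic": float(chi2),
                    "p_adjusted": float(min(1.0, p * len(pairs)))})
    return out


@dataclass
class ClusterProfileTable:
    rows: list[dict]
    cluster_sizes: dict[int, int]
    skipped: list[tuple[str, str]]

    def as_dataframe(self) -> pd.DataFrame:
        flat = []
        for r in self.rows:
            rec = {"variable": r["variable"], "test": r["test"],
                   "statistic": r["statistic"], "p_value": r["p_value"],
                   "effect_size": r.get("effect_size")}
            for c, desc in r["per_cluster"].items():
                rec[f"cluster_{c}"] = desc
            flat.append(rec)
        return pd.DataFrame(flat)

    def row(self, variable: str) -> dict:
        for r in self.rows:
            if r["variable"] == variable:
                return r
        raise KeyError(variable)


def profile_clusters(
    assignments: np.ndarray,
    raw: pd.DataFrame,
    categorical: Sequence[str] | None = None,
    alpha_normality: float = 0.05,
) -> ClusterProfileTable:
    """Compare clusters variable-by-variable on imputed, untransformed data.

    Continuous variables pass a pooled Shapiro-Wilk normality gate: normal ->
    one-way ANOVA with Tukey HSD post hoc; non-normal -> Kruskal-Wallis with
    rank eta-squared (H - k + 1)/(n - k) and Dunn's Bonferroni post hoc.
    Categorical variables get an omnibus chi-square with pairwise Bonferroni
    chi-squares.  Variables with a cluster below 2 cases, or constant
    variables, are skipped with a warning.
    """
    assignments = np.asarray(assignments)
    if len(assignments) != len(raw):
        raise ValueError("assignments and table have different lengths")
    categorical = list(categorical or [c for c in raw.columns
                                       if not pd.api.types.is_numeric_dtype(raw[c])])
    clusters = np.unique(assignments)
    k = len(clusters)
    sizes = {int(c): int((assignments == c).sum()) for c in clusters}
    rows, skipped = [], []
    for col in raw.columns:
        s = raw[col]
        obs = s.notna().to_numpy()
        groups = [s[(assignments == c) & obs] for c in clusters]
        if any(len(g) < 2 for g in groups):
            skipped.append((col, "cluster with fewer than 2 cases"))
            warnings.warn(f"variable '{col}' skipped: cluster below 2 cases")
            continue
        if col in categorical:
            tab = pd.crosstab(s[obs], assignments[obs])
            if tab.shape[0] < 2:
                skipped.append((col, "constant variable"))
                warnings.warn(f"variable '{col}' skipped: constant")
                continue
            chi2, p, _, _ = stats.chi2_contingency(tab)
            per = {int(c): {str(lev): float((g == lev).mean()) for lev in tab.index}
                   for c, g in zip(clusters, groups)}
            rows.append({"variable": col, "test": "chi2", "statistic": float(chi2),
                         "p_value": float(p), "per_cluster": per,
                         "posthoc": _pairwise_chi2(s[obs], assignments[obs]) if p < 0.05 else []})
            continue
        vals = s[obs].to_numpy(dtype=float)
        if np.all(vals == vals[0]):
            skipped.append((col, "constant variable"))
            warnings.warn(f"variable '{col}' skipped: constant")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normal = stats.shapiro(vals if len(vals) <= 5000 else vals[:5000]).pvalue > alpha_normality
        per = {int(c): (float(g.mean()), float(g.std(ddof=1))) for c, g in zip(clusters, groups)}
        garr = [g.to_numpy(dtype=float) for g in groups]
        if normal:
            stat, p = stats.f_oneway(*garr)
            posthoc = []
            if p < 0.05:
                res = stats.tukey_hsd(*garr)
                for i, j in combinations(range(k), 2):
                    posthoc.append({"pair": (int(clusters[i]), int(clusters[j])),
                                    "statistic": float(res.statistic[i, j]),
                                    "p_adjusted": float(res.pvalue[i, j])})
            rows.append({"variable": col, "test": "anova", "statistic": float(stat),
                         "p_value": float(p), "per_cluster": per, "posthoc": posthoc})
        else:
            stat, p = stats.kruskal(*garr)
            n = sum(len(g) for g in garr)
            eta2 = (stat - k + 1) / (n - k)
            posthoc = dunn_posthoc(vals, assignments[obs]) if p < 0.05 else []
            rows.append({"variable": col, "test": "kruskal", "statistic": float(stat),
                         "p_value": float(p), "effect_size": float(eta2),
                         "per_cluster": per, "posthoc": posthoc})
    return ClusterProfileTable(rows=rows, cluster_sizes=sizes, skipped=skipped)


# ---------------------------------------------------------------------------
# post-hoc naming
# ---------------------------------------------------------------------------

#: biomarker columns driving the naming rules
RULE_FEATURES = {
    "crp": "crp_mg_dl",
    "sdnn": "hrv_sdnn_lying_ms",
    "baevskii": "hrv_baevskii_lying",
    "bmi": "bmi",
    "age": "age_years",
}


@dataclass
class ClusterLabels:
    labels: dict[int, str | None]
    diagnostics: list[str]

    @property
    def resolved(self) -> bool:
        return all(v is not None for v in self.labels.values())


def label_clusters(
    assignments: np.ndarray,
    raw: pd.DataFrame,
    rule_features: dict[str, str] = RULE_FEATURES,
) -> ClusterLabels:
    """Name a 4-cluster solution from its raw biomarker means.

    Rules: the cluster with the highest CRP, lowest SDNN and highest Baevskii
    stress index (majority of the three indicators) is Immuno-Metabolic; the
    highest-BMI remaining cluster is Overweight Non-Inflammatory; the oldest
    remaining cluster is Late Depression; the last is Adaptive.  Exact ties
    on a deciding feature leave the affected clusters unlabelled with a
    diagnostic.
    """
    assignments = np.asarray(assignments)
    clusters = sorted(int(c) for c in np.unique(assignments))
    diagnostics: list[str] = []
    if len(clusters) != 4:
        return ClusterLabels(labels={c: None for c in clusters},
                             diagnostics=[f"labelling needs k=4, got k={len(clusters)}"])
    means = {
        key: {c: float(raw.loc[assignments == c, col].mean()) for c in clusters}
        for key, col in rule_features.items()
    }

    def _argbest(key, pool, sign):
        vals = {c: sign * means[key][c] for c in pool}
        best = max(vals.values())
        winners = [c for c in pool if vals[c] == best]
        if len(winners) > 1:
            diagnostics.append(f"tie on '{key}' among clusters {winners}")
            return None
        return winners[0]

    labels: dict[int, str | None] = {c: None for c in clusters}
    votes = [_argbest("crp", clusters, +1), _argbest("sdnn", clusters, -1),
             _argbest("baevskii", clusters, +1)]
    votes = [v for v in votes if v is not None]
    if not votes:
        return ClusterLabels(labels=labels, diagnostics=diagnostics or ["no deciding votes"])
    counts = pd.Series(votes).value_counts()
    if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
        diagnostics.append(f"immuno-metabolic indicators disagree: votes {votes}")
        return ClusterLabels(labels=labels, diagnostics=diagnostics)
    im = int(counts.index[0])
    labels[im] = "ImmunoMetabolic"
    remaining = [c for c in clusters if c != im]
    oni = _argbest("bmi", remaining, +1)
    if oni is None:
        return ClusterLabels(labels=labels, diagnostics=diagnostics)
    labels[oni] = "OverweightNonInflammatory"
    remaining = [c for c in remaining if c != oni]
    late = _argbest("age", remaining, +1)
    if late is None:
        return ClusterLabels(labels=labels, diagnostics=diagnostics)
    labels[late] = "LateDepression"
    last = [c for c in remaining if c != late][0]
    labels[last] = "Adaptive"
    return ClusterLabels(labels=labels, diagnostics=diagnostics)
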