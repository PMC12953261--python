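"""GMM selection/fitting, post-hoc test battery, and cluster naming."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from depcascade import preprocessing as prep
from depcascade.clustering import (
    biomarker_features,
    dunn_posthoc,
    fit_assign,
    label_clusters,
    profile_clusters,
    select_gmm,
)
from depcascade.cohort import GeneratorSpec, sample_cohort


@pytest.fixture(scope="module")
def planted_depressed():
    """360 depressed participants with the four planted biomarker subtypes,
    imputation-free, Yeo-Johnson-transformed clustering space."""
    dep = sample_cohort(GeneratorSpec(n_total=360, n_depressed=360, seed=0))
    X = dep.df[biomarker_features(dep)]
    T, _ = prep.fit_apply_yeo_johnson(X, X)
    return dep, T


class TestModalityFilter:
    def test_only_biomarker_modalities_enter_clustering(self, planted_depressed):
        dep, _ = planted_depressed
        feats = biomarker_features(dep)
        for f in feats:
            assert dep.dictionary[f]["modality"] in ("lab", "physiological", "anthropometric")
        assert not any(f.startswith(("phq", "who5", "whodas", "gad", "ucla",
                                     "pcptsd", "lsns", "madrs")) for f in feats)
        assert "age_years" not in feats


class TestSelection:
    def test_two_separated_gaussians_choose_k2(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = np.vstack([rng.normal(0, 1, (150, 2)), rng.normal(5, 1, (150, 2))])
            sel = select_gmm(X, k_grid=range(1, 6), seed=seed, n_init=3)
            hits += sel.chosen.k == 2
        assert hits >= 4

    def test_k1_has_bic_but_no_silhouette(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (100, 3))
        sel = select_gmm(X, k_grid=[1, 2], cov_grid=["diag"], seed=1, n_init=2)
        k1 = [c for c in sel.candidates if c.k == 1][0]
        assert k1.silhouette is None and np.isfinite(k1.bic)

    def test_bic_likelihood_identity(self, planted_depressed):
        """BIC = -2 logL + n_params ln(n) for every candidate."""
        _, T = planted_depressed
        sel = select_gmm(T, k_grid=[2, 4], cov_grid=["diag", "spherical"], seed=0, n_init=2)
        n = len(T)
        for c in sel.candidates:
            assert abs(c.bic - (-2 * c.log_likelihood + c.n_parameters * np.log(n))) < 1e-6

    def test_incomplete_input_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="complete"):
            select_gmm(X, k_grid=[2], seed=0)


class TestFitAssign:
    def test_responsibilities_and_hard_assignment(self, planted_depressed):
        _, T = planted_depressed
        sol = fit_assign(T, k=4, covariance="diag", seed=0, n_init=3)
        assert np.allclose(sol.responsibilities.sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(sol.assignments, sol.responsibilities.argmax(axis=1))
        assert sol.weights.sum() == pytest.approx(1.0)

    def test_more_restarts_never_hurt_likelihood(self, planted_depressed):
        _, T = planted_depressed
        one = fit_assign(T, k=4, covariance="diag", seed=3, n_init=1)
        many = fit_assign(T, k=4, covariance="diag", seed=3, n_init=10)
        assert many.log_likelihood >= one.log_likelihood - 1e-6

    def test_planted_subtypes_recovered(self, planted_depressed):
        """A k=4 mixture in the transformed biomarker space recovers the
        generator's latent subtypes."""
        dep, T = planted_depressed
        sol = fit_assign(T, k=4, covariance="diag", seed=0, n_init=5)
        ari = adjusted_rand_score(dep.df["subtype"].to_numpy(), sol.assignments)
        assert ari >= 0.7

    def test_mixing_weights_recovered(self):
        dep = sample_cohort(GeneratorSpec(n_total=1000, n_depressed=1000, seed=5))
        X = dep.df[biomarker_features(dep)]
        T, _ = prep.fit_apply_yeo_johnson(X, X)
        sol = fit_assign(T, k=4, covariance="diag", seed=5, n_init=20)
        planted = sorted([26 / 90, 27 / 90, 9 / 90, 28 / 90])
        fitted = sorted(sol.weights)
        assert np.allclose(fitted, planted, atol=0.1)


class TestProfileBattery:
    def test_shifted_cluster_flagged_with_large_effect(self):
        rng = np.random.default_rng(0)
        assignments = np.repeat([0, 1, 2, 3], 25)
        df = pd.DataFrame({"flat": rng.normal(0, 1, 100),
                           "shifted": rng.normal(0, 1, 100) + 3.0 * (assignments == 2)})
        prof = profile_clusters(assignments, df)
        row = prof.row("shifted")
        assert row["p_value"] < 0.001
        involved = [p for p in row["posthoc"] if 2 in p["pair"]]
        assert involved and all(p["p_adjusted"] < 0.05 for p in involved)
        assert prof.row("flat")["p_value"] > 0.001

    def test_constant_and_tiny_cluster_variables_skipped(self):
        assignments = np.array([0] * 10 + [1] * 10 + [2] * 1)
        df = pd.DataFrame({"x": np.ones(21), "y": np.arange(21.0)})
        with pytest.warns(UserWarning):
            prof = profile_clusters(assignments, df)
        assert not prof.rows
        assert len(prof.skipped) == 2

    def test_categorical_omnibus_and_pairwise(self):
        rng = np.random.default_rng(1)
        assignments = np.repeat([0, 1, 2], 60)
        cat = np.where(assignments == 1,
                       rng.choice(["a", "b"], 180, p=[0.9, 0.1]),
                       rng.choice(["a", "b"], 180, p=[0.3, 0.7]))
        prof = profile_clusters(assignments, pd.DataFrame({"cat": pd.Series(cat, dtype=object)}))
        row = prof.row("cat")
        assert row["test"] == "chi2" and row["p_value"] < 0.001
        assert any(1 in p["pair"] and p["p_adjusted"] < 0.05 for p in row["posthoc"])

    def test_null_omnibus_pvalues_roughly_uniform(self):
        """Type-I sanity at module scale (the full 200-variable simulation
        lives in the acceptance suite)."""
        rng = np.random.default_rng(2)
        assignments = np.repeat([0, 1, 2, 3], 25)
        df = pd.DataFrame({f"v{j}": rng.normal(0, 1, 100) for j in range(40)})
        prof = profile_clusters(assignments, df)
        frac = np.mean([r["p_value"] < 0.05 for r in prof.rows])
        assert frac <= 0.15

    def test_dunn_matches_kruskal_direction(self):
        rng = np.random.default_rng(3)
        groups = np.repeat([0, 1, 2], 40)
        vals = rng.normal(0, 1, 120) + 2.0 * (groups == 0)
        res = dunn_posthoc(vals, groups)
        flagged = {frozenset(p["pair"]) for p in res if p["p_adjusted"] < 0.05}
        assert frozenset({0, 1}) in flagged and frozenset({0, 2}) in flagged
        assert frozenset({1, 2}) not in flagged


class TestLabelling:
    def test_truth_assignments_get_their_names(self):
        dep = sample_cohort(GeneratorSpec(n_total=360, n_depressed=360, seed=2))
        truth = dep.df["subtype"].astype("category")
        assignments = truth.cat.codes.to_numpy()
        names = dict(enumerate(truth.cat.categories))
        labels = label_clusters(assignments, dep.df)
        assert labels.resolved
        for cluster_id, assigned in labels.labels.items():
            assert assigned == names[cluster_id]

    def test_wrong_k_is_notice_not_error(self):
        df = pd.DataFrame({c: np.arange(9.0) for c in
                           ("crp_mg_dl", "hrv_sdnn_lying_ms", "hrv_baevskii_lying",
                            "bmi", "age_years")})
        labels = label_clusters(np.repeat([0, 1, 2], 3), df)
        assert not labels.resolved
        assert "k=4" in labels.diagnostics[0] and "k=3" in labels.diagnostics[0]

    def test_identical_clusters_unresolved_with_diagnostic(self):
        df = pd.DataFrame({c: np.ones(8) for c in
                           ("crp_mg_dl", "hrv_sdnn_lying_ms", "hrv_baevskii_lying",
                            "bmi", "age_years")})
        labels = label_clusters(np.repeat([0, 1, 2, 3], 2), df)
        assert not labels.resolved
        assert any("tie" in d for d in labels.diagnostics)

    def test_end_to_end_immunometabolic_recovered(self, planted_depressed):
        dep, T = planted_depressed
        sol = fit_assign(T, k=4, covariance="diag", seed=0, n_init=5)
        profile_df = dep.df[biomarker_features(dep)].copy()
        profile_df["age_years"] = dep.df["age_years"]
        labels = label_clusters(sol.assignments, profile_df)
        im_clusters = [c for c, name in labels.labels.items() if name == "ImmunoMetabolic"]
        assert len(im_clusters) == 1
        members = dep.df.loc[sol.assignments == im_clusters[0], "subtype"]
        assert (members == "ImmunoMetabolic").mean() >= 0.5
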