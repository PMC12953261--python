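"""Generator calibration, determinism, and structural invariants."""

import numpy as np
import pandas as pd
import pytest

from depcascade.cohort import (
    GeneratorSpec,
    allocate_item_scores,
    inject_missingness,
    load_feature_metadata,
    load_item_scales,
    load_profiles,
    sample_cohort,
)
from depcascade.exceptions import SchemaError, ValidationError


@pytest.fixture(scope="module")
def profiles():
    return load_profiles()


class TestProfiles:
    def test_printed_parameters(self, profiles):
        groups, subtypes = profiles
        assert groups["depressed"].continuous_params["phq9_total"] == (14.68, 5.18)
        assert groups["depressed"].continuous_params["who5_total"] == (11.23, 4.11)
        assert groups["non_depressed"].continuous_params["phq9_total"] == (4.77, 3.51)
        assert subtypes["ImmunoMetabolic"].continuous_params["bmi"] == (31.51, 8.45)
        assert subtypes["ImmunoMetabolic"].continuous_params["hrv_sdnn_lying_ms"] == (20.11, 9.46)

    def test_mixing_weights_follow_cluster_sizes(self, profiles):
        _, subtypes = profiles
        expected = {"Adaptive": 26, "LateDepression": 27,
                    "ImmunoMetabolic": 9, "OverweightNonInflammatory": 28}
        for label, n in expected.items():
            assert subtypes[label].mixing_weight == pytest.approx(n / 90, abs=1e-9)
        assert sum(s.mixing_weight for s in subtypes.values()) == pytest.approx(1.0)

    def test_invalid_fixtures_rejected(self, tmp_path):
        bad_sd = tmp_path / "bad_sd.yaml"
        base = (
            "item_scales: {phq9: {items: 9, min_item: 0, max_item: 3}}\n"
            "features:\n  phq9_total: {modality: self_report_total, vtype: ordinal}\n"
            "subtype_profiles: {}\n"
        )
        bad_sd.write_text(base + (
            "group_profiles:\n"
            "  depressed: {n_default: 90, continuous: {phq9_total: [14.68, -1.0]}, categorical: {}}\n"
            "  non_depressed: {n_default: 491, continuous: {}, categorical: {}}\n"
        ))
        with pytest.raises(ValidationError, match="negative sd"):
            load_profiles(bad_sd)

        bad_prob = tmp_path / "bad_prob.yaml"
        bad_prob.write_text(base.replace(
            "features:\n  phq9_total: {modality: self_report_total, vtype: ordinal}\n",
            "features:\n  sex_female: {modality: biographic, vtype: binary}\n") + (
            "group_profiles:\n"
            "  depressed: {n_default: 90, continuous: {}, categorical: {sex_female: {1: 0.7, 0: 0.2}}}\n"
            "  non_depressed: {n_default: 491, continuous: {}, categorical: {}}\n"
        ))
        with pytest.raises(ValidationError, match="sum"):
            load_profiles(bad_prob)

        unknown = tmp_path / "unknown.yaml"
        unknown.write_text(base + (
            "group_profiles:\n"
            "  depressed: {n_default: 90, continuous: {not_a_feature: [1.0, 1.0]}, categorical: {}}\n"
            "  non_depressed: {n_default: 491, continuous: {}, categorical: {}}\n"
        ))
        with pytest.raises(SchemaError, match="not_a_feature"):
            load_profiles(unknown)


class TestSampling:
    def test_stratification_and_subtype_counts(self, clean_cohort):
        assert clean_cohort.n == 581
        assert int(clean_cohort.labels.sum()) == 90
        counts = clean_cohort.df["subtype"].value_counts()
        assert counts.to_dict() == {"OverweightNonInflammatory": 28, "LateDepression": 27,
                                    "Adaptive": 26, "ImmunoMetabolic": 9}
        # subtype is null exactly on the non-depressed rows
        assert clean_cohort.df.loc[clean_cohort.labels == 0, "subtype"].isna().all()
        assert clean_cohort.df.loc[clean_cohort.labels == 1, "subtype"].notna().all()

    def test_identical_spec_gives_identical_table(self):
        a = sample_cohort(GeneratorSpec(n_total=150, n_depressed=30, seed=7))
        b = sample_cohort(GeneratorSpec(n_total=150, n_depressed=30, seed=7))
        assert a.df.to_csv(index=False) == b.df.to_csv(index=False)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec(n_total=0)
        with pytest.raises(ValueError):
            GeneratorSpec(n_total=100, n_depressed=101)
        with pytest.raises(ValueError):
            GeneratorSpec(missing_rate=1.0)
        with pytest.raises(ValueError):
            GeneratorSpec(subtype_weights={"NotASubtype": 1.0})

    def test_group_mean_calibration(self):
        """At n=4000 per group, sample means sit within 3*sd/sqrt(n) of the
        profile means (features whose clipping bounds are far from the
        mean, so truncation bias is negligible)."""
        groups, _ = load_profiles()
        n = 4000
        dep = sample_cohort(GeneratorSpec(n_total=n, n_depressed=n, seed=11)).df
        nondep = sample_cohort(GeneratorSpec(n_total=n, n_depressed=0, seed=12)).df
        checked = ["phq9_total", "who5_total", "madrs_total", "whodas_total",
                   "gad7_total", "age_years", "cortisol_ug_dl"]
        for feat in checked:
            m_nd, s_nd = groups["non_depressed"].continuous_params[feat]
            assert abs(nondep[feat].mean() - m_nd) < 3 * s_nd / np.sqrt(n), feat
        for feat in ["phq9_total", "who5_total", "madrs_total", "whodas_total", "gad7_total"]:
            m_d, s_d = groups["depressed"].continuous_params[feat]
            assert abs(dep[feat].mean() - m_d) < 3 * s_d / np.sqrt(n), feat

    def test_within_block_correlation_structure(self):
        n = 4000
        df = sample_cohort(GeneratorSpec(n_total=n, n_depressed=0, seed=3)).df
        same_block = np.corrcoef(df["ast_u_l"], df["alt_u_l"])[0, 1]
        assert abs(same_block - 0.3) < 0.1
        cross_block = np.corrcoef(df["ast_u_l"], df["hrv_sdnn_lying_ms"])[0, 1]
        assert abs(cross_block) < 0.1

    def test_totals_equal_item_sums(self, clean_cohort):
        for qname, (k, lo, hi) in clean_cohort.item_scales.items():
            items = [f"{qname}_i{j}" for j in range(1, k + 1)]
            sums = clean_cohort.df[items].sum(axis=1)
            assert (sums == clean_cohort.df[f"{qname}_total"]).all()
            assert clean_cohort.df[items].min().min() >= lo
            assert clean_cohort.df[items].max().max() <= hi

    def test_forced_subtype(self):
        t = sample_cohort(GeneratorSpec(n_total=50, n_depressed=50, seed=5,
                                        subtype_weights={"ImmunoMetabolic": 1.0}))
        assert (t.df["subtype"] == "ImmunoMetabolic").all()


class TestItemAllocation:
    def test_boundary_totals(self):
        assert (allocate_item_scores(0, (9, 0, 3), seed=0) == 0).all()
        assert (allocate_item_scores(27, (9, 0, 3), seed=0) == 3).all()

    def test_seeded_partitions_sum_and_stay_in_bounds(self):
        for seed in range(1000):
            items = allocate_item_scores(14, (9, 0, 3), seed=seed)
            assert items.sum() == 14
            assert items.min() >= 0 and items.max() <= 3

    def test_allocation_is_random_not_rounding(self):
        draws = {tuple(allocate_item_scores(14, (9, 0, 3), seed=s)) for s in range(50)}
        assert len(draws) > 1

    def test_impossible_scale(self):
        with pytest.raises(ValueError, match="min_item"):
            allocate_item_scores(5, (3, 4, 2), seed=0)


class TestMissingness:
    def test_rate_zero_is_identity(self, clean_cohort):
        out = inject_missingness(clean_cohort, 0.0, seed=0)
        pd.testing.assert_frame_equal(out.df, clean_cohort.df)

    def test_observed_rate_and_protected_columns(self, clean_cohort):
        out = inject_missingness(clean_cohort, 0.1, seed=42)
        cells = out.df[list(out.dictionary)]
        frac = float(cells.isna().to_numpy().mean())
        assert abs(frac - 0.1) < 0.01
        assert out.df["diagnosis"].notna().all()
        assert out.df["participant_id"].notna().all()

    def test_seeded_reproducibility(self, clean_cohort):
        a = inject_missingness(clean_cohort, 0.1, seed=9)
        b = inject_missingness(clean_cohort, 0.1, seed=9)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_rate_one_rejected(self, clean_cohort):
        with pytest.raises(ValueError):
            inject_missingness(clean_cohort, 1.0, seed=0)


def test_feature_metadata_covers_required_scales():
    scales = load_item_scales()
    assert scales["phq9"] == (9, 0, 3)
    assert scales["who5"] == (5, 0, 5)
    assert scales["whodas"] == (12, 0, 4)
    assert scales["phq15"] == (15, 0, 2)
    meta = load_feature_metadata()
    assert all(m["modality"] in ("self_report_item", "self_report_total", "lab",
                                 "physiological", "anthropometric", "biographic")
               for m in meta.values())
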